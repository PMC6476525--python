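# apsscan

Analysis toolkit for **AU-rich proximal UTR sequences (APS)** — a 3′-UTR
cis-regulatory feature defined by two criteria:

1. the 3′ UTR is at least **300 bases** long, and
2. the AU base content **strictly exceeds 50%** over the **first 100 bases**
   immediately after the stop codon.

APS-positive mRNAs (CXCL8 being the prototype, with TNFAIP6 a predicted
second member) are translated at an elevated rate in macrophages, a pattern
linked to ERK1/2-driven phosphorylation of ribosomal protein S6 at S235/236.
`apsscan` implements the computational layer around that biology for people
studying UTR-mediated translational control: UTR extraction and coordinate
arithmetic, AU-content profiling and APS classification, in-silico reporter
mutagenesis, conserved-block detection across homologs, exact-match in-silico
PCR, and the quantification arithmetic for qPCR (2^−ΔΔCt), UTR-reporter,
plasmid, western-blot and 14-fraction polysome-profiling data. Seeded
synthetic-data generators emulate every input, so the whole pipeline is
testable offline and parameter recovery is measurable.

## Core definitions

For a 3′ UTR sequence *s* (DNA representation; U stored as T):

- AU fraction of a window *w*: `(#A + #T) / |w|`, with N counted in the
  denominator only.
- APS call: `is_aps_positive = (len(s) ≥ 300) AND (100 · AU(s[1..100]) > 50)`.
  The length bound is inclusive, the AU bound strict; both are parameters.
- ΔΔCt: `ΔCt = Ct_target − Ct_reference` per sample;
  `fold = E^−(ΔCt_sample − ΔCt_control)` with efficiency `E = 2` by default.
- Reporter fold change: per-replicate `log2(UTR-reporter / control-reporter)`.
- Plasmid-derived fold change: `(full − control) / (CDS − control)` after
  subtracting the endogenous background measured in empty-vector cells.
- Polysome profile: each of 14 sucrose-gradient fractions as a percentage of
  the per-mRNA sum; heavy-fraction share = percentage in fractions ≥ 8.
- Conservation: homologs globally aligned to a reference (Needleman–Wunsch,
  match +1 / mismatch −1 / gap −2); maximal runs of reference columns matched
  by every homolog are reported as conserved blocks.

## Worked example

```python
from apsscan import (ConstructSpec, TranscriptRecipe, apply_edits,
                     classify_aps, extract_utrs, gen_transcript)

utr3 = extract_utrs(gen_transcript(
    TranscriptRecipe(seed=5, utr3_len=400, proximal_au_override=(100, 0.9)))).utr3
donor = "GC" * 45 + "G"                      # 91 nt, zero AU content

for name, edits in [("original", []),
                    ("head_insertion", [("insert_at", 0, "donor")]),
                    ("distal_insertion_285_286", [("insert_at", 285, "donor")])]:
    seq = apply_edits(ConstructSpec(name, {"utr": utr3.seq, "donor": donor},
                                    "utr", edits)).seq
    call = classify_aps(seq)
    print(f"{name:<26} length={call.utr3_length:>3}  "
          f"first100_AU={call.first100_au_percent:5.1f}%  APS+={call.is_aps_positive}")
```

prints

```
original                   length=400  first100_AU= 91.0%  APS+=True
head_insertion             length=491  first100_AU=  9.0%  APS+=False
distal_insertion_285_286   length=491  first100_AU= 91.0%  APS+=True
```

Inserting the low-AU donor at the UTR head displaces the AU-rich proximal
sequence and flips the APS call; the same donor inserted between positions
285 and 286 leaves the first 100 bases — and the call — unchanged. This is
the design logic by which insertion mutants separate the proximal-sequence
effect from total-UTR composition. The `examples/` directory has one short
script per capability (classification, construct building, conservation,
expression quantification, polysome profiles, in-silico PCR).

A thin CLI mirrors the library:

```bash
apsscan classify --fasta transcripts.fasta --cds-table cds.tsv
apsscan pcr --fasta transcripts.fasta --cds-table cds.tsv --primers primers.tsv
apsscan polysome --table fractions.tsv --heavy-start 8
```

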