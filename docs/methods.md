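# Methods

## The APS classification rule

A 3′ UTR is called APS-positive when both of two criteria hold: the UTR is at
least `min_len = 300` bases long (inclusive bound), and the AU base content of
its first `proximal_len = 100` bases — the bases immediately after the stop
codon — strictly exceeds `threshold = 50` percent. The strict/inclusive
asymmetry is deliberate: "exceeds fifty percent" reads as strict, "at least
three hundred bases" as inclusive, and the boundary cases (exactly 50% AU,
exactly 299 nt) are pinned down by unit tests. All three cut-offs are
parameters because the biological boundary is soft — a ~283-nt fragment can
behave like a ≥300-nt one — but the defaults are the operative definition and
the classifier never silently departs from them.

AU content of a window is `(#A + #T) / window length`. RNA input is stored as
DNA (U→T) so A and T form the AU class; `N` counts in the denominator only,
so ambiguity can only dilute, never create, an APS call, and sequences more
than 10% N are rejected outright. UTRs shorter than 100 nt are scored over
their full length with `short_region_flag=True`; they can never be
APS-positive anyway because of the length criterion.

## Coordinates

Everything is 1-based and inclusive, the convention under which the published
construct names make arithmetic sense: fragment (79–153) has length 75,
(1112–1252) length 141, (1183–1252) length 70. `subregion` is the single
place this arithmetic lives; nested subregions compose as
`sub(sub(s,a,b),c,d) = sub(s, a+c−1, a+d−1)` (property-tested). The 3′ UTR of
a transcript with CDS `[cds_start, cds_end]` is `[cds_end+1, len]`; empty
UTRs are represented as `None`, not zero-length regions, so downstream
composition statistics fail loudly on degenerate input.

## AU profiles

The line-chart profile uses a sliding window (default 100 nt, step 10) with
the last partial window dropped. The windowing behind the published line
charts is not recorded anywhere, so window and step are exposed as options —
but the APS call itself never depends on them: it always uses the fixed
first-100-bases statistic.

## Construct building

Reporter UTR mutants are expressed as ordered edit programs
(`take`/`insert_at`/`fuse`/`delete`) over named parts, with coordinates
re-evaluated after each edit and a provenance log recording before/after
lengths. Insertion at position 0 prepends ahead of base 1 (the "disrupt the
head" mutation); insertion at position *k* places the donor between bases *k*
and *k+1* (the distal control). Length algebra
(`result = initial take + Σ inserts − Σ deletes`) and byte-for-byte replay
determinism are tested invariants.

## ARE scan

AU-rich destabilizing elements are located with a plain AUUUA-pentamer scan
(DNA `ATTTA`), reporting all overlapping occurrences; hits within 5 nt share
a cluster id. This deliberately replaces an external motif-prediction web
service with a documented, reproducible primitive; externally computed ARE
intervals can equally be supplied as coordinates when building ΔARE
constructs.

## Conservation

Homology is assessed by pairwise global alignment of each homolog to a
designated reference (not progressive multiple alignment): Needleman–Wunsch
with match +1, mismatch −1, linear gap −2, and fixed traceback tie-breaking
(diagonal, then up, then left) for reproducibility. Per-reference-column
identity is the fraction of homologs whose aligned base matches the
reference; a gap counts as a mismatch. Maximal runs of columns at or above
the identity threshold (default 1.0 — perfectly conserved columns, since no
published threshold exists) are reported longest-first.

The recovery experiment embeds a mutation-free 37-nt block at position 80 of
a 200-nt random reference and applies i.i.d. substitutions at rate 0.2 to the
flanks of each homolog. The homolog count matters: a flank column adjacent to
the block stays coincidentally perfect in all *n* homologs with probability
`0.8^n`, and those columns attach to the recovered block. With 4 homologs
(`0.8⁴ ≈ 0.41`) the expected attachment is large enough that the block
over-extends past ±2 nt in roughly a fifth of trials; with the 8 homologs
used here (`0.8⁸ ≈ 0.17`) the per-trial probability of staying within ±2 nt
is ≈98%. Eight mammalian homologs is also a realistic alignment panel for a
well-conserved chemokine UTR.

## In-silico PCR

Primer matching is exact on the sense strand (forward primer verbatim,
reverse-complemented reverse primer downstream), because qPCR primers are
designed for perfect complementarity and the printed amplicon length is the
only machine-verifiable contract. Product length includes both primer
footprints. When multiple products exist, `require_unique` (default) raises
with every site listed — a multi-product qPCR assay is broken — while batch
screening reports the shortest product with status `multiple`, matching which
product dominates amplification.

## Quantification arithmetic

- **ΔΔCt**: replicate Ct values are averaged on the Ct scale before
  differencing (geometric-mean behaviour on the expression scale; the
  aggregation order is not otherwise recorded). Efficiency defaults to 2.0
  (the 2^−ΔΔCt method as usually printed) with a per-primer override in
  (1, 2.2]. Fold change is invariant under a common Ct offset.
- **Reporter fold change**: per-replicate `log2(UTR / control)` with
  replicates paired positionally by batch; the summary is the mean of
  per-replicate log2 folds, reported alongside every replicate (averaging
  before versus after the ratio is supported by taking `scale="linear"` and
  summarising externally; log2-after-ratio is the documented default).
- **Plasmid-derived fold change**: `(full − control)/(CDS − control)` per
  replicate. Background subtraction can go negative with noisy data;
  non-computable replicates are flagged and excluded from the mean rather
  than clipped, because silent clipping biases the fold upward.
- **Western ratios**: per-lane minimum-profile background subtraction, then
  `phospho / total` per lane, normalized to the designated control lane
  (ratio 1.0). The inhibitor effect is `[Control] / [Inhibitor]`. A total
  band that vanishes after subtraction is fatal for that lane.
- No hypothesis testing is attached anywhere: the source data are replicate
  dots without named statistics, and inventing tests would be analysis the
  data do not support.

## Polysome profiles

Raw 14-fraction qPCR abundances are normalized to percentages of their sum
(idempotent, scale-invariant). Summaries: `heavy_share` = percentage in
fractions ≥ `heavy_start`, and the percentage-weighted mean fraction index in
[1, 14]. No published fraction index separates monosomes from heavy
polysomes on these gradients, so `heavy_start` defaults to 8 — the second
half of a 14-fraction 10–50% gradient — and is always carried in the summary
record; the statistic is descriptive positional mass, not a ribosome count.
Condition differences are simple `a − b` deltas, positive meaning condition
`a` sits heavier.

## Synthetic data

The generators define the test conditions:

- **Transcripts**: bases i.i.d. per region with `P(A)=P(T)=au/2`,
  `P(C)=P(G)=(1−au)/2`; CDS starts ATG and ends with a stop codon; an
  optional proximal override draws the 3′-UTR head at its own AU target. No
  dinucleotide structure — sufficient for composition statistics, not for
  secondary-structure questions.
- **Ct tables**: reference gene at a 20-cycle baseline; target Ct =
  `baseline − log2(fold) + N(0, σ)` with σ = 0.2 cycles by default (a typical
  technical-replicate spread); the control sample (fold 1) is appended
  automatically, so ΔΔCt recovers the fold exactly at σ = 0.
- **Luminescence**: log-normal multiplicative noise at CV 10% with zero-mean
  log draws, so per-replicate log2 ratios are unbiased.
- **Polysome counts**: multinomial draws (depth 10,000 ≈ a plausible
  per-profile qPCR signal mass) around weights `p_i · exp(shift·(i−1))`
  renormalized — a logit offset linear in fraction index, the simplest
  mechanism that pushes mass toward heavy fractions. `tilted_profile` gives
  the closed-form expectation for calibration tests.
- **Bands**: phospho = ratio × total with log-normal CV and a shared additive
  per-lane background, so minimum-profile subtraction is exactly invertible
  at zero noise.

Every generator is a pure function of (parameters, seed); substreams are
keyed by a CRC of the generator name off a single global seed, so adding a
generator never perturbs existing fixtures. What the generators do **not**
emulate: amplification-efficiency drift, inter-run batch effects, gradient
A260 baselines, sequence context effects on primer binding, phylogenetic
structure among homologs. Passing tests therefore demonstrate the arithmetic
and its statistical calibration under clean error models, not robustness to
those real-data artefacts.

## Problem sizes and numerical choices

The verification suite runs the classifier oracle at 1,000 random UTRs
(lengths 50–2,000), alignment identity at 100 random sequences, ΔΔCt recovery
at 100 replicates per fold in {0.25, 1, 4, 16}, reporter recovery at 50
replicates, block recovery over 20 seeds, and the polysome sign test over 200
simulations at depth 10,000 — sizes at which the expected estimator error is
several times smaller than the tested tolerance, keeping the checks sharp and
the whole suite fast. Percentage sums are validated to 1e−9 relative
tolerance; alignment and composition arithmetic is exact integer work.

## Known limitations

Single-interval mRNA-space coordinates only (no spliced genomic joins);
pairwise-to-reference conservation rather than true multiple alignment; exact
primer matching (no mismatch tolerance or melting-temperature model); the
heavy-fraction boundary is a parameter, not an inference; the APS rule is a
binary classifier of a soft biological threshold and carries no effect-size
model.
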