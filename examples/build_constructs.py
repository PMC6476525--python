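"""Reproduce the APS insertion/disruption logic of mutant reporter UTRs.

Starting from an APS-positive 400-nt UTR, a low-AU 91-nt donor is inserted
either at the UTR head (before base 1) or distally (between positions 285 and
286).  The head insertion displaces the AU-rich proximal sequence and flips
the APS call; the distal insertion leaves the first 100 bases untouched.
"""

from apsscan import (ConstructSpec, TranscriptRecipe, apply_edits, classify_aps,
                     extract_utrs, gen_transcript)

utr3 = extract_utrs(gen_transcript(
    TranscriptRecipe(seed=5, utr3_len=400, proximal_au_override=(100, 0.9)))).utr3
donor = "GC" * 45 + "G"  # 91 nt with zero AU content

variants = {
    "original": utr3.seq,
    "head_insertion": apply_edits(ConstructSpec(
        "head", {"utr": utr3.seq, "donor": donor}, "utr",
        [("insert_at", 0, "donor")])).seq,
    "distal_insertion_285_286": apply_edits(ConstructSpec(
        "distal", {"utr": utr3.seq, "donor": donor}, "utr",
        [("insert_at", 285, "donor")])).seq,
}

for name, seq in variants.items():
    call = classify_aps(seq)
    print(f"{name:<26} length={call.utr3_length:>3}  "
          f"first100_AU={call.first100_au_percent:5.1f}%  APS+={call.is_aps_positive}")

# Head insertion drops the proximal AU content below 50% -> APS-negative;
# the distal insertion preserves the head and the positive call.
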