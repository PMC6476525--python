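"""Classify synthetic 3' UTRs as APS-positive or -negative.

Builds three transcripts whose 3'-UTR heads are drawn at different AU targets,
extracts the UTRs and applies the APS rule: AU content strictly above 50% in
the first 100 bases AND a UTR of at least 300 bases.
"""

from apsscan import TranscriptRecipe, classify_aps, extract_utrs, gen_transcript

recipes = {
    "au_rich_long": TranscriptRecipe(seed=1, utr3_len=400, proximal_au_override=(100, 0.75)),
    "au_poor_long": TranscriptRecipe(seed=2, utr3_len=400, proximal_au_override=(100, 0.30)),
    "au_rich_short": TranscriptRecipe(seed=3, utr3_len=250, proximal_au_override=(100, 0.75)),
}

print(f"{'utr':<14} {'len':>5} {'first100_AU%':>13} {'len_ok':>7} {'au_ok':>6} {'APS+':>5}")
for name, recipe in recipes.items():
    utr3 = extract_utrs(gen_transcript(recipe)).utr3
    call = classify_aps(utr3)
    print(f"{name:<14} {call.utr3_length:>5} {call.first100_au_percent:>13.1f} "
          f"{str(call.length_ok):>7} {str(call.au_ok):>6} {str(call.is_aps_positive):>5}")

# Only the long UTR with the AU-rich head is APS-positive: a high proximal AU
# content alone (short UTR) or length alone (GC-rich head) does not suffice.
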