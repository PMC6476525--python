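"""Predict qPCR amplicon sizes on synthetic templates.

Embeds a primer pair's binding sites into a generated transcript at known
positions and screens the template, verifying the predicted product length
equals forward footprint + spacer + reverse footprint.
"""

from apsscan import (PrimerPair, TranscriptRecipe, batch_screen, find_amplicon,
                     gen_transcript, revcomp)

pair = PrimerPair("rpl27_like",
                  forward="ATCGCCAAGAGATCAAAGATAA",
                  reverse="TCTGAAGACATCCTTATTGACG")

t = gen_transcript(TranscriptRecipe(seed=9), id="synthetic_template")
# splice the primer sites into the 3' UTR, 79 nt apart -> 22 + 79 + 22 = 123 bp
seq = t.seq[:500] + pair.forward + t.seq[500:579] + revcomp(pair.reverse) + t.seq[579:]
amp = find_amplicon(seq, pair)
print(f"amplicon on modified template: start={amp.start}, end={amp.end}, "
      f"length={amp.length} bp")

report = batch_screen([t], [pair])
print("\nscreen of the unmodified template (no binding sites):")
print(report.to_string(index=False))
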