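"""Run the quantification arithmetic on synthetic qPCR/reporter/western data.

Each generator encodes a known truth; the corresponding formula recovers it.
"""

from apsscan import (NoiseModel, ddct_table, gen_bands, gen_ct_table,
                     gen_luminescence, phospho_fold_change, plasmid_fold_change,
                     reporter_fold_change, western_ratio)

# 2^-ddCt: a sample expressing the target 4x over control, Ct noise 0.2 cycles
table = gen_ct_table({"treated": 4.0}, NoiseModel(ct_sigma=0.2), n_replicates=6, seed=1)
res = ddct_table(table, target="TARGET", reference="REF", control_sample="control")
fold = res.set_index("sample").loc["treated", "fold_change"]
print(f"ddCt estimated fold (truth 4.0): {fold:.2f}")

# UTR-reporter: luminescence of a 4x construct over the UTR-less control
batch = gen_luminescence(4.0, NoiseModel(lum_cv=0.10), n=8, seed=2)
rep = reporter_fold_change(batch["utr_signal"], batch["control_signal"])
print(f"reporter mean log2 fold (truth 2.0): {rep['mean']:.2f} over {rep['n']} replicates")

# Plasmid-derived fold change with endogenous background subtraction
plasmid = plasmid_fold_change(full_measured=[10.0, 9.5], cds_measured=[4.0, 4.2],
                              control_measured=[2.0, 2.1])
print(f"plasmid-derived fold change (full-ctrl)/(cds-ctrl): {plasmid['mean']:.2f}")

# Western ratios: control lane at phospho/total 1.0, inhibitor lane at 0.125
bands = gen_bands([1.0, 0.125], NoiseModel(band_cv=0.05), seed=3)
ratios = western_ratio(bands["phospho_raw"], bands["total_raw"], bands["background"])
print(f"phospho fold change control/inhibitor (truth 8.0): "
      f"{phospho_fold_change(ratios[0], ratios[1]):.2f}")
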