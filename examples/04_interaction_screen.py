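"""Ligand-receptor interaction screen with exact cohort-level calls.

Scores each (ligand, receptor, sender, receiver, tissue) combination as the
product of per-sample mean expressions and calls it significant when the
seven per-patient scores are greater than zero by an exact one-sided
Wilcoxon signed-rank test (p < 0.05).
"""

import immscape as im

dataset = im.simulate_cohort(im.default_config(seed=4))  # 2,000 cells/sample
norm = im.normalize_log2(dataset.matrix)

pairs = [
    im.LigandReceptorPair("IL1B", "IL1R2"),     # planted in tumor
    im.LigandReceptorPair("HLA-A", "LILRB1"),   # planted in tumor
    im.LigandReceptorPair("LIGAND01", "RECEPTOR01"),  # null
]
result = im.interaction_screen(
    norm, pairs, [("Macrophage", "Treg"), ("Treg", "Macrophage")]
)
cols = ["ligand", "receptor", "sender_type", "tissue", "n_samples",
        "mean_score", "p_value", "significant"]
print(result[cols].round(5).to_string(index=False))
# The two planted macrophage/Treg axes are called in tumor (p = 1/128 when
# all seven patients score positive) and not in adjacent tissue; the null
# pair stays below the significance threshold.
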