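"""Cell-type composition fractions and paired tumor-vs-adjacent tests.

Builds per-sample cell-type fraction tables and tests each type's tumor
fraction against its matched adjacent fraction with a two-tailed paired
t-test across the seven patients.
"""

import immscape as im

dataset = im.simulate_cohort(im.default_config(seed=5, cells_per_sample=500))
annotations = dataset.matrix.cell_meta.reset_index()

ft = im.fraction_table(annotations, unit_column="cell_type", denominator="all_cells")
print("mean fraction by (tissue, cell type):")
print(ft.table.groupby(["tissue", "unit"])["fraction"].mean().round(3).to_string())

print("\npaired tumor-vs-adjacent tests:")
for unit in sorted(ft.table["unit"].unique()):
    stat, p, direction = im.paired_tissue_test(ft, unit)
    print(f"  {unit:<12} t={stat:+.2f}  p={p:.4f}  {direction}")
# Treg and CD8_Tex come out tumor-enriched and NK/B adjacent-enriched,
# matching the composition shifts the generator plants.
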