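"""Tree-discovered subgroups with truncated-product closed testing.

Simulated pairs where one covariate combination carries a strong effect:
a regression tree on the absolute within-pair differences proposes
subgroups, and closed testing over the subgroup sharp nulls (combined by
the truncated product of p-values) reports which subgroups survive, per
value of the sensitivity parameter Γ.
"""

from hetsens import hsr_pipeline
from hetsens.simulation import SimConfig, generate

sample, table, truth = generate(
    SimConfig(I=500, p=4, beta=(1.6, 0.0, 0.0, 0.0), seed=42), seed=42)
print(f"{sample.I} exactly matched pairs; effect 1.6 when x1=x2=0")

res = hsr_pipeline(table, table.covariate_names,
                   gamma_grid=[1.0, 1.2, 1.4, 1.6, 1.8], side="two",
                   sample=sample)
print(f"tree split on: {res.tree.selected_covariates} "
      f"-> G = {res.partition.G} subgroups, sizes {res.partition.sizes}")

singles = [c for c in res.table.columns if "&" not in c]
print("\nper-subgroup worst-case p-values (two-sided):")
print(res.table[singles].round(4).to_string())
print("\nsensitivity values (smallest Γ at which closed testing stops "
      "rejecting; inf = beyond the grid):")
for lbl in singles:
    print(f"  {lbl}: {res.sensitivity_values[lbl]}")
print("Reading: subgroups holding the planted effect stay significant "
      "deep into the Γ grid; null subgroups are never rejected.")
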