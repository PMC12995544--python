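"""Desk-scale method comparison: power and modifier identification.

Replicates the benchmark design at reduced scale: I pairs, p binary
covariates, two true effect modifiers.  Five variants are compared — the
tree-based procedure (hsr), submax on all covariates, tree-seeded submax+
and the two oracle benchmarks (true modifiers / non-modifiers only) —
by F1 and TPR for hypothesis rejections and for identified modifiers.
"""

from hetsens.simulation import SimConfig, study

cfg = SimConfig(I=300, p=4, beta=(1.2, 0.0, 0.0, 0.4), reps=30,
                gamma_grid=(1.0, 1.6), seed=5)
out = study(cfg)

for metric in ("power_f1", "modifier_f1"):
    pivot = out[out.metric == metric].pivot(index="gamma",
                                            columns="variant",
                                            values="mean")
    print(f"\nmean {metric} over {cfg.reps} replicates:")
    print(pivot.round(2).to_string())

print("\nReading: rejections and identifications fade as the permitted "
      "hidden bias Γ grows; the worst-case benchmark never identifies a "
      "true modifier (its modifier F1 is exactly 0), while the oracle "
      "benchmark bounds what data-driven selection could achieve.")
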