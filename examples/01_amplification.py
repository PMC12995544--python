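"""Interpreting the sensitivity parameter through amplification.

A sensitivity value Γ says an unmeasured confounder would have to multiply
the odds of treatment by more than Γ to overturn a finding.  The
amplification maps one Γ to pairs (Λ, Δ): a confounder that multiplies the
treatment odds by Λ AND the odds of a higher outcome by Δ produces the
same worst-case bias whenever Γ = (ΛΔ + 1)/(Λ + Δ).
"""

from hetsens import amplification_curve, delta_of, gamma_of
from hetsens.amplification import symmetric_point

print("A confounder doubling both odds (Λ=Δ=2) is equivalent to "
      f"Γ = {gamma_of(2, 2):.2f}")

for gamma in (1.17, 1.75, 1.81):
    lam = 3.0 if gamma > 1.5 else 2.0
    print(f"Γ = {gamma:<5} ≙ a confounder with Λ = {lam:.0f} and "
          f"Δ = {delta_of(gamma, lam):.1f}")

gamma = 1.81
print(f"\nAmplification curve for Γ = {gamma} "
      f"(symmetric point Λ = Δ = {symmetric_point(gamma):.2f}):")
print("  lambda  delta")
for pair in amplification_curve(gamma, [2.0, 2.5, 3.0, 4.0, 6.0]):
    print(f"  {pair.lam:6.1f} {pair.delta:6.1f}")
print("Reading: each row is one hypothetical confounder strong enough to "
      "explain away a result that survives up to this Γ.")
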