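"""Amplification of the sensitivity parameter Γ.

A single Γ >= 1 summarizes how strongly an unmeasured confounder may bias
treatment assignment.  The amplification maps it to pairs (Λ, Δ) with
Λ, Δ > 1 satisfying

    Γ = (Λ Δ + 1) / (Λ + Δ),

where Λ multiplies the odds of treatment and Δ multiplies the odds of a
larger outcome.  For example Γ = 1.25 corresponds to a confounder that
doubles both (Λ = Δ = 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["AmplificationPair", "gamma_of", "delta_of", "amplification_curve"]


@dataclass(frozen=True)
class AmplificationPair:
    lam: float  # odds multiplier on treatment, > 1
    delta: float  # odds multiplier on the outcome, > 1

    def __post_init__(self) -> None:
        if self.lam <= 1 or self.delta <= 1:
            raise ValueError("amplification requires lambda > 1 and delta > 1")


def gamma_of(lam: float, delta: float) -> float:
    """Γ = (ΛΔ + 1)/(Λ + Δ); symmetric and increasing in each argument."""
    if lam <= 1 or delta <= 1:
        raise ValueError("amplification requires lambda > 1 and delta > 1")
    return (lam * delta + 1.0) / (lam + delta)


def delta_of(gamma: float, lam: float) -> float:
    """Solve the amplification identity for Δ: Δ = (ΓΛ - 1)/(Λ - Γ)."""
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    if lam <= gamma:
        raise ValueError("no finite amplification: need lambda > gamma")
    return (gamma * lam - 1.0) / (lam - gamma)


def amplification_curve(gamma: float, lambda_grid) -> list:
    """One (Λ, Δ) pair per grid value; each round-trips back to Γ."""
    pairs = []
    for lam in lambda_grid:
        delta = delta_of(gamma, lam)
        pairs.append(AmplificationPair(lam=float(lam), delta=delta))
    return pairs


def symmetric_point(gamma: float) -> float:
    """The Λ = Δ solution of the identity: Λ = Γ + sqrt(Γ² - 1)."""
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    return gamma + math.sqrt(gamma * gamma - 1.0)
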