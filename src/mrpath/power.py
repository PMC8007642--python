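"""Analytic power for two-sample MR with a binary outcome.

Uses the non-centrality-parameter approximation for the Wald test of the
causal log-odds ratio: with instrument variance explained R², outcome GWAS
size N and case fraction φ, the test statistic under the alternative effect
b (log-OR per SD of exposure) is approximately normal with mean
``sqrt(NCP) = sqrt(N · R² · φ(1−φ)) · |b|``, giving

    power = 1 − Φ(z_{1−α/2} − √NCP) + Φ(−z_{1−α/2} − √NCP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class PowerResult:
    alpha: float
    r2: float
    n_outcome: float
    case_fraction: float
    effect: float
    ncp: float
    power: float
    detectable_effect_80: float | None = None

    @property
    def detectable_or_80(self) -> float | None:
        return None if self.detectable_effect_80 is None else float(
            np.exp(self.detectable_effect_80)
        )

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "r2": self.r2,
            "n_outcome": self.n_outcome,
            "case_fraction": self.case_fraction,
            "effect": self.effect,
            "ncp": self.ncp,
            "power": self.power,
            "detectable_effect_80": self.detectable_effect_80,
            "detectable_or_80": self.detectable_or_80,
        }


def _validate(r2: float, n_outcome: float, case_fraction: float, alpha: float) -> None:
    if not (0.0 < r2 < 1.0):
        raise ValueError("r2 must lie in (0, 1)")
    if n_outcome <= 0:
        raise ValueError("n_outcome must be positive")
    if not (0.0 < case_fraction < 1.0):
        raise ValueError("case_fraction must lie in (0, 1)")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")


def ncp(r2: float, n_outcome: float, case_fraction: float, effect: float) -> float:
    """Non-centrality parameter N·R²·φ(1−φ)·b²."""
    return n_outcome * r2 * case_fraction * (1.0 - case_fraction) * effect**2


def power_at(ncp_value: float, alpha: float = 0.05) -> float:
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    s = np.sqrt(ncp_value)
    return float(stats.norm.sf(z - s) + stats.norm.cdf(-z - s))


def mr_power(
    r2: float,
    n_outcome: float,
    case_fraction: float,
    effect: float,
    alpha: float = 0.05,
    with_detectable: bool = True,
) -> PowerResult:
    """Power to detect a causal log-OR ``effect`` per SD of exposure."""
    _validate(r2, n_outcome, case_fraction, alpha)
    ncp_value = ncp(r2, n_outcome, case_fraction, effect)
    det = (
        detectable_effect(r2, n_outcome, case_fraction, 0.80, alpha)
        if with_detectable
        else None
    )
    return PowerResult(
        alpha=alpha,
        r2=r2,
        n_outcome=n_outcome,
        case_fraction=case_fraction,
        effect=effect,
        ncp=ncp_value,
        power=power_at(ncp_value, alpha),
        detectable_effect_80=det,
    )


def detectable_effect(
    r2: float,
    n_outcome: float,
    case_fraction: float,
    target_power: float = 0.80,
    alpha: float = 0.05,
) -> float:
    """Smallest positive log-OR detectable at ``target_power`` (bisection)."""
    _validate(r2, n_outcome, case_fraction, alpha)
    if target_power <= alpha:
        raise ValueError("target_power must exceed alpha")
    if target_power >= 1.0:
        raise ValueError("target_power must be below 1")

    def gap(effect: float) -> float:
        return power_at(ncp(r2, n_outcome, case_fraction, effect), alpha) - target_power

    hi = 0.1
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("detectable effect out of range")
    return float(optimize.bisect(gap, 0.0, hi, xtol=1e-8))


def power_table(
    r2: float,
    n_outcome: float,
    case_fraction: float,
    effects,
    alpha: float = 0.05,
):
    """Power over a grid of hypothesised effects (one row per effect)."""
    import pandas as pd

    rows = [
        mr_power(r2, n_outcome, case_fraction, e, alpha, with_detectable=False).to_dict()
        for e in np.asarray(effects, float)
    ]
    table = pd.DataFrame(rows).drop(columns=["detectable_effect_80", "detectable_or_80"])
    table["or"] = np.exp(table["effect"])
    return table
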