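"""Mediation decomposition of a total causal effect.

The difference method takes the total effect from univariable MR and the
direct effect from multivariable MR on the log-odds scale; the indirect
(mediated) effect is their difference and the proportion mediated is
``100 × (1 − direct/total)``.  The product (two-step) method multiplies the
exposure→mediator and mediator→outcome effects instead.  Uncertainty
intervals come from Monte-Carlo propagation of the input estimates'
sampling normals, optionally truncated to [0, 100]%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .estimators import MREstimate


class MediationError(ValueError):
    pass


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition with the proportion mediated (%)."""

    exposure_id: str
    mediator_id: str
    total: MREstimate
    direct: MREstimate | None
    indirect: float
    proportion_mediated: float
    ci_low: float
    ci_high: float
    method: str
    n_draws: int
    seed: int | None
    n_discarded: int = 0
    truncated: bool = True

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure_id,
            "mediator": self.mediator_id,
            "total_beta": self.total.beta,
            "direct_beta": self.direct.beta if self.direct is not None else None,
            "indirect_beta": self.indirect,
            "proportion_mediated_pct": self.proportion_mediated,
            "ci_low_pct": self.ci_low,
            "ci_high_pct": self.ci_high,
            "method": self.method,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "n_discarded": self.n_discarded,
        }

    def summary(self) -> str:
        return (
            f"Mediation {self.exposure_id} -> {self.mediator_id} -> "
            f"{self.total.outcome_id or 'outcome'} [{self.method}]: "
            f"{self.proportion_mediated:.1f}% "
            f"(95% CI {self.ci_low:.1f}, {self.ci_high:.1f})"
        )


def _interval(props: np.ndarray, truncate: bool) -> tuple[float, float]:
    lo, hi = np.percentile(props, [2.5, 97.5])
    if truncate:
        lo, hi = max(0.0, lo), min(100.0, hi)
    return float(lo), float(hi)


def proportion_mediated(
    total: MREstimate,
    direct: MREstimate,
    mediator_id: str = "",
    n_draws: int = 100000,
    seed: int | None = None,
    truncate: bool = True,
) -> MediationResult:
    """Difference-method proportion mediated, 100 × (total − direct)/total.

    ``total`` and ``direct`` must be on the same log-odds scale for the same
    exposure.  The interval propagates independent normal draws of the two
    estimates and takes the 2.5/97.5 percentiles of the proportion.
    """
    if total.beta == 0:
        raise MediationError("total effect is zero: proportion mediated undefined")
    if total.beta * direct.beta < 0:
        warnings.warn(
            "inconsistent mediation: total and direct effects have opposite "
            "signs; proportion reported regardless",
            stacklevel=2,
        )
    indirect = total.beta - direct.beta
    point = 100.0 * (1.0 - direct.beta / total.beta)

    rng = np.random.default_rng(seed)
    t = rng.normal(total.beta, total.se, n_draws)
    d = rng.normal(direct.beta, direct.se, n_draws)
    ok = np.abs(t) >= 1e-8
    props = 100.0 * (1.0 - d[ok] / t[ok])
    lo, hi = _interval(props, truncate)
    return MediationResult(
        exposure_id=total.exposure_id,
        mediator_id=mediator_id,
        total=total,
        direct=direct,
        indirect=indirect,
        proportion_mediated=point,
        ci_low=lo,
        ci_high=hi,
        method="difference",
        n_draws=n_draws,
        seed=seed,
        n_discarded=int(n_draws - ok.sum()),
        truncated=truncate,
    )


def two_step_network(
    exposure_to_mediator: MREstimate,
    mediator_to_outcome: MREstimate,
    total: MREstimate,
    mediator_id: str = "",
    n_draws: int = 100000,
    seed: int | None = None,
    truncate: bool = True,
) -> MediationResult:
    """Product-method (two-step network MR) proportion mediated.

    The indirect effect is the product of the exposure→mediator and
    mediator→outcome estimates; the proportion divides it by the total.
    """
    if total.beta == 0:
        raise MediationError("total effect is zero: proportion mediated undefined")
    indirect = exposure_to_mediator.beta * mediator_to_outcome.beta
    point = 100.0 * indirect / total.beta
    rng = np.random.default_rng(seed)
    a = rng.normal(exposure_to_mediator.beta, exposure_to_mediator.se, n_draws)
    b = rng.normal(mediator_to_outcome.beta, mediator_to_outcome.se, n_draws)
    t = rng.normal(total.beta, total.se, n_draws)
    ok = np.abs(t) >= 1e-8
    props = 100.0 * (a[ok] * b[ok]) / t[ok]
    lo, hi = _interval(props, truncate)
    return MediationResult(
        exposure_id=total.exposure_id,
        mediator_id=mediator_id or mediator_to_outcome.exposure_id,
        total=total,
        direct=None,
        indirect=indirect,
        proportion_mediated=point,
        ci_low=lo,
        ci_high=hi,
        method="product",
        n_draws=n_draws,
        seed=seed,
        n_discarded=int(n_draws - ok.sum()),
        truncated=truncate,
    )
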