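"""Pleiotropy and outlier diagnostics.

MR-PRESSO builds a residual-sum-of-squares global test by parametric
simulation: each variant's residual is measured against the IVW fit that
leaves it out, and the observed (weighted) RSS is ranked within RSS values
simulated from the per-variant sampling distributions under that
leave-one-out fit.  Per-variant outlier p-values are Bonferroni-adjusted.
The main-analysis rule removes a variant only when both MR-PRESSO and the
leave-one-out influence screen flag it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import EstimatorError, MREstimate, ivw
from .summary_io import HarmonisedSet


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    rss_observed: float
    global_pvalue: float
    per_variant_pvalues: pd.Series
    flagged: list[str]
    estimate_raw: MREstimate
    estimate_outlier_corrected: MREstimate | None
    distortion_pvalue: float | None
    n_simulations: int
    seed: int | None

    @property
    def resolution(self) -> float:
        """Smallest attainable Monte-Carlo p-value, 1/(n_simulations+1)."""
        return 1.0 / (self.n_simulations + 1)

    def to_dict(self) -> dict:
        return {
            "rss_observed": self.rss_observed,
            "global_pvalue": self.global_pvalue,
            "per_variant_pvalues": self.per_variant_pvalues.to_dict(),
            "flagged": list(self.flagged),
            "distortion_pvalue": self.distortion_pvalue,
            "n_simulations": self.n_simulations,
            "mc_resolution": self.resolution,
            "seed": self.seed,
            "estimate_raw": self.estimate_raw.to_dict(),
            "estimate_outlier_corrected": (
                self.estimate_outlier_corrected.to_dict()
                if self.estimate_outlier_corrected is not None
                else None
            ),
        }


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effects IVW slopes via sufficient-statistic updates."""
    sxx = np.sum(w * x * x)
    sxy = np.sum(w * x * y)
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso(
    h: HarmonisedSet,
    n_simulations: int = 10000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
    exposure_index: int = 0,
) -> PressoResult:
    """MR-PRESSO: global pleiotropy, per-variant outlier and distortion tests."""
    j = h.n_variants
    if j < 4:
        raise EstimatorError("MR-PRESSO needs at least 4 variants")
    x = h.exposure_betas[:, exposure_index]
    sx = h.exposure_ses[:, exposure_index]
    y = h.outcome_betas
    sy = h.outcome_ses
    w = 1.0 / sy**2

    loo = _loo_slopes(x, y, w)
    resid_obs = w * (y - loo * x) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    xs = rng.normal(x, sx, size=(n_simulations, j))
    ys = rng.normal(loo * x, sy, size=(n_simulations, j))
    sxx = np.sum(w * xs * xs, axis=1, keepdims=True)
    sxy = np.sum(w * xs * ys, axis=1, keepdims=True)
    loo_sim = (sxy - w * xs * ys) / (sxx - w * xs * xs)
    resid_sim = w * (ys - loo_sim * xs) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_simulations + 1))
    per_p = (1 + np.sum(resid_sim >= resid_obs[None, :], axis=0)) / (n_simulations + 1)
    per_adj = np.minimum(1.0, per_p * j)  # Bonferroni across variants
    flagged = [h.variant_ids[i] for i in np.flatnonzero(per_adj < outlier_alpha)]

    raw = ivw(h, "random", exposure_index)
    corrected = None
    distortion_p = None
    if flagged:
        keep = [v for v in h.variant_ids if v not in flagged]
        if len(keep) >= 2:
            h_corr = h.subset(keep)
            corrected = ivw(h_corr, "random", exposure_index)
            distortion_p = _distortion_test(
                h, flagged, raw.beta, corrected.beta, rng, n_simulations,
                exposure_index,
            )
    return PressoResult(
        rss_observed=rss_obs,
        global_pvalue=global_p,
        per_variant_pvalues=pd.Series(per_p, index=h.variant_ids),
        flagged=flagged,
        estimate_raw=raw,
        estimate_outlier_corrected=corrected,
        distortion_pvalue=distortion_p,
        n_simulations=n_simulations,
        seed=seed,
    )


def _distortion_test(h, flagged, beta_raw, beta_corr, rng, n_sim, exposure_index):
    """Null distribution of the distortion coefficient by resampling
    replacement variants from the non-flagged set."""
    keep_idx = [i for i, v in enumerate(h.variant_ids) if v not in flagged]
    n_out = len(flagged)
    x = h.exposure_betas[:, exposure_index]
    y = h.outcome_betas
    w = 1.0 / h.outcome_ses**2
    xk, yk, wk = x[keep_idx], y[keep_idx], w[keep_idx]
    sxx0, sxy0 = np.sum(wk * xk * xk), np.sum(wk * xk * yk)
    d_obs = (beta_raw - beta_corr) / abs(beta_corr)
    picks = rng.integers(0, len(keep_idx), size=(n_sim, n_out))
    sxx = sxx0 + np.sum(wk[picks] * xk[picks] ** 2, axis=1)
    sxy = sxy0 + np.sum(wk[picks] * xk[picks] * yk[picks], axis=1)
    beta_star = sxy / sxx
    d_null = (beta_star - beta_corr) / abs(beta_corr)
    return float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))


def leave_one_out(
    h: HarmonisedSet,
    exposure_index: int = 0,
    effects_model: str = "random",
) -> pd.DataFrame:
    """Re-estimate IVW omitting each variant in turn.

    The influence score is |full beta − leave-one-out beta| divided by the
    full fit's fixed-effects SE (the random-effects SE is itself inflated by
    an outlier's heterogeneity, which would mask exactly the variant being
    screened).  The table's ``attrs`` carry the full-set estimate and the
    most influential variant.
    """
    if h.n_variants < 3:
        raise EstimatorError("leave-one-out needs at least 3 variants")
    full = ivw(h, effects_model, exposure_index)
    full_fixed = ivw(h, "fixed", exposure_index)
    rows = []
    for v in h.variant_ids:
        est = ivw(h.without(v), effects_model, exposure_index)
        rows.append(
            {
                "omitted": v,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "influence": abs(full.beta - est.beta) / full_fixed.se,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["full_estimate"] = full
    table.attrs["max_influence_variant"] = table.loc[
        table["influence"].idxmax(), "omitted"
    ]
    return table


@dataclass
class OutlierDecision:
    """Audit record of the joint MR-PRESSO / leave-one-out removal rule."""

    removed: list[str]
    presso_flagged: list[str]
    high_influence: list[str]
    influence_threshold: float
    main_estimate: MREstimate
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "removed": self.removed,
            "presso_flagged": self.presso_flagged,
            "high_influence": self.high_influence,
            "influence_threshold": self.influence_threshold,
            "notes": self.notes,
            "main_estimate": self.main_estimate.to_dict(),
        }


def joint_outlier_rule(
    h: HarmonisedSet,
    presso: PressoResult,
    loo: pd.DataFrame,
    influence_threshold: float = 1.0,
    exposure_index: int = 0,
) -> OutlierDecision:
    """Remove a variant only when MR-PRESSO and leave-one-out both flag it.

    The main analysis is then the IVW estimate on the reduced set; a variant
    flagged by only one diagnostic is reported but retained.
    """
    high = set(loo.loc[loo["influence"] >= influence_threshold, "omitted"])
    flagged = set(presso.flagged)
    removed = sorted(flagged & high)
    notes = []
    only_presso = sorted(flagged - high)
    only_loo = sorted(high - flagged)
    if only_presso:
        notes.append(f"flagged by MR-PRESSO only (kept): {', '.join(only_presso)}")
    if only_loo:
        notes.append(f"high leave-one-out influence only (kept): {', '.join(only_loo)}")
    if removed:
        keep = [v for v in h.variant_ids if v not in removed]
        main = ivw(h.subset(keep), "random", exposure_index)
        notes.append(f"main analysis on {len(keep)} variants after removal")
    else:
        main = presso.estimate_raw
    return OutlierDecision(
        removed=removed,
        presso_flagged=sorted(flagged),
        high_influence=sorted(high),
        influence_threshold=influence_threshold,
        main_estimate=main,
        notes=notes,
    )
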