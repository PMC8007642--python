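"""Univariable two-sample Mendelian-randomisation estimators.

All estimators consume a :class:`~mrpath.summary_io.HarmonisedSet` and return
an :class:`MREstimate` whose ``beta`` is the causal log-odds ratio of the
outcome per SD change in the exposure.  The inverse-variance-weighted (IVW)
estimator is weighted regression of outcome betas on exposure betas through
the origin; MR-Egger adds an intercept whose deviation from zero indicates
directional pleiotropy (or an InSIDE violation); the weighted median is
consistent with up to 50% invalid weight, and the mode-based estimator with
a plurality of valid instruments.  When an LD correlation matrix accompanies
the set, IVW and Egger switch to generalised least squares with outcome-error
covariance ``Σ_jk = seY_j · seY_k · r_jk``.

Cochran's Q measures heterogeneity among the per-variant causal estimates;
the random-effects variants inflate standard errors multiplicatively by
``max(1, sqrt(Q/df))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, optimize

from .summary_io import HarmonisedSet

Z95 = 1.959964  # two-sided 95% normal quantile

HETEROGENEITY_ALPHA = 0.10


class EstimatorError(ValueError):
    pass


@dataclass
class MREstimate:
    """A causal-effect estimate with uncertainty and heterogeneity metrics."""

    method: str
    beta: float
    se: float
    n_snps: int
    exposure_id: str = ""
    outcome_id: str = ""
    q_statistic: float = float("nan")
    q_df: int = 0
    q_pvalue: float = float("nan")
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def pvalue(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.beta / self.se)))

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) on the odds-ratio scale."""
        return (np.exp(self.beta), np.exp(self.ci_low), np.exp(self.ci_high))

    @property
    def heterogeneous(self) -> bool:
        return (not np.isnan(self.q_pvalue)) and self.q_pvalue < HETEROGENEITY_ALPHA

    def to_dict(self) -> dict:
        o, lo, hi = self.or_scale
        d = {
            "method": self.method,
            "exposure": self.exposure_id,
            "outcome": self.outcome_id,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "or": o,
            "or_ci_low": lo,
            "or_ci_high": hi,
            "q_statistic": self.q_statistic,
            "q_df": self.q_df,
            "q_pvalue": self.q_pvalue,
        }
        if self.intercept is not None:
            d["intercept"] = self.intercept
            d["intercept_se"] = self.intercept_se
            d["intercept_pvalue"] = self.intercept_pvalue
        return d

    def summary(self) -> str:
        o, lo, hi = self.or_scale
        lines = [
            f"MR estimate [{self.method}] {self.exposure_id or 'exposure'} -> "
            f"{self.outcome_id or 'outcome'}",
            f"  n_snps = {self.n_snps}",
            f"  beta (log-OR/SD) = {self.beta:.4f}  se = {self.se:.4f}  "
            f"p = {self.pvalue:.3g}",
            f"  OR = {o:.3f} (95% CI {lo:.3f}, {hi:.3f})",
        ]
        if not np.isnan(self.q_statistic):
            lines.append(
                f"  Cochran Q = {self.q_statistic:.3f} (df {self.q_df}, "
                f"p = {self.q_pvalue:.3g})"
            )
        if self.intercept is not None:
            lines.append(
                f"  Egger intercept = {self.intercept:.4g} "
                f"(se {self.intercept_se:.4g}, p = {self.intercept_pvalue:.3g})"
            )
        return "\n".join(lines)


def _xy(h: HarmonisedSet, exposure_index: int = 0):
    x = h.exposure_betas[:, exposure_index].astype(float)
    sx = h.exposure_ses[:, exposure_index].astype(float)
    y = h.outcome_betas.astype(float)
    sy = h.outcome_ses.astype(float)
    return x, sx, y, sy


def ratio_estimates(h: HarmonisedSet, exposure_index: int = 0) -> pd.DataFrame:
    """Per-variant Wald ratios βY/βX with first-order SEs seY/|βX|."""
    x, _, y, sy = _xy(h, exposure_index)
    zero = x == 0
    if zero.any():
        bad = [h.variant_ids[i] for i in np.flatnonzero(zero)]
        raise EstimatorError(f"zero exposure beta for variant(s): {', '.join(bad)}")
    return pd.DataFrame(
        {
            "variant_id": h.variant_ids,
            "ratio": y / x,
            "se": sy / np.abs(x),
        }
    )


def _outcome_covariance(h: HarmonisedSet, signs: np.ndarray | None = None) -> np.ndarray | None:
    if h.ld is None:
        return None
    sy = h.outcome_ses
    r = h.ld.values
    if signs is not None:
        r = r * np.outer(signs, signs)
    return np.outer(sy, sy) * r


def _gls(design: np.ndarray, y: np.ndarray, sigma: np.ndarray):
    """Weighted/generalised LS: coefficients, covariance, residual Q."""
    try:
        si = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as exc:
        raise EstimatorError(
            "singular outcome covariance; prune correlated variants or "
            "regularise the LD matrix"
        ) from exc
    xtsi = design.T @ si
    cov = np.linalg.inv(xtsi @ design)
    coef = cov @ (xtsi @ y)
    resid = y - design @ coef
    q = float(resid @ si @ resid)
    return coef, cov, q


def ivw(
    h: HarmonisedSet,
    effects_model: str = "random",
    exposure_index: int = 0,
) -> MREstimate:
    """Inverse-variance-weighted estimate (fixed or multiplicative random effects)."""
    if effects_model not in ("fixed", "random"):
        raise ValueError("effects_model must be 'fixed' or 'random'")
    x, _, y, sy = _xy(h, exposure_index)
    j = h.n_variants
    notes: list[str] = []
    if j == 1:
        warnings.warn("single variant: IVW degenerates to the Wald ratio", stacklevel=2)
        beta = float(y[0] / x[0])
        se = float(sy[0] / abs(x[0]))
        return MREstimate(
            method=f"ivw_{effects_model}", beta=beta, se=se, n_snps=1,
            exposure_id=h.exposure_ids[exposure_index], outcome_id=h.outcome_id,
            q_statistic=0.0, q_df=0, q_pvalue=float("nan"),
            notes=["wald-ratio (single variant)"],
        )
    sigma = _outcome_covariance(h)
    design = x[:, None]
    if sigma is None:
        sigma = np.diag(sy**2)
    coef, cov, q = _gls(design, y, sigma)
    beta = float(coef[0])
    se_fixed = float(np.sqrt(cov[0, 0]))
    df = j - 1
    scale = max(1.0, np.sqrt(q / df)) if df > 0 else 1.0
    se = se_fixed * scale if effects_model == "random" else se_fixed
    return MREstimate(
        method=f"ivw_{effects_model}",
        beta=beta,
        se=se,
        n_snps=j,
        exposure_id=h.exposure_ids[exposure_index],
        outcome_id=h.outcome_id,
        q_statistic=q,
        q_df=df,
        q_pvalue=float(stats.chi2.sf(q, df)),
        notes=notes,
    )


def egger(h: HarmonisedSet, exposure_index: int = 0) -> MREstimate:
    """MR-Egger regression; the intercept tests for directional pleiotropy.

    Rows are flipped so all exposure betas are non-negative before fitting
    (the intercept is only interpretable under a fixed orientation).
    """
    x, _, y, sy = _xy(h, exposure_index)
    j = h.n_variants
    if j < 3:
        raise EstimatorError("MR-Egger needs at least 3 variants")
    signs = np.where(x < 0, -1.0, 1.0)
    xo, yo = x * signs, y * signs
    if np.allclose(xo, xo[0]):
        raise EstimatorError("exposure betas collinear with intercept after orientation")
    sigma = _outcome_covariance(h, signs)
    if sigma is None:
        sigma = np.diag(sy**2)
    design = np.column_stack([np.ones(j), xo])
    coef, cov, q = _gls(design, yo, sigma)
    df = j - 2
    scale = max(1.0, np.sqrt(q / df)) if df > 0 else 1.0
    slope_se = float(np.sqrt(cov[1, 1])) * scale
    int_se = float(np.sqrt(cov[0, 0])) * scale
    return MREstimate(
        method="egger",
        beta=float(coef[1]),
        se=slope_se,
        n_snps=j,
        exposure_id=h.exposure_ids[exposure_index],
        outcome_id=h.outcome_id,
        q_statistic=q,
        q_df=df,
        q_pvalue=float(stats.chi2.sf(q, df)),
        intercept=float(coef[0]),
        intercept_se=int_se,
        intercept_pvalue=float(2.0 * stats.norm.sf(abs(coef[0]) / int_se)),
    )


def _check_uncorrelated(h: HarmonisedSet, r2_threshold: float = 0.2) -> None:
    if h.ld is None:
        return
    r2 = h.ld.values**2
    np.fill_diagonal(r2, 0.0)
    i, k = np.unravel_index(np.argmax(r2), r2.shape)
    if r2[i, k] > r2_threshold:
        raise EstimatorError(
            f"variants {h.variant_ids[i]} and {h.variant_ids[k]} are in LD "
            f"(r2={r2[i, k]:.3g} > {r2_threshold:g}); prune before using this method"
        )


def _weighted_median_value(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation of the weighted empirical CDF."""
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, p, r))


def _parametric_draws(h, rng, n_boot, exposure_index):
    x, sx, y, sy = _xy(h, exposure_index)
    xs = rng.normal(x, sx, size=(n_boot, x.size))
    ys = rng.normal(y, sy, size=(n_boot, y.size))
    return xs, ys, sy


def weighted_median(
    h: HarmonisedSet,
    n_boot: int = 10000,
    seed: int | None = None,
    exposure_index: int = 0,
) -> MREstimate:
    """Weighted-median estimate; valid with up to half the weight on invalid SNPs.

    Requires near-independent variants (pairwise LD r² ≤ 0.2).  The SE comes
    from a parametric bootstrap drawing βX, βY from their sampling normals.
    """
    if h.n_variants < 3:
        raise EstimatorError("weighted median needs at least 3 variants")
    _check_uncorrelated(h)
    x, _, y, sy = _xy(h, exposure_index)
    ratios = y / x
    weights = x**2 / sy**2  # inverse first-order variance of the ratio
    beta = _weighted_median_value(ratios, weights)

    rng = np.random.default_rng(seed)
    xs, ys, _ = _parametric_draws(h, rng, n_boot, exposure_index)
    rb = ys / xs
    wb = xs**2 / sy**2
    order = np.argsort(rb, axis=1, kind="mergesort")
    rs = np.take_along_axis(rb, order, axis=1)
    ws = np.take_along_axis(wb, order, axis=1)
    ws = ws / ws.sum(axis=1, keepdims=True)
    p = np.cumsum(ws, axis=1) - 0.5 * ws
    boots = np.array([np.interp(0.5, p[i], rs[i]) for i in range(n_boot)])
    se = float(boots.std(ddof=1))
    return MREstimate(
        method="weighted_median",
        beta=beta,
        se=se,
        n_snps=h.n_variants,
        exposure_id=h.exposure_ids[exposure_index],
        outcome_id=h.outcome_id,
        notes=[f"bootstrap n={n_boot}, seed={seed}"],
    )


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """Modified Silverman bandwidth: 0.9·min(sd, mad/Φ⁻¹(0.75))·J^(−1/5), ×phi."""
    sd = np.std(ratios, ddof=1) if ratios.size > 1 else 0.0
    mad = np.median(np.abs(ratios - np.median(ratios))) / stats.norm.ppf(0.75)
    s = min(sd, mad) if mad > 0 else sd
    return phi * 0.9 * s * ratios.size ** (-0.2)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, bw: float) -> float:
    if bw <= 0:
        return float(ratios[np.argmax(weights)])
    w = weights / weights.sum()

    def negdens(b):
        return -np.sum(w * np.exp(-0.5 * ((b - ratios) / bw) ** 2))

    grid = np.linspace(ratios.min() - 2 * bw, ratios.max() + 2 * bw, 512)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / bw) ** 2)).sum(axis=1)
    g0 = grid[np.argmax(dens)]
    step = grid[1] - grid[0]
    res = optimize.minimize_scalar(negdens, bounds=(g0 - step, g0 + step), method="bounded")
    return float(res.x)


def mode_based(
    h: HarmonisedSet,
    phi: float = 1.0,
    weighted: bool = True,
    n_boot: int = 10000,
    seed: int | None = None,
    exposure_index: int = 0,
) -> MREstimate:
    """Mode-based estimate: the mode of the smoothed Wald-ratio density.

    Consistent when the largest group of instruments sharing one causal
    estimate is valid (ZEMPA).  ``phi`` scales the modified-Silverman
    bandwidth; ``weighted`` uses inverse-variance weights in the kernel
    density.
    """
    if h.n_variants < 3:
        raise EstimatorError("mode-based estimator needs at least 3 variants")
    x, _, y, sy = _xy(h, exposure_index)
    ratios = y / x
    se_r = sy / np.abs(x)
    weights = 1.0 / se_r**2 if weighted else np.ones_like(ratios)
    bw = _mode_bandwidth(ratios, phi)
    if bw <= 0:  # all ratios identical
        beta = float(ratios[0])
    else:
        beta = _kde_mode(ratios, weights, bw)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    chunk = max(1, 200000 // max(1, h.n_variants))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        xs, ys, _ = _parametric_draws(h, rng, m, exposure_index)
        rb = ys / xs
        wb = xs**2 / sy**2 if weighted else np.ones_like(rb)
        for i in range(m):
            bwi = _mode_bandwidth(rb[i], phi)
            boots[done + i] = _kde_mode(rb[i], wb[i], bwi) if bwi > 0 else rb[i][0]
        done += m
    se = float(np.std(boots, ddof=1))
    return MREstimate(
        method="weighted_mode" if weighted else "simple_mode",
        beta=beta,
        se=se,
        n_snps=h.n_variants,
        exposure_id=h.exposure_ids[exposure_index],
        outcome_id=h.outcome_id,
        notes=[f"phi={phi}, bootstrap n={n_boot}, seed={seed}"],
    )


def robust(h: HarmonisedSet, tuning: float = 4.685, exposure_index: int = 0) -> MREstimate:
    """MR-Robust: MM-type regression with Tukey's bisquare loss.

    Regresses βY/seY on βX/seY through the origin so that gross outliers are
    down-weighted smoothly to zero.  Fitting is iteratively reweighted least
    squares started from the IVW solution.
    """
    import statsmodels.api as sm

    if h.n_variants < 3:
        raise EstimatorError("MR-Robust needs at least 3 variants")
    x, _, y, sy = _xy(h, exposure_index)
    endog = y / sy
    exog = (x / sy)[:, None]
    model = sm.RLM(endog, exog, M=sm.robust.norms.TukeyBiweight(c=tuning))
    try:
        # OLS start on the weighted scale is exactly the fixed-effects IVW fit
        fit = model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # pragma: no cover - surfaced as estimator error
        raise EstimatorError(f"robust regression failed: {exc}") from exc
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    q, df, qp = cochran_q_values(h, beta, exposure_index=exposure_index)
    est = MREstimate(
        method="robust",
        beta=beta,
        se=se,
        n_snps=h.n_variants,
        exposure_id=h.exposure_ids[exposure_index],
        outcome_id=h.outcome_id,
        q_statistic=q,
        q_df=df,
        q_pvalue=qp,
        notes=[f"tukey c={tuning}"],
    )
    est.weights = np.asarray(fit.weights)  # IRLS weights, exposed for diagnostics
    return est


def cochran_q_values(
    h: HarmonisedSet,
    fitted_beta: float,
    intercept: float | None = None,
    exposure_index: int = 0,
):
    """Cochran's Q = Σ w_j (βY_j − a − β·βX_j)² with w_j = 1/seY_j².

    Pass ``intercept`` (even 0.0) only for an Egger-type fit; the degrees of
    freedom are J−2 with an intercept and J−1 without.
    """
    x, _, y, sy = _xy(h, exposure_index)
    df = h.n_variants - (1 if intercept is None else 2)
    if intercept is None:
        intercept = 0.0
    if df <= 0:
        raise EstimatorError("Cochran's Q needs positive degrees of freedom")
    w = 1.0 / sy**2
    q = float(np.sum(w * (y - intercept - fitted_beta * x) ** 2))
    return q, df, float(stats.chi2.sf(q, df))


def cochran_q(h: HarmonisedSet, fitted_beta: float, intercept: float | None = None,
              exposure_index: int = 0):
    """Heterogeneity test; p < 0.10 is conventionally flagged."""
    return cochran_q_values(h, fitted_beta, intercept, exposure_index)


_METHODS = {
    "ivw_fixed": lambda h, **kw: ivw(h, "fixed", **kw),
    "ivw_random": lambda h, **kw: ivw(h, "random", **kw),
    "egger": lambda h, **kw: egger(h, **kw),
    "weighted_median": weighted_median,
    "weighted_mode": lambda h, **kw: mode_based(h, weighted=True, **kw),
    "simple_mode": lambda h, **kw: mode_based(h, weighted=False, **kw),
    "robust": robust,
}


def estimate(h: HarmonisedSet, method: str, **kwargs) -> MREstimate:
    """Dispatch to a named estimator (see ``_METHODS`` keys)."""
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    return _METHODS[method](h, **kwargs)


def all_methods(h: HarmonisedSet, seed: int | None = None, n_boot: int = 2000) -> pd.DataFrame:
    """Run the full estimator suite, returning a tidy one-row-per-method table."""
    rows = []
    for name in ("ivw_random", "ivw_fixed", "egger", "weighted_median",
                 "weighted_mode", "simple_mode", "robust"):
        try:
            if name in ("weighted_median", "weighted_mode", "simple_mode"):
                est = estimate(h, name, n_boot=n_boot, seed=seed)
            else:
                est = estimate(h, name)
            rows.append(est.to_dict())
        except EstimatorError as exc:
            rows.append({"method": name, "error": str(exc)})
    return pd.DataFrame(rows)
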