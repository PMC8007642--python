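"""Multivariable MR: direct effects conditional on a second exposure.

The multivariable IVW estimator regresses outcome betas on the matrix of
exposure betas (no intercept) with weights 1/seY²; coefficient k is the
direct effect of exposure k holding the other exposures constant.  The
Egger variant adds an intercept after orienting rows to the first
exposure's sign.  Instruments are the union of each exposure's instrument
set, LD-pruned across the union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import Z95, EstimatorError, MREstimate
from .instruments import InstrumentSet
from .summary_io import HarmonisedSet, LDCorrelationMatrix, harmonise

CONDITION_NUMBER_LIMIT = 1e6


@dataclass
class MVMRResult:
    """Direct effects of several exposures fitted jointly."""

    exposure_ids: list[str]
    direct_estimates: list[MREstimate]
    q_statistic: float
    q_df: int
    q_pvalue: float
    n_snps: int
    model_label: str = ""
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pvalue: float | None = None
    condition_number: float = float("nan")
    se_scale: float = 1.0
    notes: list[str] = field(default_factory=list)

    def estimate_for(self, exposure_id: str) -> MREstimate:
        return self.direct_estimates[self.exposure_ids.index(exposure_id)]

    def to_frame(self) -> pd.DataFrame:
        rows = [e.to_dict() for e in self.direct_estimates]
        table = pd.DataFrame(rows)
        table.insert(0, "model", self.model_label)
        return table

    def summary(self) -> str:
        lines = [f"Multivariable MR {self.model_label or '/'.join(self.exposure_ids)}"]
        lines.append(f"  n_snps = {self.n_snps}, Q = {self.q_statistic:.3f} "
                     f"(df {self.q_df}, p = {self.q_pvalue:.3g})")
        for e in self.direct_estimates:
            o, lo, hi = e.or_scale
            lines.append(
                f"  {e.exposure_id}: beta = {e.beta:.4f} (se {e.se:.4f}), "
                f"OR = {o:.3f} ({lo:.3f}, {hi:.3f}), p = {e.pvalue:.3g}"
            )
        if self.egger_intercept is not None:
            lines.append(
                f"  intercept = {self.egger_intercept:.4g} "
                f"(p = {self.egger_intercept_pvalue:.3g})"
            )
        return "\n".join(lines)


def build_mvmr_set(
    instrument_sets: list[InstrumentSet],
    exposure_tables: list[pd.DataFrame],
    outcome_table: pd.DataFrame,
    ld: LDCorrelationMatrix | None = None,
    ld_r2_threshold: float = 0.2,
    palindrome_eaf_window: float = 0.08,
    exposure_ids: list[str] | None = None,
) -> HarmonisedSet:
    """Assemble the multi-exposure harmonised set for one MVMR model.

    Takes the union of instrument variants across the model's exposures,
    prunes pairs above the LD threshold keeping the member with the smaller
    discovery p, and requires association records (at any p) in every
    exposure table and the outcome.  Missing variants are dropped and
    logged, never zero-imputed.
    """
    discovery_p: dict[str, float] = {}
    for iset, table in zip(instrument_sets, exposure_tables):
        tab = table.set_index("variant_id")
        for v in iset.variant_ids:
            p = float(tab.loc[v, "p_value"])
            discovery_p[v] = min(p, discovery_p.get(v, 1.0))
    union = sorted(discovery_p, key=lambda v: (discovery_p[v], v))

    kept: list[str] = []
    pruned: list[tuple[str, str]] = []
    for v in union:
        clash = None
        if ld is not None and v in ld.variant_ids:
            for k in kept:
                if k in ld.variant_ids:
                    r = ld.r(v, k)
                    if r * r > ld_r2_threshold:
                        clash = (k, r * r)
                        break
        if clash is None:
            kept.append(v)
        else:
            pruned.append((v, f"union LD r2={clash[1]:.3g} with {clash[0]}"))

    sub_tables = []
    for table in exposure_tables:
        sub = table[table["variant_id"].isin(kept)]
        sub_tables.append(sub)
    h = harmonise(
        sub_tables,
        outcome_table,
        palindrome_eaf_window=palindrome_eaf_window,
        exposure_ids=exposure_ids
        or [s.exposure_id for s in instrument_sets],
        ld=ld.subset([v for v in kept if all(
            v in set(t["variant_id"]) for t in sub_tables + [outcome_table])])
        if ld is not None else None,
    )
    h.dropped.extend(pruned)
    n_missing = len(kept) - h.n_variants
    if n_missing > 0.2 * len(kept):
        import warnings

        warnings.warn(
            f"{n_missing}/{len(kept)} union variants dropped in harmonisation",
            stacklevel=2,
        )
    return h


def _check_rank(x: np.ndarray, exposure_ids: list[str]) -> float:
    cond = float(np.linalg.cond(x))
    if cond > CONDITION_NUMBER_LIMIT:
        worst, worst_r = None, 0.0
        for i, k in combinations(range(x.shape[1]), 2):
            r = abs(np.corrcoef(x[:, i], x[:, k])[0, 1])
            if r > worst_r:
                worst, worst_r = (exposure_ids[i], exposure_ids[k]), r
        raise EstimatorError(
            f"exposure beta matrix is rank-deficient (condition number "
            f"{cond:.3g}); most collinear pair {worst} with |r| = {worst_r:.2f}"
        )
    return cond


def _fit(h: HarmonisedSet, with_intercept: bool, model_label: str) -> MVMRResult:
    j = h.n_variants
    x_all = h.exposure_betas.copy()
    # an exposure with no instrument variation cannot be estimated; drop its
    # column so the fit reduces to the remaining exposures
    active = [idx for idx in range(h.n_exposures) if np.any(x_all[:, idx] != 0.0)]
    inactive = [idx for idx in range(h.n_exposures) if idx not in active]
    x = x_all[:, active]
    active_ids = [h.exposure_ids[i] for i in active]
    k = len(active)
    n_par = k + (1 if with_intercept else 0)
    if j <= n_par:
        raise EstimatorError(
            f"multivariable MR needs more variants ({j}) than parameters ({n_par})"
        )
    y = h.outcome_betas.copy()
    sy = h.outcome_ses
    if with_intercept:
        signs = np.where(x[:, 0] < 0, -1.0, 1.0)
        x = x * signs[:, None]
        y = y * signs
    cond = _check_rank(x, active_ids)
    design = np.column_stack([np.ones(j), x]) if with_intercept else x
    w = 1.0 / sy**2
    xtw = design.T * w
    cov = np.linalg.inv(xtw @ design)
    coef = cov @ (xtw @ y)
    resid = y - design @ coef
    q = float(np.sum(w * resid**2))
    df = j - n_par
    qp = float(stats.chi2.sf(q, df))
    scale = max(1.0, np.sqrt(q / df))

    offset = 1 if with_intercept else 0
    method = "mvmr_egger" if with_intercept else "mvmr_ivw"
    estimates = []
    pos = 0
    for idx, ex in enumerate(h.exposure_ids):
        if idx in inactive:
            estimates.append(
                MREstimate(
                    method=method, beta=float("nan"), se=float("nan"), n_snps=j,
                    exposure_id=ex, outcome_id=h.outcome_id,
                    notes=["no instrument variation; excluded from fit"],
                )
            )
            continue
        b = float(coef[offset + pos])
        se = float(np.sqrt(cov[offset + pos, offset + pos])) * scale
        pos += 1
        estimates.append(
            MREstimate(
                method=method,
                beta=b,
                se=se,
                n_snps=j,
                exposure_id=ex,
                outcome_id=h.outcome_id,
                q_statistic=q,
                q_df=df,
                q_pvalue=qp,
            )
        )
    res = MVMRResult(
        exposure_ids=list(h.exposure_ids),
        direct_estimates=estimates,
        q_statistic=q,
        q_df=df,
        q_pvalue=qp,
        n_snps=j,
        model_label=model_label,
        condition_number=cond,
        se_scale=float(scale),
    )
    if with_intercept:
        i_se = float(np.sqrt(cov[0, 0])) * scale
        res.egger_intercept = float(coef[0])
        res.egger_intercept_se = i_se
        res.egger_intercept_pvalue = float(2 * stats.norm.sf(abs(coef[0]) / i_se))
    return res


def mvmr_ivw(h: HarmonisedSet, model_label: str = "") -> MVMRResult:
    """Multivariable IVW: direct effect of each exposure, random-effects SEs."""
    return _fit(h, with_intercept=False, model_label=model_label)


def mvmr_egger(h: HarmonisedSet, model_label: str = "") -> MVMRResult:
    """Multivariable MR-Egger with rows oriented to the first exposure."""
    return _fit(h, with_intercept=True, model_label=model_label)


def beta_beta_correlation(
    exposure_tables: list[pd.DataFrame],
    variant_union: list[str],
    trait_ids: list[str] | None = None,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of per-variant effect sizes between traits.

    Computed pairwise-complete over ``variant_union``; pairs sharing fewer
    than ``min_shared`` variants are reported as missing.
    """
    if trait_ids is None:
        trait_ids = [
            t["trait_id"].iloc[0] if "trait_id" in t.columns else f"trait_{k}"
            for k, t in enumerate(exposure_tables)
        ]
    mat = pd.DataFrame(index=list(variant_union), columns=trait_ids, dtype=float)
    for tid, table in zip(trait_ids, exposure_tables):
        tab = table.set_index("variant_id")["beta"]
        shared = [v for v in variant_union if v in tab.index]
        mat.loc[shared, tid] = tab.loc[shared].astype(float)
    corr = mat.corr(method="pearson", min_periods=min_shared)
    np.fill_diagonal(corr.values, 1.0)
    return corr
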