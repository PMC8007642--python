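"""Instrument selection and strength: p-value thresholding, LD pruning, R², F.

The variance in the exposure explained by one variant is approximated by
``2 * EAF * (1 - EAF) * beta**2`` for a standardised trait, and the
instrument-level R² is the sum over retained variants.  Instrument strength
is summarised by ``F = R² (N - 2) / (1 - R²)``; F < 10 conventionally flags
a weak instrument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .summary_io import LDCorrelationMatrix

WEAK_INSTRUMENT_F = 10.0


class InstrumentSelectionError(ValueError):
    pass


def variance_explained(eaf, beta) -> float:
    """Per-variant variance explained, 2·EAF·(1−EAF)·β² (SD-unit trait)."""
    eaf = np.asarray(eaf, dtype=float)
    if np.any((eaf < 0) | (eaf > 1)):
        raise ValueError("eaf must lie in [0, 1]")
    return float(np.sum(2.0 * eaf * (1.0 - eaf) * np.asarray(beta, float) ** 2))


def f_statistic(r2: float, n: float) -> float:
    """Instrument F-statistic, R²(N−2)/(1−R²)."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must lie in [0, 1)")
    if n <= 2:
        raise ValueError("n must exceed 2")
    return r2 * (n - 2.0) / (1.0 - r2)


@dataclass
class InstrumentSet:
    """Variants instrumenting one exposure, with strength diagnostics."""

    exposure_id: str
    variant_ids: list[str]
    p_threshold: float
    ld_r2_threshold: float = 0.2
    r2_total: float = 0.0
    f_statistic: float = 0.0
    n_gwas: int = 0
    correlated_retained: bool = False
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def weak_instrument(self) -> bool:
        return self.f_statistic < WEAK_INSTRUMENT_F

    def to_json(self) -> str:
        d = asdict(self)
        d["weak_instrument"] = self.weak_instrument
        return json.dumps(d, indent=2)


def _prune(
    candidates: pd.DataFrame,
    ld: LDCorrelationMatrix | None,
    ld_r2_threshold: float,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Greedy ascending-p pruning; ties on p broken by lexicographic rsID."""
    order = candidates.sort_values(
        ["p_value", "variant_id"], kind="mergesort"
    )["variant_id"].tolist()
    if ld is None:
        return order, []
    kept: list[str] = []
    excluded: list[tuple[str, str]] = []
    for v in order:
        clash = None
        for k in kept:
            if v in ld.variant_ids and k in ld.variant_ids:
                r = ld.r(v, k)
                if r * r > ld_r2_threshold:
                    clash = (k, r * r)
                    break
        if clash is None:
            kept.append(v)
        else:
            excluded.append((v, f"LD r2={clash[1]:.3g} with {clash[0]}"))
    return kept, excluded


def select_instruments(
    table: pd.DataFrame,
    p_threshold: float,
    ld: LDCorrelationMatrix | None = None,
    ld_r2_threshold: float = 0.2,
    retain_correlated: bool = False,
    exposure_id: str | None = None,
) -> InstrumentSet:
    """Select instrument variants by p-value threshold and LD pruning.

    With ``retain_correlated`` the correlated variants are kept and the set is
    marked so downstream estimators use the LD correlation matrix (the design
    used when very few variants reach significance); pairwise pruning can
    still be applied separately for median/mode methods that require
    near-independent variants.
    """
    if exposure_id is None:
        exposure_id = table["trait_id"].iloc[0] if "trait_id" in table.columns else ""
    cand = table[table["p_value"] <= p_threshold]
    exclusions = [
        (v, f"p > {p_threshold:g}")
        for v in table.loc[table["p_value"] > p_threshold, "variant_id"]
    ]
    if cand.empty:
        raise InstrumentSelectionError(
            f"no variants pass p <= {p_threshold:g} for {exposure_id or 'exposure'}"
        )
    if retain_correlated or ld is None:
        kept = cand.sort_values(["p_value", "variant_id"], kind="mergesort")[
            "variant_id"
        ].tolist()
    else:
        kept, pruned = _prune(cand, ld, ld_r2_threshold)
        exclusions += pruned

    sub = cand.set_index("variant_id").loc[kept]
    eaf = sub["effect_allele_frequency"].to_numpy(dtype=float)
    beta = sub["beta"].to_numpy(dtype=float)
    r2 = variance_explained(eaf, beta) if not np.isnan(eaf).any() else float("nan")
    n_gwas = int(sub["n"].max()) if "n" in sub.columns else 0
    f = f_statistic(r2, n_gwas) if (n_gwas > 2 and not np.isnan(r2)) else float("nan")
    return InstrumentSet(
        exposure_id=exposure_id,
        variant_ids=kept,
        p_threshold=p_threshold,
        ld_r2_threshold=ld_r2_threshold,
        r2_total=r2,
        f_statistic=f,
        n_gwas=n_gwas,
        correlated_retained=bool(retain_correlated and ld is not None),
        exclusions=exclusions,
    )
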