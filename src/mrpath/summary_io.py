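"""Reading, validating and harmonising GWAS summary statistics.

Summary-statistics tables are tab-separated with a header row and the
canonical columns ``variant_id``, ``effect_allele``, ``other_allele``,
``effect_allele_frequency``, ``beta``, ``standard_error``, ``p_value``, ``n``
(a GWAS-SSF-like dialect).  Legacy headers can be mapped with ``column_map``.

Harmonisation aligns one or more exposure tables and an outcome table to a
single effect-allele orientation (the first exposure's), resolving strand
flips through allele complements and dropping palindromic variants whose
allele frequency is too close to 0.5 to orient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class SummaryDataError(ValueError):
    """A summary-statistics table violates its schema or invariants."""


class HarmonisationError(ValueError):
    """Exposure and outcome tables cannot be reconciled."""


CANONICAL_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
    "n",
]

_MANDATORY = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "beta",
    "standard_error",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is in SD units for a continuous trait or log-odds for a binary
    one; ``eaf`` is the effect-allele frequency.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int
    trait_id: str = ""

    def __post_init__(self) -> None:
        if self.effect_allele not in _ALLELES or self.other_allele not in _ALLELES:
            raise SummaryDataError(
                f"{self.variant_id}: alleles must be one of A/C/G/T, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise SummaryDataError(f"{self.variant_id}: identical alleles")
        if not (self.se > 0):
            raise SummaryDataError(f"{self.variant_id}: standard error must be > 0")
        if not np.isnan(self.eaf) and not (0.0 <= self.eaf <= 1.0):
            raise SummaryDataError(f"{self.variant_id}: eaf outside [0, 1]")
        if not (0.0 < self.pvalue <= 1.0):
            raise SummaryDataError(f"{self.variant_id}: p-value outside (0, 1]")


def _pvalue_from_z(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(np.asarray(beta) / np.asarray(se)))
    # survival function underflows to 0 around |z| ~ 38; keep p in (0, 1]
    return np.clip(p, 1e-300, 1.0)


def validate_summary_table(table: pd.DataFrame, trait_id: str = "") -> pd.DataFrame:
    """Validate a summary table against the VariantAssociation invariants.

    Returns the validated table (a copy, with a derived ``p_value`` column
    where it was missing).  Raises :class:`SummaryDataError` on hard
    violations; inconsistent p-values only trigger a warning.
    """
    missing = [c for c in _MANDATORY if c not in table.columns]
    if missing:
        raise SummaryDataError(f"missing mandatory column(s): {', '.join(missing)}")
    out = table.copy()
    if "effect_allele_frequency" not in out.columns:
        out["effect_allele_frequency"] = np.nan
    if "n" not in out.columns:
        out["n"] = 0

    dup = out["variant_id"].duplicated()
    if dup.any():
        dups = out.loc[dup, "variant_id"].unique().tolist()
        raise SummaryDataError(f"duplicate variant_id(s): {', '.join(map(str, dups))}")

    for col in ("beta", "standard_error", "effect_allele_frequency"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() & out[col].notna() & (col != "effect_allele_frequency")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SummaryDataError(f"unparseable numeric in column {col}, row {row + 2}")
        out[col] = vals

    out["effect_allele"] = out["effect_allele"].astype(str).str.upper()
    out["other_allele"] = out["other_allele"].astype(str).str.upper()

    bad_se = ~(out["standard_error"] > 0)
    if bad_se.any():
        row = int(np.flatnonzero(bad_se.to_numpy())[0])
        raise SummaryDataError(
            f"standard_error must be > 0 (row {row + 2}, "
            f"variant {out['variant_id'].iloc[row]})"
        )
    eaf = out["effect_allele_frequency"]
    bad_eaf = eaf.notna() & ((eaf < 0) | (eaf > 1))
    if bad_eaf.any():
        row = int(np.flatnonzero(bad_eaf.to_numpy())[0])
        raise SummaryDataError(f"effect_allele_frequency outside [0, 1] (row {row + 2})")
    same = out["effect_allele"] == out["other_allele"]
    if same.any():
        row = int(np.flatnonzero(same.to_numpy())[0])
        raise SummaryDataError(f"identical alleles (row {row + 2})")
    bad_allele = ~(
        out["effect_allele"].isin(list(_ALLELES))
        & out["other_allele"].isin(list(_ALLELES))
    )
    if bad_allele.any():
        row = int(np.flatnonzero(bad_allele.to_numpy())[0])
        raise SummaryDataError(f"allele not one of A/C/G/T (row {row + 2})")

    if "p_value" not in out.columns or out["p_value"].isna().all():
        out["p_value"] = _pvalue_from_z(out["beta"].to_numpy(), out["standard_error"].to_numpy())
        out["p_derived"] = True
    else:
        out["p_value"] = pd.to_numeric(out["p_value"], errors="coerce")
        derived = out["p_value"].isna()
        if derived.any():
            out.loc[derived, "p_value"] = _pvalue_from_z(
                out.loc[derived, "beta"].to_numpy(),
                out.loc[derived, "standard_error"].to_numpy(),
            )
        out["p_derived"] = derived
        # soft check: supplied p consistent with |beta/se| within a factor of 2
        with np.errstate(divide="ignore"):
            expect = _pvalue_from_z(out["beta"].to_numpy(), out["standard_error"].to_numpy())
        supplied = out["p_value"].to_numpy(dtype=float)
        ok = (supplied > 0) & (expect > 0)
        ratio = np.ones_like(supplied)
        ratio[ok] = supplied[ok] / expect[ok]
        off = ~derived.to_numpy() & ok & ((ratio > 2.0) | (ratio < 0.5)) & (expect > 1e-300)
        if off.any():
            ids = out["variant_id"].to_numpy()[off][:5]
            warnings.warn(
                f"{trait_id or 'table'}: p-value inconsistent with beta/se for "
                f"{off.sum()} variant(s) (e.g. {', '.join(map(str, ids))})",
                stacklevel=2,
            )
    bad_p = ~((out["p_value"] > 0) & (out["p_value"] <= 1))
    if bad_p.any():
        row = int(np.flatnonzero(bad_p.to_numpy())[0])
        raise SummaryDataError(f"p_value outside (0, 1] (row {row + 2})")

    if trait_id:
        out["trait_id"] = trait_id
    out["variant_id"] = out["variant_id"].astype(str)
    return out.reset_index(drop=True)


def read_summary_stats(
    path,
    trait_id: str = "",
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a tab-separated summary-statistics table.

    ``column_map`` maps file headers to canonical names, e.g.
    ``{"SNP": "variant_id"}``.
    """
    table = pd.read_csv(path, sep="\t", dtype={0: str})
    if column_map:
        table = table.rename(columns=column_map)
    unknown = [c for c in _MANDATORY if c not in table.columns]
    if unknown:
        raise SummaryDataError(
            f"{path}: missing mandatory column(s) after mapping: {', '.join(unknown)}"
        )
    return validate_summary_table(table, trait_id=trait_id)


def write_summary_stats(table: pd.DataFrame, path) -> None:
    """Write a summary table in the canonical TSV dialect."""
    cols = [c for c in CANONICAL_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.12g")


@dataclass
class LDCorrelationMatrix:
    """Signed LD correlations (r, not r²) between variants."""

    variant_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise SummaryDataError("LD matrix must be square")
        if v.shape[0] != len(self.variant_ids):
            raise SummaryDataError("LD matrix size does not match variant_ids")
        asym = np.max(np.abs(v - v.T)) if v.size else 0.0
        if asym > 1e-8:
            raise SummaryDataError(f"LD matrix asymmetric (max deviation {asym:.3g})")
        v = (v + v.T) / 2.0
        if v.size and np.max(np.abs(np.diag(v) - 1.0)) > 1e-8:
            raise SummaryDataError("LD matrix diagonal must be 1")
        np.fill_diagonal(v, 1.0)
        if np.any(np.abs(v) > 1.0 + 1e-12):
            raise SummaryDataError("LD correlations must lie in [-1, 1]")
        if v.size:
            w = np.linalg.eigvalsh(v)
            if w.min() < -1e-8:
                raise SummaryDataError(
                    f"LD matrix not positive semi-definite (min eigenvalue {w.min():.3g})"
                )
        self.values = v

    def r(self, id_a: str, id_b: str) -> float:
        i = self.variant_ids.index(id_a)
        j = self.variant_ids.index(id_b)
        return float(self.values[i, j])

    def subset(self, variant_ids: list[str]) -> "LDCorrelationMatrix":
        idx = [self.variant_ids.index(v) for v in variant_ids]
        return LDCorrelationMatrix(list(variant_ids), self.values[np.ix_(idx, idx)])


def read_ld_matrix(path) -> LDCorrelationMatrix:
    """Read a square TSV LD matrix whose first row/column hold rsIDs."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    ids_row = [str(c) for c in frame.columns]
    ids_col = [str(i) for i in frame.index]
    if ids_row != ids_col:
        raise SummaryDataError(f"{path}: row and column rsIDs differ")
    return LDCorrelationMatrix(ids_row, frame.to_numpy(dtype=float))


def write_ld_matrix(ld: LDCorrelationMatrix, path) -> None:
    pd.DataFrame(ld.values, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )


@dataclass
class HarmonisedSet:
    """Allele-aligned exposure and outcome effects for an instrument list.

    ``exposure_betas``/``exposure_ses`` are (variants x exposures) arrays in
    SD units; ``outcome_betas``/``outcome_ses`` are log-odds vectors.  All
    rows share the orientation of the first exposure's effect allele.
    """

    variant_ids: list[str]
    exposure_betas: np.ndarray
    exposure_ses: np.ndarray
    outcome_betas: np.ndarray
    outcome_ses: np.ndarray
    exposure_ids: list[str]
    outcome_id: str = "outcome"
    effect_alleles: list[str] = field(default_factory=list)
    other_alleles: list[str] = field(default_factory=list)
    eafs: np.ndarray | None = None
    exposure_pvalues: np.ndarray | None = None
    ld: LDCorrelationMatrix | None = None
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exposure_betas = np.atleast_2d(np.asarray(self.exposure_betas, float))
        if self.exposure_betas.shape[0] == 1 and len(self.variant_ids) > 1:
            self.exposure_betas = self.exposure_betas.T
        self.exposure_ses = np.atleast_2d(np.asarray(self.exposure_ses, float))
        if self.exposure_ses.shape[0] == 1 and len(self.variant_ids) > 1:
            self.exposure_ses = self.exposure_ses.T
        self.outcome_betas = np.asarray(self.outcome_betas, float).ravel()
        self.outcome_ses = np.asarray(self.outcome_ses, float).ravel()
        j = len(self.variant_ids)
        if self.exposure_betas.shape[0] != j or self.outcome_betas.shape[0] != j:
            raise SummaryDataError("harmonised arrays do not match variant_ids length")
        if self.ld is not None and list(self.ld.variant_ids) != list(self.variant_ids):
            raise SummaryDataError("ld.variant_ids must equal variant_ids in order")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return self.exposure_betas.shape[1]

    def subset(self, keep) -> "HarmonisedSet":
        """Restrict to a subset of variants (bool mask, indices or rsIDs)."""
        keep = list(keep)
        if keep and isinstance(keep[0], str):
            idx = [self.variant_ids.index(v) for v in keep]
        else:
            idx = list(np.arange(self.n_variants)[np.asarray(keep)]) if (
                keep and isinstance(keep[0], (bool, np.bool_))
            ) else [int(i) for i in keep]
        ids = [self.variant_ids[i] for i in idx]
        return HarmonisedSet(
            variant_ids=ids,
            exposure_betas=self.exposure_betas[idx, :],
            exposure_ses=self.exposure_ses[idx, :],
            outcome_betas=self.outcome_betas[idx],
            outcome_ses=self.outcome_ses[idx],
            exposure_ids=list(self.exposure_ids),
            outcome_id=self.outcome_id,
            effect_alleles=[self.effect_alleles[i] for i in idx] if self.effect_alleles else [],
            other_alleles=[self.other_alleles[i] for i in idx] if self.other_alleles else [],
            eafs=self.eafs[idx] if self.eafs is not None else None,
            exposure_pvalues=self.exposure_pvalues[idx, :] if self.exposure_pvalues is not None else None,
            ld=self.ld.subset(ids) if self.ld is not None else None,
            dropped=list(self.dropped),
        )

    def without(self, variant_id: str) -> "HarmonisedSet":
        return self.subset([v for v in self.variant_ids if v != variant_id])


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def _orient(ref_ea: str, ref_oa: str, ea: str, oa: str):
    """How to bring (ea, oa) onto the reference orientation.

    Returns +1 (same), -1 (flip beta, 1-eaf) or None (irreconcilable).
    Strand flips are resolved by complementing; for palindromic reference
    pairs complementing is a no-op, so allele letters alone suffice there.
    """
    if (ea, oa) == (ref_ea, ref_oa):
        return 1
    if (ea, oa) == (ref_oa, ref_ea):
        return -1
    cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
    if (cea, coa) == (ref_ea, ref_oa):
        return 1
    if (cea, coa) == (ref_oa, ref_ea):
        return -1
    return None


def harmonise(
    exposure_tables,
    outcome_table: pd.DataFrame,
    palindrome_eaf_window: float = 0.08,
    exposure_ids: list[str] | None = None,
    outcome_id: str = "outcome",
    ld: LDCorrelationMatrix | None = None,
) -> HarmonisedSet:
    """Align exposure(s) and outcome tables to one effect-allele orientation.

    The alignment target is the first exposure's effect allele.  Palindromic
    variants (A/T or C/G) whose exposure EAF lies within
    ``palindrome_eaf_window`` of 0.5 are dropped as unresolvable; palindromic
    variants with informative EAF are oriented by frequency concordance.
    """
    if isinstance(exposure_tables, pd.DataFrame):
        exposure_tables = [exposure_tables]
    exposure_tables = list(exposure_tables)
    if exposure_ids is None:
        exposure_ids = [
            t["trait_id"].iloc[0] if "trait_id" in t.columns else f"exposure_{k}"
            for k, t in enumerate(exposure_tables)
        ]
    tables = [t.set_index("variant_id", drop=False) for t in exposure_tables]
    out_t = outcome_table.set_index("variant_id", drop=False)

    ref = tables[0]
    dropped: list[tuple[str, str]] = []
    all_ids = list(ref.index)
    shared = [
        v for v in all_ids if all(v in t.index for t in tables[1:]) and v in out_t.index
    ]
    for v in all_ids:
        if v not in shared:
            dropped.append((v, "missing"))
    if not shared:
        raise HarmonisationError("no variants shared by all exposure and outcome tables")

    rows: list[dict] = []
    for v in shared:
        r = ref.loc[v]
        ea, oa = r["effect_allele"], r["other_allele"]
        eaf = float(r["effect_allele_frequency"])
        palin = _is_palindromic(ea, oa)
        if palin and (
            np.isnan(eaf)
            or any(
                np.isnan(float(t.loc[v, "effect_allele_frequency"]))
                for t in tables[1:] + [out_t]
            )
        ):
            # without a frequency the strand of a palindrome is unresolvable
            raise HarmonisationError(
                f"{v} is palindromic but has no allele frequency; cannot orient"
            )
        if palin and abs(eaf - 0.5) < palindrome_eaf_window:
            dropped.append((v, "palindromic-ambiguous"))
            continue

        rec = {
            "variant_id": v,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "x_beta": [float(r["beta"])],
            "x_se": [float(r["standard_error"])],
            "x_p": [float(r["p_value"])],
        }
        ok = True
        for t in tables[1:] + [out_t]:
            row = t.loc[v]
            sign = _orient(ea, oa, row["effect_allele"], row["other_allele"])
            if sign is None:
                dropped.append((v, "allele-mismatch"))
                warnings.warn(f"{v}: allele pair irreconcilable, dropped", stacklevel=2)
                ok = False
                break
            if palin:
                # letters cannot distinguish strands; use frequency concordance
                other_eaf = float(row["effect_allele_frequency"])
                eff_eaf = other_eaf if sign == 1 else 1.0 - other_eaf
                if abs(eff_eaf - 0.5) < palindrome_eaf_window:
                    dropped.append((v, "palindromic-ambiguous"))
                    ok = False
                    break
                if (eff_eaf - 0.5) * (eaf - 0.5) < 0:
                    sign = -sign
            beta = sign * float(row["beta"])
            if t is out_t:
                rec["y_beta"] = beta
                rec["y_se"] = float(row["standard_error"])
            else:
                rec["x_beta"].append(beta)
                rec["x_se"].append(float(row["standard_error"]))
                rec["x_p"].append(float(row["p_value"]))
        if ok:
            rows.append(rec)
    if not rows:
        raise HarmonisationError("harmonisation left no usable variants")

    ids = [r["variant_id"] for r in rows]
    hs = HarmonisedSet(
        variant_ids=ids,
        exposure_betas=np.array([r["x_beta"] for r in rows]),
        exposure_ses=np.array([r["x_se"] for r in rows]),
        outcome_betas=np.array([r["y_beta"] for r in rows]),
        outcome_ses=np.array([r["y_se"] for r in rows]),
        exposure_ids=list(exposure_ids),
        outcome_id=outcome_id,
        effect_alleles=[r["effect_allele"] for r in rows],
        other_alleles=[r["other_allele"] for r in rows],
        eafs=np.array([r["eaf"] for r in rows]),
        exposure_pvalues=np.array([r["x_p"] for r in rows]),
        ld=ld.subset(ids) if ld is not None else None,
        dropped=dropped,
    )
    return hs
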