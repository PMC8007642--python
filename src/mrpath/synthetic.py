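"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator works directly at the summary level: for each instrument
variant a true effect on the exposure is drawn and scaled so the instrument
explains a requested share of exposure variance, and observed betas are the
true betas plus normal estimation noise with the analytic standard error of
a per-variant GWAS regression (``1/sqrt(2·EAF(1−EAF)·N)`` for a standardised
continuous trait, with an extra ``φ(1−φ)`` factor for the binary outcome's
log-odds scale).  The causal structure is

    exposure --(theta_direct)--> outcome
    exposure --(kappa)--> mediator --(theta_mediator)--> outcome

so the total effect is ``theta_direct + kappa·theta_mediator`` and the true
mediated proportion is ``kappa·theta_mediator / theta_total``.  Optional
per-variant pleiotropic effects (balanced, directional, or correlated with
instrument strength to violate InSIDE), LD blocks inducing correlated
estimation noise, and exposure/outcome sample overlap are supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .summary_io import LDCorrelationMatrix, validate_summary_table

_PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating")

# non-complementary allele pairs, so strand ambiguity never destroys variants
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass
class SyntheticTruth:
    """Generating parameters for one synthetic two-sample MR study."""

    theta_direct: float = -0.36
    kappa: float = 0.3
    theta_mediator: float = -0.5
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    j_snps: int = 5
    instrument_r2: float = 0.002
    j_mediator_snps: int = 0
    mediator_r2: float = 0.0
    n_exposure: int = 91105
    n_mediator: int = 322154
    n_outcome: int = 92967
    case_fraction: float = 31197 / 92967
    ld_block_r: float = 0.0
    ld_block_size: int = 1
    overlap_fraction: float = 0.0
    flip_fraction: float = 0.0
    seed: int = 0
    exposure_id: str = "exposure"
    mediator_id: str = "mediator"
    outcome_id: str = "outcome"

    def __post_init__(self) -> None:
        if self.pleiotropy_mode not in _PLEIOTROPY_MODES:
            raise ValueError(f"pleiotropy_mode must be one of {_PLEIOTROPY_MODES}")
        if not (0.0 < self.instrument_r2 < 0.5):
            raise ValueError("instrument_r2 must lie in (0, 0.5)")
        if self.j_snps < 1:
            raise ValueError("j_snps must be positive")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must lie in (0, 1)")

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.kappa * self.theta_mediator

    @property
    def proportion_mediated(self) -> float:
        if self.theta_total == 0:
            return float("nan")
        return self.kappa * self.theta_mediator / self.theta_total

    def to_dict(self) -> dict:
        d = asdict(self)
        d["theta_total"] = self.theta_total
        d["proportion_mediated"] = self.proportion_mediated
        return d


@dataclass
class SyntheticDataset:
    """Exposure, mediator and outcome summary tables sharing variants."""

    exposure_table: pd.DataFrame
    mediator_table: pd.DataFrame
    outcome_table: pd.DataFrame
    ld: LDCorrelationMatrix
    truth: SyntheticTruth
    true_gammas: np.ndarray = field(default=None, repr=False)

    @property
    def instrument_ids(self) -> list[str]:
        """The exposure's instrument variants (the study's discovered SNPs)."""
        return list(self.exposure_table["variant_id"].iloc[: self.truth.j_snps])

    @property
    def mediator_instrument_ids(self) -> list[str]:
        return list(
            self.mediator_table["variant_id"].iloc[self.truth.j_snps:]
        )

    def exposure_instruments(self) -> pd.DataFrame:
        return self.exposure_table[
            self.exposure_table["variant_id"].isin(self.instrument_ids)
        ]


def _block_correlation(j: int, r: float, size: int) -> np.ndarray:
    mat = np.eye(j)
    if size > 1 and r != 0.0:
        for start in range(0, j, size):
            stop = min(start + size, j)
            mat[start:stop, start:stop] = r
            np.fill_diagonal(mat[start:stop, start:stop], 1.0)
    return mat


def _correlated_noise(rng, corr_chol: np.ndarray, n: int = 1) -> np.ndarray:
    z = rng.standard_normal(corr_chol.shape[0])
    return corr_chol @ z


def _table(ids, eas, oas, eaf, beta, se, n, trait_id) -> pd.DataFrame:
    table = pd.DataFrame(
        {
            "variant_id": ids,
            "effect_allele": eas,
            "other_allele": oas,
            "effect_allele_frequency": eaf,
            "beta": beta,
            "standard_error": se,
            "n": n,
        }
    )
    return validate_summary_table(table, trait_id=trait_id)


def generate(truth: SyntheticTruth) -> SyntheticDataset:
    """Draw one synthetic dataset from the generating model in ``truth``."""
    rng = np.random.default_rng(truth.seed)
    j = truth.j_snps
    jm = truth.j_mediator_snps
    n_var = j + jm

    eaf = rng.uniform(0.05, 0.5, size=n_var)
    het = 2.0 * eaf * (1.0 - eaf)

    raw = rng.standard_normal(j)
    denom = float(np.sum(het[:j] * raw**2))
    if denom <= 0:
        raise RuntimeError("degenerate instrument draw")
    gamma = np.zeros(n_var)
    gamma[:j] = raw * math.sqrt(truth.instrument_r2 / denom)
    # sum(2 eaf (1-eaf) gamma^2) == instrument_r2 exactly by construction

    # mediator-specific instruments: no effect on the exposure, so the
    # multivariable design is identified (as with real adiposity GWAS hits)
    gamma_m = np.zeros(n_var)
    if jm > 0 and truth.mediator_r2 > 0:
        raw_m = rng.standard_normal(jm)
        denom_m = float(np.sum(het[j:] * raw_m**2))
        gamma_m[j:] = raw_m * math.sqrt(truth.mediator_r2 / denom_m)

    se_x = 1.0 / np.sqrt(het * truth.n_exposure)
    se_m = 1.0 / np.sqrt(het * truth.n_mediator)
    phi = truth.case_fraction
    se_y = 1.0 / np.sqrt(het * truth.n_outcome * phi * (1.0 - phi))

    alpha = np.zeros(n_var)
    if truth.pleiotropy_mode != "none" and truth.pleiotropy_sd > 0.0:
        if truth.pleiotropy_mode == "balanced":
            alpha[:j] = rng.normal(0.0, truth.pleiotropy_sd, j)
        elif truth.pleiotropy_mode == "directional":
            # directional relative to the exposure-increasing orientation of
            # each variant (the frame in which Egger's intercept is defined)
            alpha[:j] = np.sign(gamma[:j]) * rng.normal(
                truth.pleiotropy_sd, truth.pleiotropy_sd / 2.0, j
            )
        else:  # inside_violating: pleiotropy correlated with instrument strength
            g_std = gamma[:j] / max(np.std(gamma[:j]), 1e-12)
            alpha[:j] = truth.pleiotropy_sd * g_std + rng.normal(
                0.0, truth.pleiotropy_sd / 2.0, j
            )

    true_x = gamma
    true_m = truth.kappa * gamma + gamma_m
    true_y = truth.theta_total * gamma + truth.theta_mediator * gamma_m + alpha

    corr = _block_correlation(n_var, truth.ld_block_r, truth.ld_block_size)
    chol = np.linalg.cholesky(corr)
    zx = chol @ rng.standard_normal(n_var)
    zm = chol @ rng.standard_normal(n_var)
    zy_ind = chol @ rng.standard_normal(n_var)
    of = truth.overlap_fraction
    zy = of * zx + math.sqrt(max(0.0, 1.0 - of**2)) * zy_ind

    beta_x = true_x + se_x * zx
    beta_m = true_m + se_m * zm
    beta_y = true_y + se_y * zy

    ids = [f"rs{100000 + i}" for i in range(n_var)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_var)
    eas = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oas = [_ALLELE_PAIRS[i][1] for i in pair_idx]

    exposure = _table(ids, eas, oas, eaf, beta_x, se_x, truth.n_exposure,
                      truth.exposure_id)
    mediator = _table(ids, eas, oas, eaf, beta_m, se_m, truth.n_mediator,
                      truth.mediator_id)

    # optionally mis-orient some outcome rows to exercise harmonisation
    out_eas, out_oas = list(eas), list(oas)
    out_eaf, out_beta = eaf.copy(), beta_y.copy()
    if truth.flip_fraction > 0:
        flip = rng.random(n_var) < truth.flip_fraction
        for i in np.flatnonzero(flip):
            out_eas[i], out_oas[i] = out_oas[i], out_eas[i]
            out_eaf[i] = 1.0 - out_eaf[i]
            out_beta[i] = -out_beta[i]
    outcome = _table(ids, out_eas, out_oas, out_eaf, out_beta, se_y,
                     truth.n_outcome, truth.outcome_id)

    ld = LDCorrelationMatrix(ids, corr)
    return SyntheticDataset(
        exposure_table=exposure,
        mediator_table=mediator,
        outcome_table=outcome,
        ld=ld,
        truth=truth,
        true_gammas=gamma,
    )


_SCENARIOS = {
    # instrument counts, variance explained and GWAS sizes of the three
    # physical-activity exposures; outcome is the colorectal-cancer GWAS
    # meta-analysis (31,197 cases / 61,770 controls)
    "mvpa": {"j_snps": 7, "n_exposure": 385790, "instrument_r2": 0.0007,
             "theta_total": math.log(0.56), "proportion_mediated": 0.02,
             "exposure_id": "MVPA"},
    "ampa": {"j_snps": 5, "n_exposure": 91105, "instrument_r2": 0.002,
             "theta_total": math.log(0.60), "proportion_mediated": 0.32,
             "exposure_id": "AMPA"},
    "sedentary": {"j_snps": 6, "n_exposure": 91105, "instrument_r2": 0.001,
                  "theta_total": 0.0, "proportion_mediated": 0.0,
                  "exposure_id": "sedentary_time"},
}


def study_scenario(
    name: str,
    theta_total: float | None = None,
    proportion_mediated: float | None = None,
    kappa: float = 0.3,
    seed: int = 0,
    **overrides,
) -> SyntheticTruth:
    """Truth presets matching the study's instrument counts and sample sizes.

    ``theta_total`` (log-OR per SD) and the mediated proportion can be
    overridden; the decomposition uses a fixed exposure→mediator effect
    ``kappa`` and solves for the mediator→outcome effect.
    """
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    preset = dict(_SCENARIOS[name])
    tt = preset.pop("theta_total") if theta_total is None else theta_total
    prop = (
        preset.pop("proportion_mediated")
        if proportion_mediated is None
        else proportion_mediated
    )
    preset.pop("proportion_mediated", None)
    preset.pop("theta_total", None)
    if tt == 0.0:
        theta_mediator, theta_direct = 0.0, 0.0
    else:
        theta_mediator = prop * tt / kappa
        theta_direct = (1.0 - prop) * tt
    params = dict(
        theta_direct=theta_direct,
        kappa=kappa,
        theta_mediator=theta_mediator,
        # BMI-shaped mediator instrument set (68 SNPs, R2=0.0232, N=322,154)
        j_mediator_snps=68,
        mediator_r2=0.0232,
        n_mediator=322154,
        n_outcome=92967,
        case_fraction=31197 / 92967,
        mediator_id="BMI",
        outcome_id="CRC",
        seed=seed,
        **preset,
    )
    params.update(overrides)
    return SyntheticTruth(**params)
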