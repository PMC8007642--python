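"""Model-style front end: build a model from data, ``fit()`` for results.

:class:`MRModel` wraps a harmonised single-exposure set and dispatches to
the univariable estimators; :class:`MVMRModel` does the same for the
multivariable direct-effect regression.  Both return results objects
(:class:`~mrpath.estimators.MREstimate`, :class:`~mrpath.mvmr.MVMRResult`)
carrying estimates, uncertainties, heterogeneity diagnostics and
``summary()`` tables.
"""

from __future__ import annotations

import pandas as pd

from . import estimators, mvmr as _mvmr, sensitivity
from .estimators import MREstimate
from .mvmr import MVMRResult
from .summary_io import HarmonisedSet, LDCorrelationMatrix, harmonise


class MRModel:
    """Univariable two-sample MR model for one exposure and one outcome."""

    def __init__(self, harmonised: HarmonisedSet, exposure_index: int = 0):
        self.data = harmonised
        self.exposure_index = exposure_index

    @classmethod
    def from_tables(
        cls,
        exposure_table: pd.DataFrame,
        outcome_table: pd.DataFrame,
        ld: LDCorrelationMatrix | None = None,
        palindrome_eaf_window: float = 0.08,
    ) -> "MRModel":
        h = harmonise(
            [exposure_table],
            outcome_table,
            palindrome_eaf_window=palindrome_eaf_window,
            ld=ld,
        )
        return cls(h)

    @property
    def exposure_id(self) -> str:
        return self.data.exposure_ids[self.exposure_index]

    def fit(self, method: str = "ivw_random", **kwargs) -> MREstimate:
        return estimators.estimate(
            self.data, method, exposure_index=self.exposure_index, **kwargs
        )

    def fit_all(self, seed: int | None = None, n_boot: int = 2000) -> pd.DataFrame:
        return estimators.all_methods(self.data, seed=seed, n_boot=n_boot)

    def ratio_estimates(self) -> pd.DataFrame:
        return estimators.ratio_estimates(self.data, self.exposure_index)

    def leave_one_out(self, effects_model: str = "random") -> pd.DataFrame:
        return sensitivity.leave_one_out(self.data, self.exposure_index, effects_model)

    def presso(self, n_simulations: int = 10000, outlier_alpha: float = 0.05,
               seed: int | None = None) -> sensitivity.PressoResult:
        return sensitivity.mr_presso(
            self.data, n_simulations, outlier_alpha, seed, self.exposure_index
        )

    def outlier_decision(
        self,
        n_simulations: int = 10000,
        influence_threshold: float = 1.0,
        seed: int | None = None,
    ) -> sensitivity.OutlierDecision:
        presso = self.presso(n_simulations=n_simulations, seed=seed)
        loo = self.leave_one_out()
        return sensitivity.joint_outlier_rule(
            self.data, presso, loo, influence_threshold, self.exposure_index
        )


class MVMRModel:
    """Multivariable MR model: joint direct effects of several exposures."""

    def __init__(self, harmonised: HarmonisedSet, model_label: str = ""):
        if harmonised.n_exposures < 2:
            raise ValueError("MVMRModel needs at least two exposure columns")
        self.data = harmonised
        self.model_label = model_label

    @classmethod
    def from_tables(
        cls,
        instrument_sets,
        exposure_tables,
        outcome_table,
        ld: LDCorrelationMatrix | None = None,
        model_label: str = "",
        **kwargs,
    ) -> "MVMRModel":
        h = _mvmr.build_mvmr_set(
            instrument_sets, exposure_tables, outcome_table, ld=ld, **kwargs
        )
        return cls(h, model_label=model_label)

    def fit(self, method: str = "ivw") -> MVMRResult:
        if method == "ivw":
            return _mvmr.mvmr_ivw(self.data, model_label=self.model_label)
        if method == "egger":
            return _mvmr.mvmr_egger(self.data, model_label=self.model_label)
        raise ValueError("method must be 'ivw' or 'egger'")
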