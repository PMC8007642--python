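import numpy as np
import pandas as pd
import pytest

from mrpath.summary_io import HarmonisedSet, LDCorrelationMatrix


def make_harmonised(x, y, sy, sx=None, ld=None, ids=None, exposure_id="X",
                    outcome_id="Y"):
    """Assemble a single-exposure HarmonisedSet from plain arrays."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sy = np.asarray(sy, float)
    sx = np.full_like(x, 1e-6) if sx is None else np.asarray(sx, float)
    ids = ids or [f"rs{i+1}" for i in range(x.size)]
    ld_obj = None
    if ld is not None:
        ld_obj = ld if isinstance(ld, LDCorrelationMatrix) else LDCorrelationMatrix(
            list(ids), np.asarray(ld, float)
        )
    return HarmonisedSet(
        variant_ids=list(ids),
        exposure_betas=x[:, None],
        exposure_ses=sx[:, None],
        outcome_betas=y,
        outcome_ses=sy,
        exposure_ids=[exposure_id],
        outcome_id=outcome_id,
        ld=ld_obj,
    )


def make_table(variant_ids, betas, ses, eafs=None, ea=None, oa=None,
               pvals=None, n=100000, trait_id="trait"):
    """Build a validated summary-statistics DataFrame from plain lists."""
    from mrpath.summary_io import validate_summary_table

    j = len(variant_ids)
    table = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "effect_allele": ea or ["A"] * j,
            "other_allele": oa or ["G"] * j,
            "effect_allele_frequency": eafs if eafs is not None else [0.3] * j,
            "beta": betas,
            "standard_error": ses,
            "n": n,
        }
    )
    if pvals is not None:
        table["p_value"] = pvals
    return validate_summary_table(table, trait_id=trait_id)


@pytest.fixture
def toy_harmonised():
    # 3-SNP toy with equal outcome SEs; exact IVW slope is 0.507142857...
    return make_harmonised(
        x=[0.1, 0.2, 0.3], y=[0.05, 0.12, 0.14], sy=[0.01, 0.01, 0.01]
    )


@pytest.fixture
def ampa_dataset():
    from mrpath.synthetic import generate, study_scenario

    return generate(study_scenario("ampa", seed=11))
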