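import numpy as np
import pandas as pd
import pytest

from circashift.glm import FittedGLM, ModelSpec
from circashift.preprocess import ColumnRecipe, TransformRecipe
from circashift.synthetic import generate_descriptive, generate_model_mode, refit_planted


@pytest.fixture(scope="session")
def cohort():
    """Descriptive-mode cohort at the published calibration (n=288)."""
    table, _ = generate_descriptive(n=288, seed=42)
    return table


@pytest.fixture(scope="session")
def planted_fits():
    """PSQI and PHQ-9 models refitted on model-mode cohorts (known truth)."""
    tab_p, _ = generate_model_mode(outcome="psqi", n=600, seed=11)
    tab_d, _ = generate_model_mode(outcome="phq9", n=600, seed=12)
    return refit_planted(tab_p, "psqi"), refit_planted(tab_d, "phq9")


def make_affine_fit(outcome: str, dynamic: str, intercept: float,
                    slope: float) -> FittedGLM:
    """Hand-built Gaussian-identity fit: prediction = intercept + slope * raw.

    The recipe is the identity (Yeo-Johnson lambda 1, mean 0, SD 1), so the
    coupled simulation reduces to an exactly analysable affine recursion.
    """
    spec = ModelSpec(outcome=outcome, mains=(dynamic,), interactions=(),
                     moderator=dynamic, family="gaussian")
    recipe = TransformRecipe(columns={dynamic: ColumnRecipe(
        fence_lo=-1e9, fence_hi=1e9, impute_value=0.0,
        lmbda=1.0, mean=0.0, sd=1.0)})
    params = pd.DataFrame({"term": ["intercept", dynamic],
                           "beta": [intercept, slope]})
    return FittedGLM(spec=spec, params=params, llf=0.0, aic=0.0, bic=0.0,
                     pseudo_r2=0.0, vif=pd.Series(dtype=float),
                     recipe=recipe, n=0, k=2)
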