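import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from herbtox.dose_response import ResponseModel, effect_at
from herbtox.mixture import HerbicideCurveDB
from herbtox.synthetic import default_curve_db


@pytest.fixture(scope="session")
def logistic_unit() -> ResponseModel:
    """Logistic curve with midpoint at 10 nmol/L and unit slope."""
    return ResponseModel("logistic", 1.0, -1.0, 1.0)


@pytest.fixture(scope="session")
def weibull_unit() -> ResponseModel:
    return ResponseModel("weibull", 1.0, 0.0, 1.0)


@pytest.fixture(scope="session")
def curve_db() -> HerbicideCurveDB:
    return default_curve_db()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240227)


def dense_responses(model, concentrations):
    """Noise-free responses from a truth curve (helper for recovery tests)."""
    return effect_at(model, np.asarray(concentrations, dtype=float))
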