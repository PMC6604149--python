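import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tivadjust import CohortTable, default_atlas, default_spec, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


def make_cohort(
    tiv_f, tiv_m, voi_values: dict[str, list[float]], atlas=None, covariates=None
) -> CohortTable:
    """Hand-build a small cohort; VOI value lists follow F-then-M row order."""
    n_f, n_m = len(tiv_f), len(tiv_m)
    df = pd.DataFrame(
        {
            "subject_id": [f"f{i}" for i in range(n_f)] + [f"m{i}" for i in range(n_m)],
            "group": ["F"] * n_f + ["M"] * n_m,
            "tiv": list(tiv_f) + list(tiv_m),
        }
    )
    for voi, values in voi_values.items():
        df[voi] = values
    for name, values in (covariates or {}).items():
        df[name] = values
    return CohortTable(data=df, atlas=atlas if atlas is not None else default_atlas())


@pytest.fixture()
def toy_cohort(atlas):
    """Six subjects, two regions, plausible ml volumes."""
    return make_cohort(
        tiv_f=[1450.0, 1500.0, 1480.0],
        tiv_m=[1600.0, 1650.0, 1580.0],
        voi_values={
            "Amygdala_L": [1.51, 1.62, 1.55, 1.78, 1.81, 1.70],
            "Amygdala_R": [1.62, 1.71, 1.66, 1.92, 1.97, 1.85],
        },
        atlas=atlas,
    )


@pytest.fixture(scope="session")
def null_cohort(atlas):
    """Default-calibration cohort with TIV scaling only (no true effects)."""
    spec = default_spec("null_scaling", seed=11)
    cohort, report = generate_cohort(spec, atlas)
    return cohort, report, spec


@pytest.fixture(scope="session")
def effects_cohort(atlas):
    """Default-calibration cohort with 19 seeded group effects."""
    spec = default_spec("with_effects", seed=13)
    cohort, report = generate_cohort(spec, atlas)
    return cohort, report, spec


def random_cohort(rng: np.random.Generator, n_f=5, n_m=5, n_voi=3, atlas=None) -> CohortTable:
    """Small random cohort for closed-form oracle checks."""
    atlas = atlas if atlas is not None else default_atlas()
    names = atlas.names[:n_voi]
    tiv_f = rng.uniform(1300, 1600, size=n_f)
    tiv_m = rng.uniform(1400, 1750, size=n_m)
    tiv = np.concatenate([tiv_f, tiv_m])
    vois = {
        name: (0.002 + 0.004 * rng.random()) * tiv * np.exp(rng.normal(0, 0.1, size=len(tiv)))
        for name in names
    }
    return make_cohort(tiv_f, tiv_m, vois, atlas=atlas)
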