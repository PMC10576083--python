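import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from polyhcc import GeneratorConfig, call_cohort, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_nuclei(
    spots,
    tumor_id="T001",
    field_id=None,
    area=50.0,
    dapi=100.0,
    hnf4a=True,
    ki67=False,
    is_tumor=True,
):
    """Build a minimal nuclei table; scalar arguments broadcast over rows."""
    spots = np.atleast_2d(np.asarray(spots, dtype=int))
    n = len(spots)

    def col(v):
        return np.broadcast_to(np.asarray(v), (n,)).copy()

    return pd.DataFrame(
        {
            "tumor_id": col(tumor_id),
            "field_id": col(field_id if field_id is not None else 1),
            "nucleus_id": [f"{tumor_id}-N{i:04d}" for i in range(n)],
            "spots_chr7": spots[:, 0],
            "spots_chr11": spots[:, 1],
            "spots_chr16": spots[:, 2],
            "area_um2": col(area).astype(float),
            "dapi_integrated": col(dapi).astype(float),
            "hnf4a_pos": col(hnf4a).astype(bool),
            "ki67_pos": col(ki67).astype(bool),
            "is_tumor": col(is_tumor).astype(bool),
        }
    )


def uniform_nuclei(triple, n=12, **kw):
    """n nuclei all carrying the same spot triple."""
    return make_nuclei([list(triple)] * n, **kw)


@pytest.fixture(scope="session")
def study_cohort():
    """Default study-mirror cohort at the first documented seed."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def study_calls(study_cohort):
    return call_cohort(study_cohort.nuclei)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for I/O and CLI tests."""
    return generate_cohort(
        GeneratorConfig(n_tumors=6, nuclei_per_tumor=100, fields_per_tumor=3, seed=3)
    )
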