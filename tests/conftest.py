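import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from isclone import AbundanceMatrix, make_mix_fixture, to_relative_abundance

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def abundance_from_rows(rows: dict[str, list[float]],
                        normalize: bool = True) -> AbundanceMatrix:
    """Build a small AbundanceMatrix from literal rows, column-normalized."""
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    if normalize:
        df = df / df.sum(axis=0)
    return AbundanceMatrix(df)


@pytest.fixture(scope="session")
def two_clone_series() -> AbundanceMatrix:
    """Noiseless series of two clones with opposite dynamics: clone A
    (3 IS, growing) and clone B (4 IS, shrinking), normalized together with
    a fluctuating background that is then filtered out (as in real data,
    where dropped minor IS carry part of each column's mass)."""
    a = np.array([10.0, 20.0, 40.0, 80.0, 100.0])
    b = np.array([100.0, 80.0, 40.0, 20.0, 10.0])
    bg = np.array([40.0, 90.0, 30.0, 70.0, 50.0])
    rows = {f"A{i}": a for i in range(3)} | {f"B{i}": b for i in range(4)}
    rows["bg"] = bg
    full = abundance_from_rows({k: list(v) for k, v in rows.items()})
    return full.subset([i for i in full.is_ids if i != "bg"])


@pytest.fixture(scope="session")
def mix_fixture():
    return make_mix_fixture(seed=0)


@pytest.fixture(scope="session")
def mix_abundance(mix_fixture):
    return to_relative_abundance(mix_fixture.counts)
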