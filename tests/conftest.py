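from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

DATA_DIR = Path(__file__).resolve().parent.parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


def exact_median_moments(values) -> tuple[float, float]:
    """Exhaustive bootstrap-of-the-median oracle.

    Enumerates all n**n equiprobable with-replacement resamples of the
    vector, takes each resample's median, and returns the exact mean and
    population SD of that distribution — the B -> infinity limit of the
    Monte-Carlo bootstrap.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    meds = np.array([np.median(vals[list(t)])
                     for t in itertools.product(range(n), repeat=n)])
    return float(meds.mean()), float(meds.std()), meds


@pytest.fixture(scope="session")
def screen_proteins(data_dir) -> list[str]:
    import plexscreen.network_report as nr

    return sorted(nr.read_families(data_dir / "families.tsv"))
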