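import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from circare.series import EpochSeries

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MIDNIGHT = pd.Timestamp("2023-03-06 00:00:00")


def make_series(counts, start=MIDNIGHT, epoch_seconds=60, **meta) -> EpochSeries:
    counts = np.asarray(counts, dtype=float)
    ts = pd.date_range(start, periods=len(counts), freq=pd.Timedelta(seconds=epoch_seconds))
    return EpochSeries(ts, counts, epoch_seconds, metadata=dict(meta))


@pytest.fixture(scope="session")
def default_subject():
    """One synthetic subject under the generator's default study conditions."""
    from circare.synthetic import SyntheticSpec, generate_subject

    return generate_subject(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def default_features(default_subject):
    from circare.features import extract_features

    series, truth = default_subject
    fs, qc = extract_features(series)
    return fs, qc, truth
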