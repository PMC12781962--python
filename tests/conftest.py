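import numpy as np
import pytest

from dsamonitor import (
    CohortConfig,
    DsaPatternModel,
    TrajectorySeries,
    generate_cohort,
    interpolate_daily,
)


def make_series(days, mfi, patient_id="P1", dsa_label="total", group=None, **kw):
    return TrajectorySeries(patient_id, dsa_label, np.asarray(days), np.asarray(mfi), group=group, **kw)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noiseless 4-group cohort (10 per group) on the daily grid."""
    cfg = CohortConfig(
        n_per_group=10, seed=20240, noise_cv=0.0, groups=(1, 2, 3, 4),
        sampling_schedule=tuple(range(1, 51)),
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default noisy 4-group cohort, interpolated to daily."""
    cfg = CohortConfig(n_per_group=10, seed=777, groups=(1, 2, 3, 4))
    return [interpolate_daily(s) for s in generate_cohort(cfg)]


@pytest.fixture(scope="session")
def noiseless_results(noiseless_cohort):
    return DsaPatternModel(noiseless_cohort).fit()


@pytest.fixture(scope="session")
def noisy_results(noisy_cohort):
    return DsaPatternModel(noisy_cohort).fit()
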