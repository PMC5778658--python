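import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import temposig as tp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def longitudinal_ds():
    """Small balanced longitudinal dataset with 3 relevant features."""
    ds, truth = tp.gen_temporal_longitudinal(K=20, d=4, p=30, s=3, seed=11)
    return ds, truth


@pytest.fixture
def distinct_ds():
    ds, truth = tp.gen_distinct(N=60, d=4, p=20, s=2, seed=7)
    return ds, truth


def ols_partial_f_p(y, base, xcol):
    """Independent closed-form partial-F oracle for nested linear models."""
    from scipy import stats

    design = np.column_stack([base, xcol])
    c0, *_ = np.linalg.lstsq(base, y, rcond=None)
    c1, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss0 = float(np.sum((y - base @ c0) ** 2))
    rss1 = float(np.sum((y - design @ c1) ** 2))
    df_den = len(y) - design.shape[1]
    F = (rss0 - rss1) / (rss1 / df_den)
    return float(stats.f.sf(F, 1, df_den))
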