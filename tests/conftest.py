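import numpy as np
import pytest

from alffpipe.cohort import CohortSpec, SiteSpec, study_sites
from alffpipe.io import BoldRun, MotionTrace


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def centered_cosine(k, n, amp=1.0):
    """Cosine at exact DFT bin k, phase-centred on the series midpoint.

    Even symmetry about (n-1)/2 makes it exactly orthogonal to the intercept
    and the centred linear trend, so linear detrending leaves it untouched and
    its one-sided spectrum is a single bin of amplitude ``amp``.
    """
    t = np.arange(n)
    return amp * np.cos(2 * np.pi * k * (t - (n - 1) / 2) / n)


def make_run(
    data=None,
    shape=(6, 6, 6),
    n_frames=40,
    tr=2.0,
    rng=None,
    mask=None,
    **kwargs,
):
    """Small BoldRun around random or supplied data."""
    if data is None:
        rng = rng or np.random.default_rng(0)
        data = 100.0 + rng.standard_normal(shape + (n_frames,))
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldRun(data=data, tr_seconds=tr, brain_mask=mask, **kwargs)


@pytest.fixture
def small_run(rng):
    return make_run(rng=rng)


@pytest.fixture
def zero_trace():
    return MotionTrace(values=np.zeros((40, 6)))


@pytest.fixture
def tiny_cohort_spec():
    """One-site, 3+3-subject cohort on the default phantom grid."""
    return CohortSpec(
        sites=[SiteSpec("s1", 3, 3)],
        master_seed=7,
    )


@pytest.fixture
def four_site_spec():
    return CohortSpec(sites=study_sites(4, 4), master_seed=3)
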