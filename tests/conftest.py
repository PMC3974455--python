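import numpy as np
import pytest

from circatox.dam_io import ActivitySeries, LightSchedule


@pytest.fixture
def dd_schedule():
    return LightSchedule.constant("DD")


@pytest.fixture
def ld_dd_schedule():
    return LightSchedule.standard_ld_dd()


def make_series(counts, bin_width_min=30.0, schedule=None, fly_id="fly", **kw):
    if schedule is None:
        schedule = LightSchedule.constant("DD")
    return ActivitySeries(
        fly_id=fly_id,
        counts=np.asarray(counts, dtype=np.int64),
        bin_width_min=bin_width_min,
        schedule=schedule,
        **kw,
    )


@pytest.fixture
def cosine_series(dd_schedule):
    """7 days of 30-min bins tracking a 24-h cosine (noiseless)."""

    def _make(tau=24.0, days=7, bin_h=0.5, baseline=50.0, amp=1.0):
        t = (np.arange(int(days * 24 / bin_h)) + 0.5) * bin_h
        lam = baseline * (1 + amp * np.cos(2 * np.pi * t / tau))
        return make_series(np.round(lam), bin_width_min=bin_h * 60, schedule=dd_schedule)

    return _make
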