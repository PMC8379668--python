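import warnings

import numpy as np
import pytest

import stimecog as se

warnings.filterwarnings("ignore", message="recording shorter than one full duty cycle")


@pytest.fixture(scope="session")
def demo_recording():
    """One default 180-s recording with a middle on-interval at [30, 90)."""
    cfg = se.SimConfig(duration_s=180.0, seed=101)
    return se.simulate_recording(cfg)


@pytest.fixture(scope="session")
def streamed_recording():
    """A 15-min streamed recording containing three full on-intervals."""
    cfg = se.SimConfig(duration_s=900.0, seed=202)
    return se.simulate_recording(cfg)


def simulate_cohort(n, seed, duration_s=180.0, **cfg_kw):
    """n independent recordings with their truth intervals, preprocessed for
    band analysis (blanking excised, 105 Hz notch, z-scored)."""
    rng = np.random.default_rng(seed)
    recs, intervals, truths = {}, [], {}
    for i in range(n):
        cfg = se.SimConfig(
            duration_s=duration_s, seed=int(rng.integers(2**31)), **cfg_kw
        )
        rec, truth = se.simulate_recording(cfg)
        rid = f"r{i:03d}"
        rec.recording_id = rid
        recs[rid] = se.standard_preprocess(rec)
        truths[rid] = truth
        for iv in truth.on_intervals:
            intervals.append(
                se.StimInterval(rid, iv.start_s, iv.end_s, "on", "simulated")
            )
    return recs, intervals, truths


@pytest.fixture(scope="session")
def theta_cohort():
    """30 preprocessed default recordings (theta effect_z = -1.5 injected)."""
    return simulate_cohort(30, seed=7)


@pytest.fixture(scope="session")
def theta_trials(theta_cohort):
    recs, intervals, _ = theta_cohort
    theta = se.DEFAULT_BANDS[1]
    return se.align_trials(recs, intervals, "HPC1-HPC2", theta)
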