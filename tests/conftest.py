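import numpy as np
import pytest

import nirfperf as nf


@pytest.fixture()
def config():
    return nf.AnalysisConfig()


@pytest.fixture(scope="session")
def success_run():
    """One successful-pattern simulation with ROIs and ground truth."""
    cfg = nf.preset("successful_gmi", seed=11)
    stack, truth = nf.generate_video(cfg)
    return cfg, stack, truth, nf.default_roi_set(cfg)


@pytest.fixture(scope="session")
def failed_run():
    """One failed-pattern simulation with ROIs and ground truth."""
    cfg = nf.preset("failed_gmi", seed=12)
    stack, truth = nf.generate_video(cfg)
    return cfg, stack, truth, nf.default_roi_set(cfg)


@pytest.fixture()
def ramp_stack():
    """Noiseless uniform stack with intensity = 3 * t everywhere."""
    times = np.arange(0, 30, 0.5)
    frames = np.broadcast_to(3.0 * times[:, None, None], (len(times), 6, 6)).copy()
    return nf.FrameStack(frames=frames, timestamps=times)


def make_curve(times, intensities, **kw):
    kw.setdefault("baseline_n", 5)
    y = np.asarray(intensities, dtype=float)
    base = y[: kw["baseline_n"]]
    kw.setdefault("baseline_mean", float(base.mean()))
    kw.setdefault("baseline_sd", float(base.std()))
    return nf.PerfusionCurve(times=np.asarray(times, float), intensities=y, **kw)
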