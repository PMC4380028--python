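import numpy as np
import pytest

from lcmsopt.instrument_sim import (
    default_parameter_space,
    default_steroid_model,
    simulate_run,
)
from lcmsopt.mzml_io import Chromatogram, RunData
from lcmsopt.objectives import evaluate_objectives
from lcmsopt.peak_detection import DetectionSettings, TargetAnalyte, detect_all


@pytest.fixture(scope="session")
def steroid_model():
    return default_steroid_model()


@pytest.fixture(scope="session")
def parameter_space():
    return tuple(default_parameter_space())


@pytest.fixture(scope="session")
def steroid_targets(steroid_model):
    return tuple(
        TargetAnalyte(a.name, a.parent_mz, a.fragment_mz) for a in steroid_model.analytes
    )


@pytest.fixture(scope="session")
def detection_settings():
    return DetectionSettings()


@pytest.fixture(scope="session")
def noise_free_evaluator(steroid_model, steroid_targets, detection_settings):
    """Solution -> ObjectiveVector on the noise-free simulator, in memory."""

    def evaluate(solution):
        run = simulate_run(steroid_model, solution)
        peaks = detect_all(run, steroid_targets, detection_settings)
        return evaluate_objectives(peaks, run.max_time)

    return evaluate


def gaussian_chromatogram(
    height=1000.0,
    sigma=0.05,
    apex=2.0,
    t_max=4.0,
    dt=0.005,
    precursor=331.2,
    product=97.0,
    noise_sd=0.0,
    rng=None,
):
    """Synthetic single-peak trace used across the detection tests."""
    t = np.arange(0.0, t_max + dt / 2, dt)
    y = height * np.exp(-((t - apex) ** 2) / (2 * sigma**2))
    if noise_sd > 0:
        y = y + (rng or np.random.default_rng(0)).normal(0, noise_sd, len(t))
    return Chromatogram("gauss", precursor, product, t, np.clip(y, 0, None))


@pytest.fixture
def six_transition_run(steroid_model):
    """A clean six-transition run built directly from the model's analytes."""
    chroms = tuple(
        gaussian_chromatogram(
            height=a.base_height,
            sigma=0.05,
            apex=a.base_rt,
            t_max=5.0,
            dt=0.01,
            precursor=a.parent_mz,
            product=a.fragment_mz,
        )
        for a in steroid_model.analytes
    )
    return RunData("six", chroms)
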