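"""Simulated LC-MS/MS instrument for closed-loop optimization at desk scale.

The optimizer only ever sees an :class:`Instrument`: something that accepts
a parameter set and yields an mzML file.  On real hardware that contract is
fulfilled by instrument control software; here a parametric chromatography
model stands in, giving the loop a ground-truth-known target cheap enough
to evaluate exhaustively.

Model
-----
Each analyte elutes as a Gaussian peak.  One designated parameter (the
gradient time) scales every retention time linearly:
``rt = base_rt * value / reference``.  Compressing the gradient also costs
signal — peak height scales as ``sqrt(value / reference)``, a stand-in for
the band compression and ion-suppression losses of very fast gradients —
so a shorter analysis (objective i) trades directly against total peak
area (objective iii).  Other parameters carry per-analyte unimodal
sensitivity curves,
``height *= exp(-(value - optimum)^2 / (2 width^2))``, with analyte-specific
optima so no single setting maximizes every analyte at once (a non-trivial
Pareto front is guaranteed by construction).  Gaussian detector noise
(truncated at zero) is added when ``noise_sd > 0``.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .mzml_io import Chromatogram, RunData, write_run
from .pesa2 import ParameterSpec, Solution

__all__ = [
    "AnalyteSpec",
    "SensitivityCurve",
    "InstrumentModel",
    "Instrument",
    "SimulatedInstrument",
    "simulate_run",
    "default_steroid_model",
    "default_parameter_space",
]


@dataclass(frozen=True)
class AnalyteSpec:
    """Ground truth for one simulated analyte."""

    name: str
    parent_mz: float
    fragment_mz: float
    base_rt: float  # minutes, at the reference gradient time
    base_height: float  # counts, at all sensitivity optima

    def __post_init__(self) -> None:
        if self.base_rt <= 0 or self.base_height <= 0:
            raise ValueError(f"analyte {self.name!r}: base_rt and base_height must be positive")


@dataclass(frozen=True)
class SensitivityCurve:
    """Unimodal response of one analyte to one parameter."""

    analyte: str
    parameter: str
    optimum: float  # native units
    width: float  # native units, Gaussian sigma of the response

    def multiplier(self, value: float) -> float:
        return math.exp(-((value - self.optimum) ** 2) / (2.0 * self.width**2))


@dataclass(frozen=True)
class InstrumentModel:
    """Parametric model of a targeted LC-MS/MS analysis."""

    analytes: tuple[AnalyteSpec, ...]
    rt_parameter: str  # parameter scaling retention times (gradient time)
    rt_reference: float  # native units; rt scale = value / rt_reference
    sensitivity_curves: tuple[SensitivityCurve, ...] = ()
    peak_sigma: float = 0.05  # minutes
    noise_sd: float = 0.0  # counts
    sampling_interval: float = 0.01  # minutes
    run_length_factor: float = 1.2  # max_time = factor * latest rt

    def __post_init__(self) -> None:
        object.__setattr__(self, "analytes", tuple(self.analytes))
        object.__setattr__(self, "sensitivity_curves", tuple(self.sensitivity_curves))
        if not self.analytes:
            raise ValueError("model needs at least one analyte")
        if self.peak_sigma <= 0 or self.sampling_interval <= 0 or self.rt_reference <= 0:
            raise ValueError("peak_sigma, sampling_interval and rt_reference must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def required_parameters(self) -> set[str]:
        return {self.rt_parameter} | {c.parameter for c in self.sensitivity_curves}


class Instrument(Protocol):
    """The single contract the optimizer needs from any instrument."""

    def run(self, solution: Solution, run_id: str) -> Path:
        """Execute one analysis; return the path of a fresh, readable mzML file."""
        ...


def simulate_run(
    model: InstrumentModel,
    solution: Solution,
    rng: np.random.Generator | None = None,
) -> RunData:
    """Simulate one analysis: one chromatogram per analyte.

    Deterministic given the rng state; with ``noise_sd == 0`` the rng is
    never consumed.
    """
    params = solution.phenotype
    missing = model.required_parameters() - set(params)
    if missing:
        raise ValueError(f"solution lacks parameters required by the model: {sorted(missing)}")

    rt_scale = params[model.rt_parameter] / model.rt_reference
    if rt_scale <= 0:
        raise ValueError("retention-time scale must be positive")
    # fast gradients lose signal (band compression / suppression): h ~ sqrt(scale)
    dilution = math.sqrt(rt_scale)

    rts = {a.name: a.base_rt * rt_scale for a in model.analytes}
    max_time = model.run_length_factor * max(rts.values())
    times = np.arange(0.0, max_time + model.sampling_interval / 2, model.sampling_interval)

    chroms = []
    for analyte in model.analytes:
        height = analyte.base_height * dilution
        for curve in model.sensitivity_curves:
            if curve.analyte == analyte.name:
                height *= curve.multiplier(params[curve.parameter])
        signal = height * np.exp(-((times - rts[analyte.name]) ** 2) / (2.0 * model.peak_sigma**2))
        if model.noise_sd > 0:
            if rng is None:
                raise ValueError("noisy model requires an rng")
            signal = signal + rng.normal(0.0, model.noise_sd, size=len(times))
        signal = np.clip(signal, 0.0, None)
        chroms.append(
            Chromatogram(
                id=f"SRM {analyte.name} {analyte.parent_mz:g}->{analyte.fragment_mz:g}",
                precursor_mz=analyte.parent_mz,
                product_mz=analyte.fragment_mz,
                times=times,
                intensities=signal,
            )
        )
    return RunData(run_id="simulated", chromatograms=tuple(chroms))


@dataclass
class SimulatedInstrument:
    """Instrument adapter over :func:`simulate_run`.

    Writes every analysis through the real mzML writer so the closed loop
    exercises the same I/O path a hardware adapter would.  The noise stream
    of each run is keyed on ``(seed, run_id)``, so any single run can be
    reproduced without replaying the ones before it — the property that
    makes crash-resume exact even on a noisy model.
    """

    model: InstrumentModel
    output_dir: Path
    seed: int = 0

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        self.output_dir.mkdir(parents=True, exist_ok=True)

    def run(self, solution: Solution, run_id: str) -> Path:
        rng = np.random.default_rng(
            [self.seed & 0x7FFFFFFF, zlib.crc32(run_id.encode())]
        )
        data = simulate_run(self.model, solution, rng)
        data = RunData(run_id=run_id, chromatograms=data.chromatograms)
        return write_run(data, self.output_dir / f"{run_id}.mzML")


# ---------------------------------------------------------------------------
# default six-steroid scenario


def default_steroid_model(noise_sd: float = 0.0) -> InstrumentModel:
    """Six-analyte steroid-mixture model with a non-trivial Pareto front.

    The six transitions and retention times are synthetic but mass-plausible
    placeholders for a steroid panel (testosterone-like precursors in the
    270-410 Th range, classic fragment ions near 97/109 Th).  The gradient
    time scales retention linearly; spray voltage and source temperature
    carry analyte-specific sensitivity optima chosen so that no single
    setting maximizes all six analytes at once.
    """
    analytes = (
        AnalyteSpec("steroid_A", 289.2, 97.0, 1.10, 9.0e4),
        AnalyteSpec("steroid_B", 305.2, 109.0, 1.55, 7.5e4),
        AnalyteSpec("steroid_C", 331.2, 97.0, 2.05, 1.1e5),
        AnalyteSpec("steroid_D", 347.2, 121.0, 2.60, 6.0e4),
        AnalyteSpec("steroid_E", 363.2, 309.0, 3.20, 8.5e4),
        AnalyteSpec("steroid_F", 409.3, 267.0, 3.90, 5.0e4),
    )
    curves = (
        # spray voltage (kV): early eluters favor low voltage, late high;
        # narrow widths let extreme settings push the far analytes below
        # the detector's S/N threshold, so detection count joins the
        # time/area conflict
        SensitivityCurve("steroid_A", "spray_voltage", 3.0, 0.5),
        SensitivityCurve("steroid_B", "spray_voltage", 3.5, 0.5),
        SensitivityCurve("steroid_C", "spray_voltage", 4.0, 0.5),
        SensitivityCurve("steroid_D", "spray_voltage", 4.5, 0.5),
        SensitivityCurve("steroid_E", "spray_voltage", 5.0, 0.5),
        SensitivityCurve("steroid_F", "spray_voltage", 5.5, 0.5),
        # source temperature (degC): two blocks with opposed optima
        SensitivityCurve("steroid_A", "source_temp", 350.0, 120.0),
        SensitivityCurve("steroid_B", "source_temp", 350.0, 120.0),
        SensitivityCurve("steroid_C", "source_temp", 450.0, 120.0),
        SensitivityCurve("steroid_D", "source_temp", 450.0, 120.0),
        SensitivityCurve("steroid_E", "source_temp", 550.0, 120.0),
        SensitivityCurve("steroid_F", "source_temp", 550.0, 120.0),
    )
    return InstrumentModel(
        analytes=analytes,
        rt_parameter="gradient_time",
        rt_reference=10.0,
        sensitivity_curves=curves,
        peak_sigma=0.05,
        noise_sd=noise_sd,
        sampling_interval=0.01,
    )


def default_parameter_space() -> list[ParameterSpec]:
    """3-parameter, 5-level grid matched to :func:`default_steroid_model`.

    125 combinations in total — small enough for the exhaustive oracle.
    """
    return [
        ParameterSpec("gradient_time", 4.0, 16.0, 3.0, unit="min"),
        ParameterSpec("spray_voltage", 3.0, 5.0, 0.5, unit="kV"),
        ParameterSpec("source_temp", 350.0, 550.0, 50.0, unit="degC"),
    ]
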