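"""Targeted SRM peak detection: one peak per target transition.

The detector is deliberately simple and instrument-agnostic — it must work
on chromatograms from any triple quadrupole without per-dataset tuning.
For each target it finds the matching transition trace, smooths it with a
centered moving average, takes the global maximum of the smoothed signal in
the retention-time search window as the apex, walks outward to the peak
boundaries, estimates noise robustly (scaled median absolute deviation of
the off-peak smoothed signal) and integrates the *raw* signal trapezoidally
between the boundaries.  A target counts as detected when the
signal-to-noise ratio clears a threshold and the peak spans enough samples.

Alternative detectors can be registered under a name and selected in the
experiment configuration (``register_algorithm`` / ``get_algorithm``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .mzml_io import Chromatogram, RunData

__all__ = [
    "TargetAnalyte",
    "DetectionSettings",
    "Peak",
    "match_transition",
    "detect_peak",
    "detect_all",
    "load_targets_csv",
    "register_algorithm",
    "get_algorithm",
]

#: noise floor (counts) applied to the MAD estimate; keeps S/N finite on
#: noise-free synthetic data
NOISE_FLOOR = 1.0


@dataclass(frozen=True)
class TargetAnalyte:
    """One SRM transition to detect and quantify."""

    name: str
    parent_mz: float
    fragment_mz: float
    rt_expected: float | None = None  # minutes
    rt_window: float | None = None  # minutes, half-width around rt_expected

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("target name must be non-empty")
        if self.parent_mz <= 0 or self.fragment_mz <= 0:
            raise ValueError(f"target {self.name!r}: m/z values must be positive")
        if self.rt_window is not None and self.rt_window <= 0:
            raise ValueError(f"target {self.name!r}: rt_window must be positive")


@dataclass(frozen=True)
class DetectionSettings:
    """Tunables of the default peak detector."""

    mz_tolerance: float = 0.5  # Th, transition matching
    smoothing_width: int = 5  # points, centered moving average (odd)
    snr_threshold: float = 3.0
    min_points_across_peak: int = 5
    boundary_fraction: float = 0.05  # of apex height

    def __post_init__(self) -> None:
        if self.mz_tolerance < 0:
            raise ValueError("mz_tolerance must be >= 0")
        if self.smoothing_width < 1 or self.smoothing_width % 2 == 0:
            raise ValueError("smoothing_width must be odd and >= 1")
        if self.snr_threshold <= 0:
            raise ValueError("snr_threshold must be positive")
        if self.min_points_across_peak < 3:
            raise ValueError("min_points_across_peak must be >= 3")
        if not (0 < self.boundary_fraction < 1):
            raise ValueError("boundary_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class Peak:
    """An integrated chromatographic peak for one target."""

    target_name: str
    apex_rt: float  # minutes
    start_rt: float
    end_rt: float
    height: float  # counts, raw apex height
    area: float  # counts * minutes, trapezoidal over raw signal
    snr: float

    def __post_init__(self) -> None:
        if not (self.start_rt <= self.apex_rt <= self.end_rt):
            raise ValueError("peak boundaries must bracket the apex")
        if self.area < 0 or self.height < 0 or self.snr < 0:
            raise ValueError("area, height and snr must be non-negative")


def match_transition(
    run: RunData, target: TargetAnalyte, settings: DetectionSettings
) -> Chromatogram | None:
    """Find the chromatogram whose transition matches the target.

    Both the precursor and product m/z must lie within ``mz_tolerance`` of
    the target's parent and fragment m/z.  Ties go to the smallest combined
    absolute m/z distance, then to the lowest chromatogram index.  Returns
    ``None`` when no trace qualifies.
    """
    best: Chromatogram | None = None
    best_dist = np.inf
    for chrom in run.chromatograms:
        d1 = abs(chrom.precursor_mz - target.parent_mz)
        d2 = abs(chrom.product_mz - target.fragment_mz)
        if d1 <= settings.mz_tolerance and d2 <= settings.mz_tolerance:
            if d1 + d2 < best_dist:
                best, best_dist = chrom, d1 + d2
    return best


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at edges."""
    if width <= 1:
        return y.astype(np.float64, copy=True)
    half = width // 2
    csum = np.concatenate([[0.0], np.cumsum(y, dtype=np.float64)])
    n = len(y)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def _walk_boundary(smoothed: np.ndarray, apex: int, threshold: float, step: int) -> int:
    """Walk from the apex in direction ``step`` until the signal drops below
    ``threshold`` or a local minimum followed by a rise is passed; returns
    the boundary index."""
    i = apex
    n = len(smoothed)
    while True:
        j = i + step
        if j < 0 or j >= n:
            return i
        if smoothed[j] < threshold:
            return j
        if smoothed[j] > smoothed[i] and i != apex:
            # i was a local minimum and the signal is rising again
            return i
        i = j


def detect_peak(
    chrom: Chromatogram, target: TargetAnalyte, settings: DetectionSettings
) -> Peak | None:
    """Locate and integrate the target's peak in one chromatogram.

    Returns ``None`` when no peak clears the S/N threshold or spans fewer
    than ``min_points_across_peak`` samples.
    """
    times = chrom.times
    raw = chrom.intensities
    smoothed = _moving_average(raw, settings.smoothing_width)

    if target.rt_expected is not None and target.rt_window is not None:
        lo_t = target.rt_expected - target.rt_window
        hi_t = target.rt_expected + target.rt_window
        region = np.flatnonzero((times >= lo_t) & (times <= hi_t))
        if len(region) < settings.min_points_across_peak:
            return None
        r0, r1 = int(region[0]), int(region[-1])
    else:
        r0, r1 = 0, len(times) - 1

    seg = smoothed[r0 : r1 + 1]
    apex_rel = int(np.argmax(seg))
    apex = r0 + apex_rel
    apex_height_smooth = smoothed[apex]
    if apex_height_smooth <= 0:
        return None

    threshold = settings.boundary_fraction * apex_height_smooth
    start = _walk_boundary(smoothed[r0 : r1 + 1], apex_rel, threshold, -1) + r0
    end = _walk_boundary(smoothed[r0 : r1 + 1], apex_rel, threshold, +1) + r0
    if end - start + 1 < settings.min_points_across_peak:
        return None

    outside = np.concatenate([smoothed[:start], smoothed[end + 1 :]])
    if len(outside) >= 4:
        mad = np.median(np.abs(outside - np.median(outside)))
        noise = 1.4826 * mad
    else:
        noise = 0.0
    noise = max(noise, NOISE_FLOOR)
    snr = apex_height_smooth / noise
    if snr < settings.snr_threshold:
        return None

    area = float(np.trapezoid(raw[start : end + 1], times[start : end + 1]))
    return Peak(
        target_name=target.name,
        apex_rt=float(times[apex]),
        start_rt=float(times[start]),
        end_rt=float(times[end]),
        height=float(raw[apex]),
        area=max(area, 0.0),
        snr=float(snr),
    )


def detect_all(
    run: RunData,
    targets: Sequence[TargetAnalyte],
    settings: DetectionSettings | None = None,
    algorithm: str = "simple",
) -> dict[str, Peak | None]:
    """Detect every target in a run; exactly one entry per target name.

    ``algorithm`` names a registered detector (see
    :func:`register_algorithm`); the default is the built-in one.
    """
    if not targets:
        raise ValueError("target list must be non-empty")
    names = [t.name for t in targets]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate target names: {dupes}")
    settings = settings or DetectionSettings()
    detector = get_algorithm(algorithm)
    result: dict[str, Peak | None] = {}
    for target in targets:
        chrom = match_transition(run, target, settings)
        result[target.name] = (
            detector(chrom, target, settings) if chrom is not None else None
        )
    return result


def load_targets_csv(path: str | Path) -> list[TargetAnalyte]:
    """Load a target list from CSV.

    Columns: ``name, parent_mz, fragment_mz`` with optional ``rt_expected``
    and ``rt_window`` (minutes).
    """
    targets = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "parent_mz", "fragment_mz"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"target CSV must have columns {sorted(required)}")
        for row in reader:
            opt = {}
            for key in ("rt_expected", "rt_window"):
                v = row.get(key)
                if v not in (None, ""):
                    opt[key] = float(v)
            targets.append(
                TargetAnalyte(
                    name=row["name"].strip(),
                    parent_mz=float(row["parent_mz"]),
                    fragment_mz=float(row["fragment_mz"]),
                    **opt,
                )
            )
    if not targets:
        raise ValueError(f"{path}: empty target list")
    return targets


# --- pluggable-algorithm registry ------------------------------------------

DetectorFn = Callable[[Chromatogram, TargetAnalyte, DetectionSettings], Peak | None]

_REGISTRY: dict[str, DetectorFn] = {}


def register_algorithm(name: str, fn: DetectorFn) -> None:
    """Register a peak-detection algorithm under a name."""
    _REGISTRY[name] = fn


def get_algorithm(name: str) -> DetectorFn:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown peak-detection algorithm {name!r}; known: {sorted(_REGISTRY)}"
        ) from None


register_algorithm("simple", detect_peak)
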