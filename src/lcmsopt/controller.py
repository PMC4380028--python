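"""Closed-loop orchestration: configuration, the optimization loop, reports.

One optimization campaign = a validated :class:`ExperimentConfig` (targets,
parameter grid, GA and detection settings, instrument) driven through
:func:`run_optimization`:

1. the first ``initial_runs`` parameter sets are drawn uniformly at random
   (generation 1);
2. each subsequent generation proposes ``runs_per_generation`` offspring
   (region-based parent selection from the archive, uniform crossover,
   resampling mutation), runs them on the instrument, reads the mzML back,
   detects the targets and scores the three objectives;
3. every evaluation updates the bounded Pareto archive;
4. the loop stops at ``max_runs`` evaluations, or earlier on a user stop
   signal; a pause signal blocks between runs until released.

Everything is persisted under ``output_dir`` as it happens: one mzML per
run, an append-only evaluation history (TSV), and at the end a front table,
a per-generation trace and a scatter plot.  The history file is
deterministic for a fixed seed (wall-clock timestamps go to a separate
``events.log``), and an interrupted campaign can be resumed from it — the
optimizer replays its own random stream over the logged evaluations and
continues with runs that are identical to an uninterrupted campaign.
"""

from __future__ import annotations

import dataclasses
import datetime
import shlex
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import yaml

from .instrument_sim import (
    AnalyteSpec,
    Instrument,
    InstrumentModel,
    SensitivityCurve,
    SimulatedInstrument,
    default_parameter_space,
    default_steroid_model,
)
from .mzml_io import read_run
from .objectives import OBJECTIVE_REGISTRY, ObjectiveVector, evaluate_objectives, nondominated_front
from .peak_detection import DetectionSettings, TargetAnalyte, detect_all
from .pesa2 import (
    ArchiveEntry,
    GASettings,
    Hypergrid,
    ParameterSpec,
    Solution,
    crossover,
    mutate,
    random_solution,
    select_parent,
    update_archive,
)

__all__ = [
    "ExperimentConfig",
    "OptimizationResult",
    "HistoryRecord",
    "FileSignalSource",
    "default_config",
    "load_config",
    "save_config",
    "run_optimization",
    "front_report",
]

#: analysis_time (minutes) charged to a run whose instrument call failed
#: before any chromatogram existed; large enough to weakly dominate any
#: real run of the bundled scenarios
FAILED_RUN_TIME = 60.0

#: consecutive instrument failures tolerated before aborting the campaign
MAX_CONSECUTIVE_FAILURES = 5

HISTORY_NAME = "history.tsv"
_HISTORY_COLUMNS = (
    "run_index",
    "generation",
    "run_id",
    "genotype",
    "analysis_time",
    "n_detected",
    "total_area",
    "mzml_path",
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one optimization campaign needs."""

    targets: tuple[TargetAnalyte, ...]
    parameters: tuple[ParameterSpec, ...]
    ga: GASettings = field(default_factory=GASettings)
    detection: DetectionSettings = field(default_factory=DetectionSettings)
    objectives: tuple[str, ...] = ("analysis_time", "n_detected", "total_area")
    instrument_kind: Literal["simulated", "external-command"] = "simulated"
    instrument_model: InstrumentModel | None = None
    external_command: str | None = None
    peak_algorithm: str = "simple"
    output_dir: Path = Path("lcmsopt_output")

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "parameters", tuple(self.parameters))
        object.__setattr__(self, "objectives", tuple(self.objectives))
        object.__setattr__(self, "output_dir", Path(self.output_dir))
        if not self.targets:
            raise ValueError("config needs at least one target")
        if not self.parameters:
            raise ValueError("config needs at least one parameter")
        names = [t.name for t in self.targets]
        if len(set(names)) != len(names):
            raise ValueError("target names must be unique")
        unknown = [o for o in self.objectives if o not in OBJECTIVE_REGISTRY]
        if unknown:
            raise ValueError(
                f"unknown objectives {unknown}; registered: {sorted(OBJECTIVE_REGISTRY)}"
            )
        if self.instrument_kind == "simulated" and self.instrument_model is None:
            raise ValueError("simulated instrument requires an instrument_model")
        if self.instrument_kind == "external-command" and not self.external_command:
            raise ValueError("external-command instrument requires a command template")

    def make_instrument(self) -> Instrument:
        if self.instrument_kind == "simulated":
            assert self.instrument_model is not None
            return SimulatedInstrument(
                model=self.instrument_model,
                output_dir=self.output_dir / "mzml",
                seed=self.ga.seed,
            )
        return ExternalCommandInstrument(
            command=self.external_command or "", output_dir=self.output_dir / "mzml"
        )


@dataclass
class ExternalCommandInstrument:
    """Adapter for real hardware driven by a shell command.

    The command template is formatted with every decoded parameter value
    plus ``{mzml_path}``; it must deposit a readable mzML file at that path.
    The scriptable analogue of desktop automation of vendor software.
    """

    command: str
    output_dir: Path

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        self.output_dir.mkdir(parents=True, exist_ok=True)

    def run(self, solution: Solution, run_id: str) -> Path:
        out = self.output_dir / f"{run_id}.mzML"
        cmd = self.command.format(mzml_path=str(out), **solution.phenotype)
        subprocess.run(shlex.split(cmd), check=True)
        if not out.exists():
            raise RuntimeError(f"external command did not produce {out}")
        return out


@dataclass(frozen=True)
class HistoryRecord:
    run_index: int
    generation: int
    run_id: str
    solution: Solution
    objectives: ObjectiveVector
    mzml_path: str | None


@dataclass
class OptimizationResult:
    archive: list[ArchiveEntry]
    history: list[HistoryRecord]
    #: per generation: (generation, best full-detection analysis_time or nan,
    #: best full-detection total_area or nan) among archive members
    traces: list[tuple[int, float, float]]
    stop_reason: Literal["completed", "stopped", "paused"]


# ---------------------------------------------------------------------------
# configuration file handling

_GA_FIELDS = {f.name for f in dataclasses.fields(GASettings)}
_DET_FIELDS = {f.name for f in dataclasses.fields(DetectionSettings)}


def default_config(output_dir: str | Path = "lcmsopt_output", seed: int = 0,
                   noise_sd: float = 0.0) -> ExperimentConfig:
    """The bundled six-steroid scenario: simulated instrument, 3x5 grid."""
    model = default_steroid_model(noise_sd=noise_sd)
    targets = tuple(
        TargetAnalyte(a.name, a.parent_mz, a.fragment_mz) for a in model.analytes
    )
    return ExperimentConfig(
        targets=targets,
        parameters=tuple(default_parameter_space()),
        ga=GASettings(seed=seed),
        instrument_model=model,
        output_dir=Path(output_dir),
    )


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ValueError(f"unknown keys in {where}: {unknown}")


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and fully validate a YAML experiment configuration.

    Unknown keys are an error (listed by name); omitted settings take
    their defaults, and :func:`save_config` echoes every default back so a
    round-tripped file is self-contained.  A missing ``ga.seed`` is drawn
    from the OS entropy pool and becomes part of the configuration.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    _check_keys(
        raw,
        {"targets", "parameters", "ga", "detection", "objectives", "instrument",
         "peak_algorithm", "output_dir"},
        "config",
    )

    targets = []
    for i, t in enumerate(raw.get("targets", [])):
        _check_keys(t, {"name", "parent_mz", "fragment_mz", "rt_expected", "rt_window"},
                    f"targets[{i}]")
        targets.append(TargetAnalyte(**t))

    parameters = []
    for i, p in enumerate(raw.get("parameters", [])):
        _check_keys(p, {"name", "minimum", "maximum", "step", "unit"}, f"parameters[{i}]")
        parameters.append(ParameterSpec(**p))

    ga_raw = dict(raw.get("ga", {}))
    _check_keys(ga_raw, _GA_FIELDS, "ga")
    if "seed" not in ga_raw:
        ga_raw["seed"] = int(np.random.SeedSequence().entropy % (2**31))
    ga = GASettings(**ga_raw)

    det_raw = dict(raw.get("detection", {}))
    _check_keys(det_raw, _DET_FIELDS, "detection")
    detection = DetectionSettings(**det_raw)

    inst = dict(raw.get("instrument", {"kind": "simulated"}))
    _check_keys(inst, {"kind", "model", "command"}, "instrument")
    kind = inst.get("kind", "simulated")
    model = None
    command = None
    if kind == "simulated":
        model_raw = inst.get("model")
        model = _model_from_dict(model_raw) if model_raw else default_steroid_model()
    elif kind == "external-command":
        command = inst.get("command")
    else:
        raise ValueError(f"unknown instrument kind {kind!r}")

    objectives = tuple(raw.get("objectives") or ("analysis_time", "n_detected", "total_area"))
    return ExperimentConfig(
        targets=tuple(targets),
        parameters=tuple(parameters),
        ga=ga,
        detection=detection,
        objectives=objectives,
        instrument_kind=kind,
        instrument_model=model,
        external_command=command,
        peak_algorithm=raw.get("peak_algorithm", "simple"),
        output_dir=Path(raw.get("output_dir", "lcmsopt_output")),
    )


def _model_from_dict(d: dict) -> InstrumentModel:
    _check_keys(
        d,
        {"analytes", "rt_parameter", "rt_reference", "sensitivity_curves",
         "peak_sigma", "noise_sd", "sampling_interval", "run_length_factor"},
        "instrument.model",
    )
    analytes = tuple(AnalyteSpec(**a) for a in d["analytes"])
    curves = tuple(SensitivityCurve(**c) for c in d.get("sensitivity_curves", []))
    extra = {
        k: d[k]
        for k in ("peak_sigma", "noise_sd", "sampling_interval", "run_length_factor")
        if k in d
    }
    return InstrumentModel(
        analytes=analytes,
        rt_parameter=d["rt_parameter"],
        rt_reference=d["rt_reference"],
        sensitivity_curves=curves,
        **extra,
    )


def _model_to_dict(m: InstrumentModel) -> dict:
    return {
        "analytes": [dataclasses.asdict(a) for a in m.analytes],
        "rt_parameter": m.rt_parameter,
        "rt_reference": m.rt_reference,
        "sensitivity_curves": [dataclasses.asdict(c) for c in m.sensitivity_curves],
        "peak_sigma": m.peak_sigma,
        "noise_sd": m.noise_sd,
        "sampling_interval": m.sampling_interval,
        "run_length_factor": m.run_length_factor,
    }


def save_config(config: ExperimentConfig, path: str | Path) -> Path:
    """Export a configuration with every default made explicit."""
    doc: dict = {
        "targets": [
            {k: v for k, v in dataclasses.asdict(t).items() if v is not None}
            for t in config.targets
        ],
        "parameters": [dataclasses.asdict(p) for p in config.parameters],
        "ga": dataclasses.asdict(config.ga),
        "detection": dataclasses.asdict(config.detection),
        "objectives": list(config.objectives),
        "peak_algorithm": config.peak_algorithm,
        "output_dir": str(config.output_dir),
    }
    if config.instrument_kind == "simulated":
        assert config.instrument_model is not None
        doc["instrument"] = {"kind": "simulated", "model": _model_to_dict(config.instrument_model)}
    else:
        doc["instrument"] = {"kind": "external-command", "command": config.external_command}
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# pause/stop signalling


class FileSignalSource:
    """Pause/stop control through flag files in the output directory.

    Create a file named ``STOP`` to halt after the current run, ``PAUSE``
    to block between runs (delete it to resume).
    """

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)

    def __call__(self) -> str:
        if (self.directory / "STOP").exists():
            return "stop"
        if (self.directory / "PAUSE").exists():
            return "pause"
        return "run"


# ---------------------------------------------------------------------------
# the loop


def _generation_of(run_index: int, ga: GASettings) -> int:
    """Generation numbering: the initial random batch is generation 1,
    offspring generations count from 2."""
    if run_index < ga.initial_runs:
        return 1
    return 2 + (run_index - ga.initial_runs) // ga.runs_per_generation


def _load_history(path: Path, space: tuple[ParameterSpec, ...]) -> list[HistoryRecord]:
    records = []
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != list(_HISTORY_COLUMNS):
        raise ValueError(f"{path}: not a history file")
    for line in lines[1:]:
        f = line.split("\t")
        records.append(
            HistoryRecord(
                run_index=int(f[0]),
                generation=int(f[1]),
                run_id=f[2],
                solution=Solution(tuple(int(g) for g in f[3].split(",")), space),
                objectives=ObjectiveVector(float(f[4]), int(f[5]), float(f[6])),
                mzml_path=f[7] or None,
            )
        )
    return records


def _history_line(rec: HistoryRecord) -> str:
    # only the mzML file name is logged: the directory is the campaign's
    # own, which keeps fixed-seed histories byte-identical across locations
    mzml = Path(rec.mzml_path).name if rec.mzml_path else ""
    return "\t".join(
        [
            str(rec.run_index),
            str(rec.generation),
            rec.run_id,
            ",".join(str(g) for g in rec.solution.genotype),
            repr(rec.objectives.analysis_time),
            str(rec.objectives.n_detected),
            repr(rec.objectives.total_area),
            mzml,
        ]
    )


def _trace_point(
    archive: Sequence[ArchiveEntry], n_targets: int
) -> tuple[float, float]:
    full = [e.objectives for e in archive if e.objectives.n_detected == n_targets]
    if not full:
        return (float("nan"), float("nan"))
    return (min(o.analysis_time for o in full), max(o.total_area for o in full))


def run_optimization(
    config: ExperimentConfig,
    instrument: Instrument | None = None,
    progress: Callable[[int, ObjectiveVector, list[ArchiveEntry]], None] | None = None,
    control: Callable[[], str] | None = None,
    resume: bool = False,
) -> OptimizationResult:
    """Run (or resume) one closed-loop optimization campaign.

    ``control``, when given, is polled between runs and may return ``"run"``,
    ``"pause"`` (block, poll again) or ``"stop"`` (halt after the current
    run).  ``progress`` is invoked after every evaluation with the run
    index, its objectives and a snapshot of the archive.

    With ``resume=True`` the persisted history under ``config.output_dir``
    is replayed — logged evaluations are reused instead of re-running the
    instrument, while the optimizer's random stream advances exactly as in
    the original campaign — and the loop continues to ``max_runs``.

    A failing instrument run is scored ``(FAILED_RUN_TIME, 0, 0)`` and the
    loop continues; ``MAX_CONSECUTIVE_FAILURES`` consecutive failures abort.
    """
    ga = config.ga
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if instrument is None:
        instrument = config.make_instrument()

    history_path = out_dir / HISTORY_NAME
    events_path = out_dir / "events.log"
    replay: list[HistoryRecord] = []
    if resume and history_path.exists():
        replay = _load_history(history_path, config.parameters)

    rng = np.random.default_rng(ga.seed)
    memo: dict[tuple[int, ...], ObjectiveVector] = {}
    archive: list[ArchiveEntry] = []
    history: list[HistoryRecord] = []
    traces: list[tuple[int, float, float]] = []
    n_targets = len(config.targets)
    stop_reason: str = "completed"
    consecutive_failures = 0

    mode = "a" if replay else "w"
    with open(history_path, mode) as hist_fh, open(events_path, "a") as ev_fh:
        if not replay:
            hist_fh.write("\t".join(_HISTORY_COLUMNS) + "\n")

        def log_event(msg: str) -> None:
            stamp = datetime.datetime.now().isoformat(timespec="seconds")
            ev_fh.write(f"{stamp}\t{msg}\n")
            ev_fh.flush()

        run_index = 0
        current_generation = 1
        while run_index < ga.max_runs:
            replaying = run_index < len(replay)
            if control is not None and not replaying:
                state = control()
                while state == "pause":
                    log_event(f"paused before run {run_index}")
                    time.sleep(0.2)
                    state = control()
                if state == "stop":
                    stop_reason = "stopped"
                    log_event(f"stopped before run {run_index}")
                    break

            generation = _generation_of(run_index, ga)
            if generation != current_generation:
                traces.append((current_generation, *_trace_point(archive, n_targets)))
                current_generation = generation

            # --- propose (consumes the rng identically when replaying)
            if generation == 1:
                solution = random_solution(config.parameters, rng)
            else:
                grid = Hypergrid.fit([e.objectives for e in archive], ga.grid_divisions)
                p1 = select_parent(archive, grid, rng)
                p2 = select_parent(archive, grid, rng)
                child = crossover(p1.solution, p2.solution, ga.crossover_prob, rng)
                solution = mutate(
                    child, ga.mutation_prob_for(len(config.parameters)), config.parameters, rng
                )

            run_id = f"run_{run_index:04d}"

            # --- evaluate
            if replaying:
                rec = replay[run_index]
                if rec.solution.genotype != solution.genotype:
                    raise RuntimeError(
                        f"history replay diverged at run {run_index}: "
                        f"logged {rec.solution.genotype}, reproposed {solution.genotype}"
                    )
                objectives, mzml_path = rec.objectives, rec.mzml_path
            elif ga.memoize and solution.genotype in memo:
                objectives, mzml_path = memo[solution.genotype], None
            else:
                try:
                    path = instrument.run(solution, run_id)
                    run_data = read_run(path, run_id=run_id)
                    peaks = detect_all(
                        run_data, config.targets, config.detection,
                        algorithm=config.peak_algorithm,
                    )
                    objectives = evaluate_objectives(peaks, run_data.max_time)
                    mzml_path = str(path)
                    consecutive_failures = 0
                except Exception as exc:  # noqa: BLE001 - a failed analysis is a bad run
                    consecutive_failures += 1
                    log_event(f"run {run_index} failed: {exc!r}")
                    if consecutive_failures >= MAX_CONSECUTIVE_FAILURES:
                        raise RuntimeError(
                            f"{consecutive_failures} consecutive instrument failures; "
                            f"last error: {exc!r}"
                        ) from exc
                    objectives, mzml_path = ObjectiveVector(FAILED_RUN_TIME, 0, 0.0), None

            if ga.memoize:
                memo.setdefault(solution.genotype, objectives)

            entry = ArchiveEntry(
                solution=solution,
                objectives=objectives,
                generation=generation,
                run_id=run_id,
                mzml_path=mzml_path,
            )
            archive = update_archive(archive, entry, ga)
            rec = HistoryRecord(run_index, generation, run_id, solution, objectives, mzml_path)
            history.append(rec)
            if not replaying:
                hist_fh.write(_history_line(rec) + "\n")
                hist_fh.flush()
                log_event(
                    f"run {run_index} gen {generation} genotype "
                    f"{','.join(map(str, solution.genotype))} -> {tuple(objectives)}"
                )
            if progress is not None:
                progress(run_index, objectives, list(archive))
            run_index += 1

        traces.append((current_generation, *_trace_point(archive, n_targets)))

    return OptimizationResult(
        archive=archive,
        history=history,
        traces=traces,
        stop_reason=stop_reason,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# reporting


def front_report(result: OptimizationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the Pareto-front table, the generation trace and a scatter plot.

    Returns the paths written, keyed ``front`` / ``trace`` / ``plot``.
    """
    import pandas as pd

    if not result.archive:
        raise ValueError("archive is empty; nothing to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for e in sorted(result.archive, key=lambda e: e.objectives.analysis_time):
        row = {
            "run_id": e.run_id,
            "generation": e.generation,
            "analysis_time_min": e.objectives.analysis_time,
            "n_detected": e.objectives.n_detected,
            "total_area": e.objectives.total_area,
        }
        row.update({f"param_{k}": v for k, v in e.solution.phenotype.items()})
        rows.append(row)
    front_path = out_dir / "front.csv"
    pd.DataFrame(rows).to_csv(front_path, index=False)

    trace_path = out_dir / "trace.csv"
    pd.DataFrame(
        result.traces,
        columns=["generation", "best_full_detection_time_min", "best_full_detection_area"],
    ).to_csv(trace_path, index=False)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    times = [e.objectives.analysis_time for e in result.archive]
    areas = [e.objectives.total_area for e in result.archive]
    counts = [e.objectives.n_detected for e in result.archive]
    sc = ax.scatter(times, areas, c=counts, marker="x", cmap="viridis")
    fig.colorbar(sc, ax=ax, label="targets detected")
    ax.set_xlabel("analysis time (min, RT of last detected target)")
    ax.set_ylabel("total peak area (counts·min)")
    ax.set_title("Pareto archive")
    plot_path = out_dir / "front.png"
    fig.savefig(plot_path, dpi=120)
    plt.close(fig)

    return {"front": front_path, "trace": trace_path, "plot": plot_path}
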