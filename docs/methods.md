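# Methods

## Problem setting

A targeted LC-MS/MS method monitors a list of SRM transitions (precursor
m/z → product m/z, one per analyte) and is characterized by a handful of
LC and MS control parameters. Evaluating a candidate parameter set costs
one chromatographic run (minutes to tens of minutes), so an optimizer gets
tens to a few hundred evaluations, not the tens of thousands a typical GA
assumes. `lcmsopt` treats each run as one fitness evaluation of a
multi-objective search and exchanges all data through mzML, so the loop is
independent of instrument vendor.

## Objectives

For one run, after peak detection over the target list:

- `analysis_time` = max apex retention time over *detected* targets
  (minutes, minimized). When nothing is detected it is set to the run's
  largest recorded time as a worst-case penalty — scoring an empty
  chromatogram as time 0 would make failed methods look optimal under
  minimization. Apex (not peak-end) time is used: "retention time" of an
  analyte conventionally refers to its apex.
- `n_detected` = number of targets with an accepted peak (maximized).
- `total_area` = summed trapezoidal areas of those peaks (counts·min,
  maximized).

Objectives stay on raw scales; Pareto dominance and the selection
hypergrid are scale-free, so no normalization is needed. The three
defaults are registered by name (`objectives.OBJECTIVE_REGISTRY`) so
alternates can be declared in the configuration without touching the
optimizer.

## Peak detection

The detector is deliberately simple — it must behave sanely on data from
any triple quadrupole without per-dataset tuning — and is fully specified
by `DetectionSettings`:

1. transition matching: a trace matches a target when both precursor and
   product m/z are within `mz_tolerance` (default 0.5 Th); ties go to the
   smallest combined distance, then file order;
2. smoothing: centered moving average of `smoothing_width` points
   (default 5, window shrinking at the edges);
3. apex: global maximum of the smoothed signal, restricted to
   `rt_expected ± rt_window` when the target declares both;
4. boundaries: walk out from the apex until the smoothed signal drops
   below `boundary_fraction` × apex (default 5%) or a local minimum
   followed by a rise is passed;
5. noise: 1.4826 × median absolute deviation of the smoothed signal
   outside the peak, floored at 1 count (the floor keeps S/N finite on
   noise-free synthetic data);
6. area: trapezoidal integral of the **raw** signal between the
   boundaries (smoothing biases areas; boundaries are where smoothing
   helps);
7. accept iff S/N ≥ `snr_threshold` (default 3) and the peak spans
   ≥ `min_points_across_peak` samples (default 5).

One peak per target is reported — the task is targeted quantification,
not deconvolution. Detectors are pluggable through a named registry
(default `"simple"`); co-eluting isomers, calibration and cross-run RT
alignment are out of scope.

Accuracy: on noise-free Gaussians sampled at ≥ 10 points per σ with
`boundary_fraction` 0.01, the detected area is within 2% of
h·σ·√(2π) across h ∈ {10², 10³, 10⁴} and σ ∈ {0.02, 0.05, 0.1} min
(truncating at 1% of apex height leaves ≈ 98.9% of the Gaussian mass,
and trapezoidal error at that sampling density is negligible).

## Optimizer (PESA-II)

Parameters are discretized by their `minimum`, `maximum`, `step`; a
solution's genotype is the integer level vector, which makes the search
space finite and exhaustive enumeration exact. Defaults:
`archive_capacity` 100, `grid_divisions` 8 per objective,
`crossover_prob` 0.9, `mutation_prob` 1/(number of parameters),
`initial_runs` 20, `runs_per_generation` 2, `max_runs` 200. The campaign
structure (20 + 2/generation to 200) is the standard budget the tool is
designed around; the remaining values are conventional PESA-II settings,
all overridable in the configuration.

Numerical choices:

- grid bounds are refit to the archive's extent whenever membership
  changes; a degenerate dimension (all members equal) collapses to one
  bin;
- box coordinates clamp the upper edge into the last bin;
- archive updates are deterministic: eviction draws from a generator
  seeded by the GA seed and the archive contents, so a fixed-seed
  campaign is reproducible bit for bit without threading an RNG through
  the archive API;
- the freshly inserted candidate is never evicted unless it is the sole
  occupant of every maximally crowded box;
- duplicate genotypes may be re-proposed and re-evaluated (real
  instruments are stochastic); an optional `memoize` switch short-circuits
  repeats for noise-free simulations, default off.

`brute_force_front` refuses spaces beyond 10⁵ combinations; it exists as
the ground-truth oracle for simulator studies, not as an optimizer.

## Instrument simulator

The simulator realizes the same `Instrument` contract a hardware adapter
would (parameter set in, fresh mzML file out) and writes through the real
mzML writer, so every campaign exercises the full I/O path. The model:

- each analyte elutes as a Gaussian of width `peak_sigma` (0.05 min),
  sampled every `sampling_interval` (0.01 min) over 1.2 × the last
  retention time;
- one parameter (gradient time) scales all retention times linearly,
  `rt = base_rt · value/reference`;
- peak height scales as √(value/reference): fast gradients lose signal
  (band compression, incomplete separation, suppression), so shortening
  the analysis genuinely costs peak area. The opposite sign — faster also
  taller — would make the shortest gradient best in every objective at
  once and collapse the Pareto front to a point, defeating the purpose of
  a multi-objective benchmark;
- other parameters act through per-analyte unimodal (Gaussian) response
  curves `exp(−(value−optimum)²/2·width²)`;
- optional additive detector noise (`noise_sd`, truncated at zero), with
  the per-run stream keyed on (seed, run id) so any run is reproducible in
  isolation.

The bundled scenario has six steroid-like analytes — transitions and
retention times are synthetic, mass-plausible placeholders, not measured
values — over a 3-parameter × 5-level grid (gradient time 4–16 min, spray
voltage 3–5 kV, source temperature 350–550 °C). Voltage optima are spread
across analytes with a 0.5 kV response width, so extreme voltages drop
far-optimum analytes below the S/N gate: detection count, analysis time
and total area all genuinely conflict, and the noise-free exhaustive front
has six distinct objective vectors. What the simulator does **not**
emulate: retention drift and carryover between runs, ion-suppression
interactions between co-eluting analytes, heteroscedastic detector noise,
peak tailing. Passing tests therefore demonstrate the optimizer, the
scoring pipeline and the I/O contract — not chromatographic realism.

## Controller

The loop runs `initial_runs` random evaluations (generation 1), then
generations of `runs_per_generation` offspring, to `max_runs`. A pause or
stop signal (injected callable; flag files `PAUSE`/`STOP` for the CLI) is
polled between runs: stop finishes the current run and halts, pause
blocks until released. A failed instrument run is scored
(60 min, 0, 0) — a failed analysis is just a very bad chromatogram — and
five consecutive failures abort with a diagnostic.

Persistence: each run appends one TSV line (index, generation, run id,
genotype, objectives, mzML file name) and is flushed immediately;
wall-clock timestamps go to a separate `events.log` so the history file
itself is byte-identical across fixed-seed repeats. Resume replays the
logged evaluations — consuming the optimizer's random stream exactly as
the original campaign did, verifying each replayed genotype — then
continues with fresh runs; the result is identical to an uninterrupted
campaign.

Generation numbering counts the initial random batch as generation 1 and
offspring generations from 2, so the default budget spans 91 generations
(1 + 90 × 2 offspring after 20 random runs = 200 analyses). The
per-generation trace reports the best analysis time and best total area
among archive members detecting the full target list; it is non-increasing
(resp. non-decreasing) whenever the archive capacity exceeds the number of
evaluations, and quasi-monotone otherwise (crowding eviction can remove an
incumbent).

## Problem sizes used in tests

The default test suite and the acceptance script run entire campaigns at
the standard 200-analysis budget (sub-second each on the simulator), ten
seeds for the front-recovery study, and a 125-point exhaustive
enumeration — sizes chosen because they are the tool's actual operating
envelope, not scaled-down stand-ins.

## Known limitations

- The simulator's response surfaces are smooth and separable per analyte;
  real instruments have interactions and drift, so recovery rates here are
  an upper bound on hardware behaviour.
- `analysis_time` uses apex RT; if a lab's convention is peak-end time,
  the objective registry is the extension point.
- The archive stores every non-dominated entry including objective-value
  duplicates (distinct runs of equal merit); with capacity 100 and
  200-run campaigns this is never a constraint in the bundled scenario.
- External-command instruments are trusted to deposit schema-valid mzML;
  the reader rejects files without unit annotations rather than guessing.
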