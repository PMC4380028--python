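# lcmsopt

Closed-loop multi-objective optimization of targeted LC-MS/MS method
parameters.

Developing a targeted LC-MS/MS method means tuning many coupled LC and MS
instrument parameters (gradient time, spray voltage, source temperature,
…) where each trial costs a full chromatographic run. `lcmsopt` automates
this with a closed loop: a genetic algorithm proposes a parameter set, the
instrument runs one analysis, the resulting mzML chromatograms are scored
by a targeted peak detector, and the scores steer the next proposal. It is
aimed at analytical chemists and method developers who can script their
instrument (or want to study the optimizer against the bundled simulator).

## Method

Each analysis is scored on three objectives:

- **analysis time** *t* (minutes, minimize) — the retention time of the
  last-eluting *detected* target, not the programmed run length;
- **targets detected** *n* (maximize) — targets whose transition trace
  yields a peak with S/N ≥ threshold;
- **total peak area** *A* (counts·min, maximize) — summed trapezoidal areas
  of the detected peaks.

Because the objectives conflict, there is no single best method, only a
Pareto front. The optimizer is PESA-II: a bounded external archive holds
all mutually non-dominated solutions found so far; the archive is binned
into an adaptive hypergrid over (t, n, A); parents are chosen by binary
tournament between grid boxes (the less crowded box wins), recombined by
uniform crossover and per-gene resampling mutation over each parameter's
discrete `minimum:step:maximum` grid; when the archive overflows, a member
of the most crowded box is evicted. The first *n* runs are random
(default 20), then each generation spends 2 runs, to a default budget of
200 analyses — the scale of one unattended overnight campaign.

Every run crosses a real mzML 1.1 boundary (write → read) so any
instrument that can deposit an mzML file can close the loop; a simulated
six-steroid instrument with known ground truth is included.

## Worked example

```
python examples/exhaustive_front.py
```

enumerates all 125 settings of the bundled scenario (3 parameters × 5
levels) on the noise-free simulator and prints the true Pareto front:

```
enumerated 125 parameter combinations; 6 are Pareto-optimal:

time (min)  detected   total area   parameters
      1.28         5      14344.2   {'gradient_time': 4.0, 'spray_voltage': 3.5, 'source_temp': 350.0}
      1.56         6      15361.5   {'gradient_time': 4.0, 'spray_voltage': 4.0, 'source_temp': 450.0}
      2.73         6      20357.7   {'gradient_time': 7.0, 'spray_voltage': 4.0, 'source_temp': 450.0}
      3.90         6      24288.7   {'gradient_time': 10.0, 'spray_voltage': 4.0, 'source_temp': 450.0}
      5.07         6      27742.8   {'gradient_time': 13.0, 'spray_voltage': 4.0, 'source_temp': 450.0}
      6.24         6      30723.0   {'gradient_time': 16.0, 'spray_voltage': 4.0, 'source_temp': 450.0}
```

Reading the table: a 4-minute gradient elutes the last detected steroid at
1.56 min but costs half the peak area of the 16-minute gradient (15361 vs
30723 counts·min), and pushing the voltage/temperature toward the early
eluters (first row) shaves another 0.28 min at the price of losing the
sixth steroid entirely. `python examples/run_campaign.py` then shows a
200-analysis PESA-II campaign (seed 1) recovering this entire front
without enumerating the grid, and `examples/simulate_and_detect.py` walks
one single analysis through mzML round-trip and peak detection.

The same loop is scriptable from a shell:

```
lcmsopt optimize --out campaign --seed 1          # bundled simulator
lcmsopt detect --mzml run.mzML --targets targets.csv
lcmsopt front --history campaign                  # rebuild reports
```

Dropping a file named `STOP` (or `PAUSE`) into the campaign directory
stops (or pauses) the loop between analyses; `--resume` continues an
interrupted campaign exactly where it left off. Real hardware is attached
via an `external-command` instrument in the YAML configuration: a command
template that receives the decoded parameter values and must deposit an
mzML file at a given path.

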