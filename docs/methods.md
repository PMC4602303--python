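# Methods

This note records the model behind the engine, the choices made where the
behaviour was underdetermined, how the synthetic inputs are generated, and
the limitations of both.

## Model

### Workflow

Every session executes a fixed submission workflow of 22 concrete stages in
9 abstract groups:

| group | stages | scope |
|-------|--------|-------|
| 1 general setup | SessionInit, HostSetup, CommTest, NotifyStart | once per session |
| 2 build simulators | SimulatorPayloadUpload, SimulatorBuild, SimulatorVerify | once per simulator |
| 3 model upload | ModelFileUpload | once per session |
| 4 parameters | FetchParameterVector | per simulation |
| 5 input data | InputDataUpload | per simulation |
| 6 model processing | PreRunModelProcessingHost, ModelFileTransfer, PreRunModelProcessingRemote | per simulation |
| 7 run | JobFileGeneration, JobSubmission, SimulationExecute, RemotePostProcess | per simulation |
| 8 collect | ResultDownload, ResultRegister | per simulation |
| 9 housekeeping | SimulatorReset, ReportUpdate, NotifyProgress | per simulation |

Per-simulation stage indices are strictly increasing (9 → 22); the
activity log is the authoritative record and parses back losslessly
(`provenance.parse_log`).

### Scheduling

Simulations are assumed independent, of equal priority and equal load;
simulators are assumed identical and static for the session. Scheduling is
first-come-first-served: each pass of a single-threaded polling loop first
assigns pending simulations, in SimSet order, to the lowest-index
AVAILABLE simulator (pool order = machine insertion order, then slot
index), then polls in-flight jobs. Concurrency lives entirely in the
remote runs, which makes assignment order deterministic and testable by a
brute-force replay oracle over the log. Load balancing is manual, via the
per-machine simulator counts. A simulator that accumulates
`retire_threshold` consecutive failures is retired; if every simulator
retires with work outstanding, the remaining simulations fail with
`no available simulator` rather than hanging.

### Simulation state machine

PENDING → ASSIGNED → STAGED → RUNNING → DOWNLOADING → COMPLETE, with
FAILED reachable from any post-PENDING, non-terminal state. Transitions
are forward-only; rejected transitions leave the state unchanged.

### Completion detection

Job completion is sentinel-based: the remote entry point writes `SUCCESS`
or `FAIL` in its run directory. Two status sources can disagree — the
sentinel and the process exit status — so the generated job script carries
an epilogue that (a) records the exit status in `.exit_status` and (b)
writes the sentinel *from* the exit status only if the entry point wrote
neither. Entry-point sentinels therefore always win (a `FAIL` written by
the payload beats a zero exit status), while bare commands such as `true`
still poll to COMPLETE. A run past `wall_time` plus a grace period
(max(10 s, 10 % of wall time)) is reported TIMEOUT.

### Job-script dialects

One pure renderer produces all three dialects from the same descriptor:
SGE (`#$ -N/-cwd/-q/-pe smp/-o/-e/-l h_rt=HH:MM:SS`), SLURM
(`#SBATCH --job-name/--partition/--ntasks/--output/--error/--time`), and
DIRECT (plain shell with stdout/stderr redirection, launched with
`nohup ... & echo $!`). A queue on a DIRECT machine is ignored with a
`UserWarning`. Rendering is deterministic, so scripts are byte-stable
across runs.

### SimSpec dialect

UTF-8 text; `#` starts a comment to end of line; blank lines ignored;
fields tab-separated; first field the simulation id (non-empty, no
whitespace), remaining fields the free-parameter strings. Parameters are
treated as opaque strings end-to-end — no numeric parsing, no
normalization — so what the sweep author writes is exactly what reaches
the simulator command line and the model templates.

### Templating

Model files are assembled with `{name}` placeholders via Python's
`string.Formatter` (literal braces escaped as `{{ }}`); a missing
placeholder value raises an error naming the placeholder. Channel XML
editing addresses the 8 gate-rate parameters through the grammar
`(gate)(Alpha|Beta)(A|k)` (e.g. `mAlphaA`), edits a deep copy (the input
document is never mutated), and rendering to simulator-core input is a
pluggable transform with the same strict-formatter default.

### Timing metrics

*Session time* spans the first to the last log entry; *SimSet time* spans
the first FetchParameterVector to the last ResultDownload; *overhead* is
their difference (an enforced invariant of `SessionMetrics`). *SimSet
overhead* is SimSet time minus the mean per-simulation execution span
(SimulationExecute → RemotePostProcess), and divided by the pool size
gives the mean overhead per simulator, reported rounded to whole seconds.
Reference arithmetic checked by tests: (3950, 3741) → 209 s;
(1408, 1242) → 166 s; 179 s over 12 simulators → 15 s/simulator.

## Generated inputs (fixtures) and their realism

All test inputs are generated programmatically and deterministically
(`random.Random(seed)`; same seed → byte-identical output):

- **Channel XML** (`make_channel_fixture`): a fast-sodium-style channel
  with m (activation, 3 instances) and h (inactivation) gates, each with
  exponential alpha/beta rates — exactly 8 editable slots — plus a static
  leak. Amplitudes are drawn from 0.1–9000 ms⁻¹ and slopes from
  ±(3–30) mV, the order of magnitude typical of published Na-channel rate
  constants; activation and inactivation get opposite slope signs. The
  document validates against the shipped schema.
- **Model template** (`make_model_template_fixture`): a hoc-style cell
  with soma, smooth-dendrite and spiny-dendrite sections, each carrying
  one anomalous-rectifier density placeholder — the three-parameter
  per-section sweep shape.
- **SimSpec files** (`make_simspec_fixture`): n vectors of k positive
  numeric strings; a configurable rounded fraction get one extra
  parameter (wrong arity) for failure-path tests.
- **Local machine sets** (`make_local_machineset`): local stub machines
  (host = remote, subprocess transport) with configurable slot counts;
  the canonical test pool is 2 + 5 = 7.

These stand in for real NEURON morphologies, NeuroML channel documents and
cluster accounts: they reproduce the *shape* those inputs impose on the
engine (arity, placeholder structure, XML vocabulary, pool geometry), not
their scientific content.

## Numerical and timing choices

- The sine toy samples `sin(2π f t)` at 1000 samples/s over the requested
  duration using only the standard library, writing `repr`-formatted
  floats, so outputs are byte-deterministic across pool sizes — the basis
  of the serial/parallel equivalence tests. Its plot is a hand-written
  SVG polyline for the same reason (no plotting library, no embedded
  timestamps).
- Tests run with a 0.02 s poll interval and sub-second toy runs; the
  defaults (0.5 s poll, 300 s wall time) suit real workloads.
- Directory-name collisions (session dirs, result dirs, snapshots) are
  resolved with numeric suffixes rather than sub-second timestamps, so
  behaviour is deterministic under a frozen test clock.
- Hypothesis runs under a derandomized profile (50 examples, no deadline)
  so CI results are reproducible.

## Problem sizes exercised

Scheduling tests use 20 simulations on 7 simulators (and 5 on 1);
equivalence tests 12 simulations on pools of 1 and 7; templating sessions
2–4 simulations with 3 free parameters; channel tests the full 8-parameter
edit. The acceptance script (`scripts/acceptance.py`) reruns these sizes
end-to-end from a single seed.

## Limitations

- Wall-clock performance numbers depend entirely on hardware and workload;
  only the accounting *arithmetic* is asserted, never absolute times.
- The SSH transport is a thin optional adapter (lazily imported, used only
  when `paramiko` is present) and is not exercised by the test suite; all
  tests run through the local subprocess transport, which shares the same
  interface.
- SGE/SLURM scripts are rendered and (in dry-run form) submitted, but no
  real queueing system is driven in tests; queue-side behaviour
  (accounting, preemption, array jobs) is out of scope.
- The scheduler assumes equal-load simulations and identical simulators;
  there is no work stealing, priority, or dynamic machine discovery.
- The toy simulator families are deliberately tiny; they validate the
  engine's staging, templating, scheduling and provenance, not any
  neuroscience result.
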