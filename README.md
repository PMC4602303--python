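# simbatch

A simulation-management engine for parameter-sweep studies on heterogeneous
machines.

## The problem

Computational studies — a neuron model swept over channel densities, a
signal generator swept over frequencies — need the *same* simulation run
many times with different parameter values, often across several machines:
a local workstation, a departmental server, an SGE or SLURM cluster. Doing
this by hand means copying model files, editing parameter values into
templates, writing job scripts, polling queues, downloading results, and
keeping enough records to later say exactly which inputs produced which
outputs. simbatch automates that loop:

- **SimSets and SimSpecs.** A batch of simulations is an ordered *SimSet*,
  one simulation per *input parameter vector*. A SimSet is written down as
  a *SimSpec*: a tab-separated text file, one line per simulation, first
  field the simulation id, remaining fields the free-parameter strings.
  Parameters stay strings end-to-end; the engine never interprets them.
- **Machine sets and simulators.** Machines (plain Unix hosts, SGE or
  SLURM clusters) are wrapped with transport, job-submission and
  simulator-core location knowledge. Each machine hosts a configured number
  of *simulator* slots; all slots together form the simulator pool.
- **Fixed 22-stage workflow.** Every simulation passes through the same
  22 concrete stages (session init, communications test, simulator build
  and verify, parameter fetch, host-side model processing, file transfer,
  job generation and submission, execution, download, registration, reset,
  reporting, notification), grouped into 9 abstract groups. The activity
  log records every stage with a timestamp.
- **FCFS scheduling.** Pending simulations are assigned, in SimSet order,
  to the lowest-index available simulator; a single host thread polls the
  in-flight jobs. Concurrency lives in the remote runs, so assignment
  order is reproducible.
- **Provenance.** Every session gets a time-stamped directory holding the
  activity log, sha-256-verified snapshots of the SimSpec and of every
  generated model file, a version manifest, per-simulation result
  directories, an HTML status page, and machine- and human-readable final
  reports.
- **Model-file pre-processing.** Simulator families can assemble model
  files from templates per simulation (hoc-style section templates) or
  edit XML channel descriptions and render them to simulator-core input
  (mod-style rate files).
- **XML session documents.** A whole session — SimSet, machine set,
  simulator options, notifications, locations — can be written as one
  schema-validated XML file and transformed deterministically into the
  SimSpec + config artifacts the engine runs from.

## Worked example

A four-simulation frequency sweep of the bundled deterministic sine
simulator on two local "machines" with 2 + 5 simulator slots. The SimSpec
(`sweep.txt`):

```text
# sim_id	frequency_hz	duration_s
run01	1	0.2
run02	2	0.2
run03	4	0.2
run04	0.5	0.2
```

The config (`session.cfg`):

```ini
[session]
name = demo
sim_type = sine01
root = scratch/demo/sessions
poll_interval = 0.05
wall_time = 60

[machines.local1]
machine_type = generic_unix
address = localhost
num_simulators = 2
work_dir = /abs/path/scratch/demo/machine1

[machines.local2]
machine_type = generic_unix
address = localhost
num_simulators = 5
work_dir = /abs/path/scratch/demo/machine2
```

Running it:

```text
$ simbatch run --config session.cfg --simspec sweep.txt
session directory: scratch/demo/sessions/demo_20261002T065639Z
total 4  complete 4  failed 0
session time 0.3 s, SimSet time 0.3 s, overhead 0.0 s
```

The activity log opens with the session-level stages:

```text
$ head -8 scratch/demo/sessions/demo_20261002T065639Z/log/activity.log
2026-10-02T06:56:39.278148+00:00	1	SessionInit	-	session 'demo', sim_type 'sine01', 4 simulation(s)
2026-10-02T06:56:39.280681+00:00	2	HostSetup	-	session directory scratch/demo/sessions/demo_20261002T065639Z
2026-10-02T06:56:39.285976+00:00	3	CommTest	-	local1 ok
2026-10-02T06:56:39.292669+00:00	3	CommTest	-	local2 ok
2026-10-02T06:56:39.292754+00:00	4	NotifyStart	-	SESSION_START
2026-10-02T06:56:39.295634+00:00	5	SimulatorPayloadUpload	-	simulator local11: payload -> .../machine1/simulators/sine01_local11/install
2026-10-02T06:56:39.295703+00:00	6	SimulatorBuild	-	simulator local11: build ok
2026-10-02T06:56:39.295731+00:00	7	SimulatorVerify	-	simulator local11: AVAILABLE
```

and every simulation reached the final stage:

```text
$ simbatch status scratch/demo/sessions/demo_20261002T065639Z
run01	22 NotifyProgress
run02	22 NotifyProgress
run03	22 NotifyProgress
run04	22 NotifyProgress
```

Each result directory holds the simulation outputs, e.g.
`results/run01_20261002T065639Z/sine.csv`:

```text
t,value
0.0,0.0
0.001,0.006283143965558951
0.002,0.012566039883352607
```

The same session as one XML document (`simbatch run-xml session.xml`) is
shown in the test suite (`tests/test_sessionml.py`) and in
`docs/methods.md`.

## Library use

```python
from simbatch.core import parse_simspec
from simbatch.engine import EngineConfig, run_from_simset
from simbatch.fixtures import make_local_machineset

machines = make_local_machineset("scratch/machines", counts=(2, 5))
cfg = EngineConfig(session_name="sweep", sim_type="sine01",
                   root="scratch/sessions", machines=machines)
session = run_from_simset(cfg, parse_simspec("a\t1\t0.2\nb\t2\t0.2\n", "s"))
print(session.metrics.overhead, [r.success for r in session.result.records])
```

## Simulator families

| key         | free parameters                          | pre-processing                       |
|-------------|------------------------------------------|--------------------------------------|
| `sine01`    | 2 (frequency Hz, duration s)             | none; writes `sine.csv` + `sine.svg` |
| `noop01`    | 0                                        | none; optional static `delay`        |
| `khmodel01` | 3 (per-section channel densities)        | hoc-style template assembly          |
| `channel01` | 8 (gate-rate amplitudes and slopes)      | XML channel edit + mod-file render   |

New families register through `simbatch.simulators.register_simtype`; new
machine types through `simbatch.machines.register_machine_type`.

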