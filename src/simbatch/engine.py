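"""The orchestrator: builds the machine set and simulator pool, drives every
simulation through the fixed 22-stage submission workflow, schedules
first-come-first-served, computes timing metrics, and shuts down cleanly.

Workflow
--------
Nine abstract stage groups (general setup; build simulators; upload model
files; fetch parameter vector; upload input data; process model files; run
and post-process; download outputs; post-simulation housekeeping) expand to
22 concrete stages, listed in :data:`STAGES`.  Groups 1-3 run once per
session/simulator; groups 4-9 run once per simulation.

Scheduling
----------
Simulations are presumed independent, of equal priority and equal load, and
are scheduled in SimSet order; simulators are presumed independent,
identical, and static.  Starting at the beginning of the simulator pool,
the first AVAILABLE simulator gets the next pending simulation; as each run
finishes and its simulator is reset, the next pending simulation is placed
on it.  Load balancing is manual, via the per-machine simulator counts.
The event loop is a single host thread polling in-flight runs; concurrency
lives in the remote runs, which keeps the assignment order reproducible.

Timing
------
The *SimSet time* spans the first parameter fetch to the last result
download and covers fetching vectors, running simulations, and moving
files; the *overhead* is the total session time minus the SimSet time.
"""

from __future__ import annotations

import configparser
import time
from dataclasses import dataclass, field
from pathlib import Path, PurePosixPath
from typing import Optional, Sequence

from .core import (SessionResult, SimSet, SimState, Simulation,
                   parse_simspec, summarize, write_simspec)
from .machines import (JobDescriptor, JobHandle, JobStatus, MachineConfig,
                       MachineSetConfig, SubmissionKind, Transport,
                       poll_job, render_job_script, submit_job,
                       test_communications)
from .provenance import (Clock, FileSink, NotificationSink, SessionLedger,
                         create_session_dir, utc_now)
from .simulators import (SimulatorDescriptor, SimulatorInstance,
                         SimulatorState, build_run_command,
                         construct_simulator, download_results,
                         make_descriptor, prerun_model_processing,
                         reset_simulator)

__all__ = [
    "WorkflowStage",
    "STAGES",
    "stage",
    "SessionMetrics",
    "EngineConfig",
    "Session",
    "SessionAbort",
    "load_config",
    "build_machine_set",
    "dispatch_loop",
    "run_session",
    "run_from_simset",
    "compute_metrics",
    "shutdown",
]


# ---------------------------------------------------------------------------
# The 22-stage workflow
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WorkflowStage:
    index: int                    # 1..22
    name: str
    abstract_group: int           # 1..9
    locus: str                    # HOST | REMOTE | BOTH


STAGES: tuple[WorkflowStage, ...] = (
    WorkflowStage(1, "SessionInit", 1, "HOST"),
    WorkflowStage(2, "HostSetup", 1, "HOST"),
    WorkflowStage(3, "CommTest", 1, "BOTH"),
    WorkflowStage(4, "NotifyStart", 1, "HOST"),
    WorkflowStage(5, "SimulatorPayloadUpload", 2, "BOTH"),
    WorkflowStage(6, "SimulatorBuild", 2, "REMOTE"),
    WorkflowStage(7, "SimulatorVerify", 2, "REMOTE"),
    WorkflowStage(8, "ModelFileUpload", 3, "BOTH"),
    WorkflowStage(9, "FetchParameterVector", 4, "HOST"),
    WorkflowStage(10, "InputDataUpload", 5, "BOTH"),
    WorkflowStage(11, "PreRunModelProcessingHost", 6, "HOST"),
    WorkflowStage(12, "ModelFileTransfer", 6, "BOTH"),
    WorkflowStage(13, "PreRunModelProcessingRemote", 6, "REMOTE"),
    WorkflowStage(14, "JobFileGeneration", 7, "HOST"),
    WorkflowStage(15, "JobSubmission", 7, "BOTH"),
    WorkflowStage(16, "SimulationExecute", 7, "REMOTE"),
    WorkflowStage(17, "RemotePostProcess", 7, "REMOTE"),
    WorkflowStage(18, "ResultDownload", 8, "BOTH"),
    WorkflowStage(19, "ResultRegister", 8, "HOST"),
    WorkflowStage(20, "SimulatorReset", 9, "REMOTE"),
    WorkflowStage(21, "ReportUpdate", 9, "HOST"),
    WorkflowStage(22, "NotifyProgress", 9, "HOST"),
)

_BY_NAME = {s.name: s for s in STAGES}


def stage(name: str) -> WorkflowStage:
    return _BY_NAME[name]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class SessionMetrics:
    """Timing accounting for one session, all in seconds."""

    session_time: float
    simset_time: float
    overhead: float
    per_simulation_times: dict[str, float] = field(default_factory=dict)
    simset_overhead: float = 0.0
    mean_overhead_per_simulator: int = 0

    def __post_init__(self) -> None:
        if abs(self.overhead - (self.session_time - self.simset_time)) > 1e-9:
            raise ValueError("overhead must equal session_time - simset_time")

    @classmethod
    def from_times(cls, session_time: float, simset_time: float,
                   mean_execution_time: Optional[float] = None,
                   pool_size: int = 1,
                   per_simulation_times: Optional[dict] = None,
                   ) -> "SessionMetrics":
        """Build metrics from recorded times.

        ``simset_overhead`` is the SimSet time in excess of the mean
        simulation execution time; divided over the pool it gives the mean
        overhead per simulator, reported rounded to whole seconds.
        """
        simset_overhead = (simset_time - mean_execution_time
                           if mean_execution_time is not None else 0.0)
        return cls(
            session_time=session_time,
            simset_time=simset_time,
            overhead=session_time - simset_time,
            per_simulation_times=dict(per_simulation_times or {}),
            simset_overhead=simset_overhead,
            mean_overhead_per_simulator=int(round(simset_overhead
                                                  / max(pool_size, 1))),
        )


def compute_metrics(events: Sequence, pool_size: int = 1) -> SessionMetrics:
    """Derive SessionMetrics from a session's activity-log records.

    Session time spans the first to the last log entry; SimSet time spans
    the first FetchParameterVector to the last ResultDownload; execution
    time per simulation spans SimulationExecute to RemotePostProcess.
    """
    if not events:
        return SessionMetrics.from_times(0.0, 0.0)
    t0, t1 = events[0].timestamp, events[-1].timestamp
    session_time = (t1 - t0).total_seconds()
    fetches = [e.timestamp for e in events
               if e.stage_name == "FetchParameterVector"]
    downloads = [e.timestamp for e in events
                 if e.stage_name == "ResultDownload"]
    simset_time = ((max(downloads) - min(fetches)).total_seconds()
                   if fetches and downloads else 0.0)
    per_sim: dict[str, float] = {}
    exec_spans: list[float] = []
    by_sim: dict[str, dict[str, object]] = {}
    for e in events:
        if e.sim_id is not None:
            by_sim.setdefault(e.sim_id, {})[e.stage_name] = e.timestamp
    for sim_id, stamps in by_sim.items():
        if "FetchParameterVector" in stamps and "ResultDownload" in stamps:
            per_sim[sim_id] = (stamps["ResultDownload"]
                               - stamps["FetchParameterVector"]
                               ).total_seconds()
        if "SimulationExecute" in stamps and "RemotePostProcess" in stamps:
            exec_spans.append((stamps["RemotePostProcess"]
                               - stamps["SimulationExecute"]).total_seconds())
    mean_exec = sum(exec_spans) / len(exec_spans) if exec_spans else None
    return SessionMetrics.from_times(
        session_time, simset_time, mean_execution_time=mean_exec,
        pool_size=pool_size, per_simulation_times=per_sim)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class EngineConfig:
    session_name: str
    sim_type: str
    root: str
    machines: MachineSetConfig = field(default_factory=MachineSetConfig)
    simulator_options: dict = field(default_factory=dict)
    simspec: Optional[str] = None
    poll_interval: float = 0.5
    wall_time: float = 300.0
    retire_threshold: int = 3
    dry_run: bool = False
    notify_file: Optional[str] = None
    notify_events: tuple[str, ...] = ()
    notify_scope: str = "global"


def load_config(path: Path) -> EngineConfig:
    """Read an engine config file: INI-style key-value text with sections
    ``[session]``, ``[machines.<name>]``, ``[simulator.<simtype>]`` and an
    optional ``[notify]``."""
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    if "session" not in cp:
        raise ValueError(f"config {path} has no [session] section")
    s = cp["session"]
    cfg = EngineConfig(
        session_name=s.get("name", "session"),
        sim_type=s["sim_type"],
        root=s["root"],
        simspec=s.get("simspec") or None,
        poll_interval=s.getfloat("poll_interval", 0.5),
        wall_time=s.getfloat("wall_time", 300.0),
        retire_threshold=s.getint("retire_threshold", 3),
    )
    for section in cp.sections():
        if section.startswith("machines."):
            m = cp[section]
            simcores = {k.split(".", 1)[1]: v for k, v in m.items()
                        if k.startswith("simcore.")}
            job_defaults = {}
            if m.get("queue"):
                job_defaults["queue"] = m["queue"]
            if m.get("job_wall_time"):
                job_defaults["wall_time"] = m["job_wall_time"]
            cfg.machines.add_machine(
                m["machine_type"],
                m.getint("num_simulators"),
                m["work_dir"],
                name=section.split(".", 1)[1],
                address=m.get("address", "localhost"),
                simcore_paths=simcores,
                job_defaults=job_defaults,
            )
        elif section.startswith("simulator."):
            if section.split(".", 1)[1] == cfg.sim_type:
                cfg.simulator_options.update(cp[section])
    if "notify" in cp:
        n = cp["notify"]
        cfg.notify_file = n.get("file") or None
        cfg.notify_events = tuple(
            e.strip() for e in n.get("events", "").split(",") if e.strip())
        cfg.notify_scope = n.get("scope", "global")
    return cfg


def dump_config(cfg: EngineConfig) -> str:
    """Serialize an EngineConfig to the INI config format (inverse of
    :func:`load_config` for the fields the XML session transform emits)."""
    cp = configparser.ConfigParser()
    cp["session"] = {
        "name": cfg.session_name,
        "sim_type": cfg.sim_type,
        "root": cfg.root,
        "poll_interval": str(cfg.poll_interval),
        "wall_time": str(cfg.wall_time),
    }
    if cfg.simspec:
        cp["session"]["simspec"] = cfg.simspec
    for m in cfg.machines.entries:
        sec = f"machines.{m.name}"
        cp[sec] = {
            "machine_type": m.machine_type,
            "address": m.address,
            "num_simulators": str(m.num_simulators),
            "work_dir": m.work_dir,
        }
        if m.job_defaults.get("queue"):
            cp[sec]["queue"] = m.job_defaults["queue"]
        if m.job_defaults.get("wall_time"):
            cp[sec]["job_wall_time"] = str(m.job_defaults["wall_time"])
    if cfg.simulator_options:
        cp[f"simulator.{cfg.sim_type}"] = {
            k: str(v) for k, v in cfg.simulator_options.items()}
    if cfg.notify_file:
        cp["notify"] = {"file": cfg.notify_file,
                        "events": ",".join(cfg.notify_events),
                        "scope": cfg.notify_scope}
    import io
    buf = io.StringIO()
    cp.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Session
# ---------------------------------------------------------------------------

class SessionAbort(RuntimeError):
    pass


@dataclass
class Session:
    config: EngineConfig
    session_dir: Path
    ledger: SessionLedger
    descriptor: SimulatorDescriptor
    simset: Optional[SimSet] = None
    pool: list[SimulatorInstance] = field(default_factory=list)
    transports: dict[str, Transport] = field(default_factory=dict)
    result: Optional[SessionResult] = None
    metrics: Optional[SessionMetrics] = None
    aborted: bool = False
    _shutdown_done: bool = False

    def log(self, stage_name: str, sim_id: Optional[str], detail: str):
        return self.ledger.log_event(stage(stage_name), sim_id, detail)


def _start_session(config: EngineConfig, clock: Clock,
                   sinks: Optional[Sequence[NotificationSink]]) -> Session:
    descriptor = make_descriptor(config.sim_type, config.simulator_options)
    session_dir = create_session_dir(Path(config.root), clock,
                                     name=config.session_name)
    if sinks is None:
        sinks = []
        if config.notify_file:
            sinks.append(FileSink(session_dir / config.notify_file))
    ledger = SessionLedger(session_dir, clock=clock, sinks=sinks)
    return Session(config=config, session_dir=session_dir, ledger=ledger,
                   descriptor=descriptor)


def build_machine_set(msconfig: MachineSetConfig,
                      descriptor: SimulatorDescriptor,
                      transports: dict[str, Transport],
                      session: Optional[Session] = None,
                      ) -> list[SimulatorInstance]:
    """Construct the simulator pool: for each machine, in insertion order,
    ``num_simulators`` instances in slot order.  Failed constructions are
    RETIRED and excluded from dispatch but reported; zero usable simulators
    aborts the session."""
    if not msconfig.entries:
        raise SessionAbort("machine set is empty")
    pool: list[SimulatorInstance] = []
    for machine in msconfig.entries:
        transport = transports[machine.name]
        for slot in range(1, machine.num_simulators + 1):
            inst = construct_simulator(descriptor, machine, transport,
                                       slot=slot)
            if session is not None:
                session.log("SimulatorPayloadUpload", None,
                            f"simulator {inst.simulator_id}: payload -> "
                            f"{inst.install_dir}")
                session.log("SimulatorBuild", None,
                            f"simulator {inst.simulator_id}: "
                            + ("build ok" if not descriptor.build_command
                               else ("build ok" if inst.state is not
                                     SimulatorState.RETIRED else "build failed"))
                            )
                session.log("SimulatorVerify", None,
                            f"simulator {inst.simulator_id}: {inst.state.name}")
            pool.append(inst)
    if all(i.state is not SimulatorState.AVAILABLE for i in pool):
        raise SessionAbort(
            "no simulator could be constructed; build logs: "
            + "; ".join(f"{i.simulator_id}: {i.build_log.strip()}"
                        for i in pool))
    return pool


# ---------------------------------------------------------------------------
# Dispatch (FCFS)
# ---------------------------------------------------------------------------

@dataclass
class _InFlight:
    simulation: Simulation
    instance: SimulatorInstance
    handle: JobHandle
    generated_files: list[Path]


def _fail(session: Session, sim: Simulation, reason: str) -> None:
    if sim.state is SimState.PENDING:
        sim.advance(SimState.ASSIGNED)
    sim.advance(SimState.FAILED, reason)


def _job_descriptor(session: Session, sim: Simulation,
                    inst: SimulatorInstance) -> JobDescriptor:
    defaults = inst.machine.job_defaults
    return JobDescriptor(
        job_name=f"sb_{sim.sim_id}",
        command=build_run_command(inst, sim.ipv),
        wall_time=float(defaults.get("wall_time",
                                     session.config.wall_time)),
        queue=defaults.get("queue", ""),
    )


def _assign(session: Session, sim: Simulation,
            inst: SimulatorInstance) -> Optional[_InFlight]:
    """Run stages 9-16 for one simulation on one simulator.  Returns the
    in-flight record, or None if the simulation failed before submission."""
    clock = session.ledger.clock
    sim.advance(SimState.ASSIGNED)
    sim.simulator_id = inst.simulator_id
    inst.state = SimulatorState.BUSY

    def slog(name: str, detail: str) -> None:
        rec = session.log(name, sim.sim_id, detail)
        sim.stage_timestamps[name] = rec.timestamp

    slog("FetchParameterVector",
         f"params={list(sim.ipv.params)!r} -> simulator {inst.simulator_id}")
    slog("InputDataUpload", "no input data files")
    workspace = session.session_dir / "workspace" / sim.sim_id
    try:
        generated = prerun_model_processing(session.descriptor, sim.ipv,
                                            workspace)
        slog("PreRunModelProcessingHost",
             f"generated {[p.name for p in generated]}")
        if generated:
            session.ledger.snapshot_inputs(generated, prefix=sim.sim_id)
    except Exception as exc:
        slog("PreRunModelProcessingHost", f"error: {exc}")
        _finish_failed_before_submit(session, sim, inst, str(exc))
        return None
    try:
        for f in generated:
            inst.transport.upload(
                f, str(PurePosixPath(inst.run_dir) / f.name))
        slog("ModelFileTransfer",
             f"{len(generated)} file(s) -> {inst.run_dir}")
    except Exception as exc:
        slog("ModelFileTransfer", f"error: {exc}")
        _finish_failed_before_submit(session, sim, inst, f"transfer: {exc}")
        return None
    slog("PreRunModelProcessingRemote", "no remote pre-processing")
    sim.advance(SimState.STAGED)

    desc = _job_descriptor(session, sim, inst)
    script = render_job_script(desc, inst.machine.submission_kind)
    slog("JobFileGeneration",
         f"{inst.machine.submission_kind.value} job script, "
         f"wall_time={desc.wall_time}s")
    try:
        handle = submit_job(inst.transport, script, desc, inst.run_dir,
                            kind=inst.machine.submission_kind,
                            dry_run=session.config.dry_run)
    except Exception as exc:
        slog("JobSubmission", f"error: {exc}")
        sim.advance(SimState.FAILED, f"submission: {exc}")
        _register_outcome(session, sim, inst)
        return None
    if session.config.dry_run:
        slog("JobSubmission", f"dry-run: {handle.dry_run_command}")
        sim.advance(SimState.FAILED, "dry-run (not executed)")
        _register_outcome(session, sim, inst)
        return None
    slog("JobSubmission",
         f"{inst.machine.submission_kind.value} job id {handle.job_id}")
    sim.advance(SimState.RUNNING)
    slog("SimulationExecute", "running on remote")
    return _InFlight(sim, inst, handle, list(generated))


def _finish_failed_before_submit(session: Session, sim: Simulation,
                                 inst: SimulatorInstance,
                                 reason: str) -> None:
    sim.advance(SimState.FAILED, reason)
    _register_outcome(session, sim, inst)


def _register_outcome(session: Session, sim: Simulation,
                      inst: SimulatorInstance) -> None:
    """Stages 20-22 plus failure bookkeeping for one finished simulation."""
    failed = sim.state is SimState.FAILED
    if failed:
        inst.consecutive_failures += 1
    else:
        inst.consecutive_failures = 0
    if sim.result_dir is None:
        # failures keep a result directory holding whatever was retrieved
        rd = session.session_dir / "results" / f"{sim.sim_id}_failed"
        rd.mkdir(parents=True, exist_ok=True)
        (rd / "FAILURE_REASON.txt").write_text(
            (sim.failure_reason or "unknown") + "\n")
        sim.result_dir = str(rd)
    retire = (inst.consecutive_failures
              >= session.config.retire_threshold)
    try:
        if retire:
            inst.state = SimulatorState.RETIRED
            detail = (f"simulator {inst.simulator_id} RETIRED after "
                      f"{inst.consecutive_failures} consecutive failures")
        else:
            reset_simulator(inst, inst.transport)
            detail = f"simulator {inst.simulator_id} reset, AVAILABLE"
    except Exception as exc:
        detail = f"simulator {inst.simulator_id} reset failed, RETIRED: {exc}"
    rec = session.log("SimulatorReset", sim.sim_id, detail)
    sim.stage_timestamps["SimulatorReset"] = rec.timestamp
    session.ledger.render_status_page(session.simset, _pool_summary(session))
    session.log("ReportUpdate", sim.sim_id, "status page regenerated")
    event = ("SIMULATION_COMPLETE" if sim.state is SimState.COMPLETE
             else "SIMULATION_FAILED")
    if event in session.config.notify_events:
        session.ledger.notify(event, scope=session.config.notify_scope,
                              sim_id=sim.sim_id,
                              message=sim.failure_reason or "complete",
                              attachments=[sim.result_dir]
                              if sim.result_dir else [])
    session.log("NotifyProgress", sim.sim_id,
                f"{event} ({'dispatched' if event in session.config.notify_events else 'no sink configured'})")


def _complete_run(session: Session, flight: _InFlight,
                  status: JobStatus) -> None:
    """Stages 17-19: remote post-processing, download, registration."""
    sim, inst = flight.simulation, flight.instance

    def slog(name: str, detail: str) -> None:
        rec = session.log(name, sim.sim_id, detail)
        sim.stage_timestamps[name] = rec.timestamp

    slog("RemotePostProcess", f"job finished: {status.value}")
    sim.advance(SimState.DOWNLOADING)
    try:
        result_dir = download_results(inst, sim, inst.transport,
                                      session.session_dir,
                                      clock=session.ledger.clock)
        slog("ResultDownload", f"-> {result_dir}")
    except Exception as exc:
        slog("ResultDownload", f"error: {exc}")
        sim.advance(SimState.FAILED, f"download: {exc}")
        _register_outcome(session, sim, inst)
        return
    if status is JobStatus.COMPLETE:
        missing = [o for o in session.descriptor.declared_outputs
                   if not (Path(result_dir) / o).exists()]
        if missing:
            slog("ResultRegister", f"missing declared outputs: {missing}")
            sim.advance(SimState.FAILED,
                        f"missing declared outputs: {missing}")
        else:
            slog("ResultRegister", "all declared outputs present")
            sim.advance(SimState.COMPLETE)
    else:
        reason = flight.handle.last_error or status.value
        fail_file = Path(result_dir) / "FAIL"
        if fail_file.is_file():
            remote_reason = fail_file.read_text().strip()
            if remote_reason:
                reason = remote_reason
        slog("ResultRegister", f"failed run registered: {reason}")
        sim.advance(SimState.FAILED, reason)
    _register_outcome(session, sim, inst)


def _pool_summary(session: Session) -> str:
    counts: dict[str, int] = {}
    for inst in session.pool:
        counts[inst.state.name] = counts.get(inst.state.name, 0) + 1
    per_machine = {}
    for inst in session.pool:
        per_machine.setdefault(inst.machine.name, 0)
        per_machine[inst.machine.name] += 1
    return (f"pool of {len(session.pool)} simulators "
            f"({', '.join(f'{m}: {n}' for m, n in per_machine.items())}); "
            f"states: {counts}")


def dispatch_loop(pool: list[SimulatorInstance], simset: SimSet,
                  session: Session) -> SessionResult:
    """Drive every simulation to COMPLETE or FAILED with FCFS scheduling.

    Each pass first assigns pending simulations, in SimSet order, to the
    lowest-index AVAILABLE simulators, then polls the in-flight runs and
    finishes any that are done.  The loop sleeps ``poll_interval`` between
    passes that made no progress.
    """
    session.simset = simset
    pending = list(simset.simulations)
    next_i = 0
    in_flight: dict[str, _InFlight] = {}
    while next_i < len(pending) or in_flight:
        progressed = False
        # assignment pass: SimSet order onto lowest-index available slots
        for inst in pool:
            if next_i >= len(pending):
                break
            if inst.state is not SimulatorState.AVAILABLE:
                continue
            sim = pending[next_i]
            next_i += 1
            progressed = True
            flight = _assign(session, sim, inst)
            if flight is not None:
                in_flight[sim.sim_id] = flight
        # poll pass
        for sim_id in list(in_flight):
            flight = in_flight[sim_id]
            status = poll_job(flight.handle)
            if status in (JobStatus.COMPLETE, JobStatus.FAILED,
                          JobStatus.TIMEOUT):
                del in_flight[sim_id]
                _complete_run(session, flight, status)
                progressed = True
        if next_i < len(pending) and not in_flight and \
                all(i.state is not SimulatorState.AVAILABLE for i in pool):
            # every simulator retired with work outstanding: fail the rest
            for sim in pending[next_i:]:
                session.log("FetchParameterVector", sim.sim_id,
                            "no available simulator")
                _fail(session, sim, "no available simulator")
                _register_outcome_min(session, sim)
            next_i = len(pending)
            break
        if not progressed:
            time.sleep(session.config.poll_interval)
    result = SessionResult.from_simset(simset)
    session.result = result
    return result


def _register_outcome_min(session: Session, sim: Simulation) -> None:
    rd = session.session_dir / "results" / f"{sim.sim_id}_failed"
    rd.mkdir(parents=True, exist_ok=True)
    (rd / "FAILURE_REASON.txt").write_text(
        (sim.failure_reason or "unknown") + "\n")
    sim.result_dir = str(rd)


# ---------------------------------------------------------------------------
# Full session
# ---------------------------------------------------------------------------

def run_from_simset(config: EngineConfig, simset: SimSet,
                    clock: Clock = utc_now,
                    sinks: Optional[Sequence[NotificationSink]] = None,
                    ) -> Session:
    """Execute the 22 stages in order over an in-memory SimSet."""
    session = _start_session(config, clock, sinks)
    cfg = session.config
    session.log("SessionInit",
                None, f"session {cfg.session_name!r}, sim_type "
                f"{cfg.sim_type!r}, {len(simset)} simulation(s)")
    # snapshot the SimSpec (writing it first if the set came in-memory)
    simspec_path = Path(cfg.simspec) if cfg.simspec else None
    if simspec_path is None or not simspec_path.is_file():
        simspec_path = session.session_dir / "simset.txt"
        simspec_path.write_text(write_simspec(simset), encoding="utf-8")
    session.ledger.snapshot_inputs([simspec_path])
    session.ledger.record_versions({
        f"sim_type.{session.descriptor.sim_type}":
            session.descriptor.version,
        "machine_registry": _machine_registry_digest(cfg.machines),
    })
    (session.session_dir / "workspace").mkdir(exist_ok=True)
    session.log("HostSetup", None,
                f"session directory {session.session_dir}")

    usable = MachineSetConfig()
    for machine in cfg.machines.entries:
        try:
            transport = machine.make_transport()
            diagnostics = test_communications(machine, transport)
        except Exception as exc:
            diagnostics = [f"{machine.name}: transport: {exc}"]
        if diagnostics:
            session.log("CommTest", None,
                        f"{machine.name} EXCLUDED: {'; '.join(diagnostics)}")
            continue
        session.log("CommTest", None, f"{machine.name} ok")
        session.transports[machine.name] = transport
        usable.entries.append(machine)
    if not usable.entries:
        session.log("CommTest", None, "no usable machines, aborting")
        session.aborted = True
        shutdown(session)
        raise SessionAbort("communications test failed on every machine")

    if session.ledger.sinks and (
            not cfg.notify_events or "SESSION_START" in cfg.notify_events):
        session.ledger.notify("SESSION_START",
                              message=f"session {cfg.session_name}")
    session.log("NotifyStart", None, "SESSION_START")

    try:
        session.pool = build_machine_set(usable, session.descriptor,
                                         session.transports, session)
    except SessionAbort:
        session.aborted = True
        shutdown(session)
        raise
    n_static = len(session.descriptor.model_files)
    session.log("ModelFileUpload", None,
                f"{n_static} model template(s) registered host-side"
                if n_static else "no static model files")

    dispatch_loop(session.pool, simset, session)
    session.metrics = compute_metrics(session.ledger.events,
                                      pool_size=len(session.pool))
    shutdown(session)
    return session


def run_session(config: EngineConfig, simspec_path: Optional[Path] = None,
                clock: Clock = utc_now,
                sinks: Optional[Sequence[NotificationSink]] = None,
                ) -> Session:
    """Run a full session from a SimSpec file (the run-from-file form)."""
    path = Path(simspec_path or config.simspec)
    simset = parse_simspec(path.read_text(encoding="utf-8"), path.stem)
    config.simspec = str(path)
    return run_from_simset(config, simset, clock=clock, sinks=sinks)


def _machine_registry_digest(machines: MachineSetConfig) -> str:
    import hashlib
    text = ";".join(
        f"{m.name},{m.machine_type},{m.address},{m.work_dir},"
        f"{m.num_simulators}" for m in machines.entries)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def shutdown(session: Session) -> Path:
    """Housekeeping: clean remote scratch on all reachable machines, write
    the final report, and finalize the status page.  Idempotent; an
    unreachable machine yields a warning entry, never an error."""
    report_path = session.session_dir / "reports" / "final_report.json"
    if session._shutdown_done:
        return report_path
    session._shutdown_done = True
    for inst in session.pool:
        try:
            inst.transport.remove_tree(inst.run_dir)
        except Exception as exc:
            session.log("ReportUpdate", None,
                        f"warning: cleanup failed on "
                        f"{inst.simulator_id}: {exc}")
    counts = summarize(session.result) if session.result else \
        {"n_total": 0, "n_complete": 0, "n_failed": 0}
    report = {
        "session": session.config.session_name,
        "aborted": session.aborted,
        **counts,
        "version_manifest": str(session.session_dir / "versions.txt"),
        "metrics": None,
    }
    if session.metrics is not None:
        report["metrics"] = {
            "session_time": session.metrics.session_time,
            "simset_time": session.metrics.simset_time,
            "overhead": session.metrics.overhead,
            "simset_overhead": session.metrics.simset_overhead,
            "mean_overhead_per_simulator":
                session.metrics.mean_overhead_per_simulator,
        }
    import json
    report_path.write_text(json.dumps(report, indent=2), encoding="utf-8")
    if session.result is not None:
        (session.session_dir / "reports" / "result.csv").write_text(
            session.result.to_csv(), encoding="utf-8")
        (session.session_dir / "reports" / "result.json").write_text(
            session.result.to_json(), encoding="utf-8")
    session.ledger.render_status_page(session.simset,
                                      _pool_summary(session))
    if "SESSION_END" in session.config.notify_events or session.aborted:
        if session.ledger.sinks:
            session.ledger.notify("SESSION_END",
                                  message="aborted" if session.aborted
                                  else "complete")
    return report_path
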