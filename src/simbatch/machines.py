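"""Execution machines: configuration, transports, and job submission.

A machine is an execution resource reached through a :class:`Transport`
(local filesystem/shell, or SSH), with a *submission kind* saying how jobs
are started there: DIRECT (a background process on the machine), SGE
(``qsub`` on a Sun/Univa Grid Engine cluster), or SLURM (``sbatch``).
Queue identity, core/node counts, wall time, and other job characteristics
are carried by a :class:`JobDescriptor` and written into the job script for
the user.

Job completion is detected through sentinel files: the remote entry point
writes ``SUCCESS`` or ``FAIL`` into its run directory, and the generated
job script additionally records the command's exit status (writing the
sentinel itself if the entry point wrote neither).  This works identically
for direct and queued jobs without scheduler-specific status parsing.
"""

from __future__ import annotations

import enum
import shlex
import shutil
import subprocess
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path, PurePosixPath
from typing import Optional

__all__ = [
    "SubmissionKind",
    "JobStatus",
    "JobDescriptor",
    "Transport",
    "LocalTransport",
    "SSHTransport",
    "MachineConfig",
    "MachineSetConfig",
    "JobHandle",
    "MACHINE_TYPES",
    "register_machine_type",
    "render_job_script",
    "submit_job",
    "poll_job",
    "test_communications",
]

SUCCESS_SENTINEL = "SUCCESS"
FAIL_SENTINEL = "FAIL"
EXIT_STATUS_FILE = ".exit_status"


class SubmissionKind(enum.Enum):
    DIRECT = "DIRECT"
    SGE = "SGE"
    SLURM = "SLURM"


class JobStatus(enum.Enum):
    QUEUED = "QUEUED"
    RUNNING = "RUNNING"
    COMPLETE = "COMPLETE"
    FAILED = "FAILED"
    TIMEOUT = "TIMEOUT"


@dataclass(frozen=True)
class JobDescriptor:
    """Everything needed to write one job script."""

    job_name: str
    command: str
    wall_time: float = 300.0          # seconds
    queue: str = ""                   # SGE queue / SLURM partition
    cores_or_nodes: int = 1
    stdout_path: str = "stdout.txt"
    stderr_path: str = "stderr.txt"
    parallel_env: str = "smp"         # SGE -pe environment
    extra_directives: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.wall_time <= 0:
            raise ValueError("wall_time must be > 0")
        if not self.command:
            raise ValueError("command must be non-empty")
        if self.cores_or_nodes < 1:
            raise ValueError("cores_or_nodes must be >= 1")
        object.__setattr__(self, "extra_directives",
                           tuple(self.extra_directives))


# ---------------------------------------------------------------------------
# Transports
# ---------------------------------------------------------------------------

class TransportError(RuntimeError):
    pass


class Transport:
    """Contract for host <-> machine communications and file transfer.

    Invariants: upload followed by download yields byte-identical content;
    mkdir is idempotent.
    """

    def run_command(self, cmd: str) -> tuple[int, str, str]:
        raise NotImplementedError

    def upload(self, local: Path, remote: str) -> None:
        raise NotImplementedError

    def download(self, remote: str, local: Path) -> None:
        raise NotImplementedError

    def mkdir(self, path: str) -> None:
        raise NotImplementedError

    def exists(self, path: str) -> bool:
        raise NotImplementedError

    def listdir(self, path: str) -> list[str]:
        raise NotImplementedError

    def remove_tree(self, path: str) -> None:
        raise NotImplementedError


class LocalTransport(Transport):
    """Transport where the "remote" is the host filesystem and shell."""

    def run_command(self, cmd: str) -> tuple[int, str, str]:
        proc = subprocess.run(["/bin/sh", "-c", cmd],
                              capture_output=True, text=True)
        return proc.returncode, proc.stdout, proc.stderr

    def upload(self, local: Path, remote: str) -> None:
        dest = Path(remote)
        dest.parent.mkdir(parents=True, exist_ok=True)
        shutil.copyfile(local, dest)
        shutil.copymode(local, dest)

    def download(self, remote: str, local: Path) -> None:
        local = Path(local)
        local.parent.mkdir(parents=True, exist_ok=True)
        shutil.copyfile(remote, local)

    def mkdir(self, path: str) -> None:
        Path(path).mkdir(parents=True, exist_ok=True)

    def exists(self, path: str) -> bool:
        return Path(path).exists()

    def listdir(self, path: str) -> list[str]:
        return sorted(p.name for p in Path(path).iterdir())

    def remove_tree(self, path: str) -> None:
        if Path(path).exists():
            shutil.rmtree(path)


class SSHTransport(Transport):
    """SSH2/SFTP transport for genuinely remote machines.

    Thin adapter over paramiko (imported lazily); authentication is
    key-based, with the passphrase resolved once at session start so no
    user intervention is needed afterwards.
    """

    def __init__(self, address: str, username: str,
                 key_path: Optional[str] = None,
                 passphrase: Optional[str] = None):
        try:
            import paramiko  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise TransportError(
                "SSHTransport requires the 'paramiko' package"
            ) from exc
        import paramiko
        self._client = paramiko.SSHClient()
        self._client.set_missing_host_key_policy(paramiko.AutoAddPolicy())
        self._client.connect(address, username=username,
                             key_filename=key_path, passphrase=passphrase)
        self._sftp = self._client.open_sftp()

    def run_command(self, cmd):  # pragma: no cover - needs a live host
        _, stdout, stderr = self._client.exec_command(cmd)
        rc = stdout.channel.recv_exit_status()
        return rc, stdout.read().decode(), stderr.read().decode()

    def upload(self, local, remote):  # pragma: no cover
        self._sftp.put(str(local), remote)

    def download(self, remote, local):  # pragma: no cover
        Path(local).parent.mkdir(parents=True, exist_ok=True)
        self._sftp.get(remote, str(local))

    def mkdir(self, path):  # pragma: no cover
        self.run_command(f"mkdir -p {shlex.quote(path)}")

    def exists(self, path):  # pragma: no cover
        rc, _, _ = self.run_command(f"test -e {shlex.quote(path)}")
        return rc == 0

    def listdir(self, path):  # pragma: no cover
        return sorted(self._sftp.listdir(path))

    def remove_tree(self, path):  # pragma: no cover
        self.run_command(f"rm -rf {shlex.quote(path)}")


# ---------------------------------------------------------------------------
# Machine configuration
# ---------------------------------------------------------------------------

#: machine_type registry key -> default submission kind
MACHINE_TYPES: dict[str, SubmissionKind] = {
    "generic_unix": SubmissionKind.DIRECT,
    "sge_cluster": SubmissionKind.SGE,
    "slurm_cluster": SubmissionKind.SLURM,
}


def register_machine_type(key: str, submission_kind: SubmissionKind) -> None:
    MACHINE_TYPES[key] = submission_kind


@dataclass
class MachineConfig:
    """One execution resource in the Machine Set."""

    machine_type: str
    num_simulators: int
    work_dir: str
    name: str = ""
    address: str = "localhost"
    auth_ref: Optional[str] = None
    submission_kind: SubmissionKind = SubmissionKind.DIRECT
    simcore_paths: dict[str, str] = field(default_factory=dict)
    job_defaults: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.num_simulators < 1:
            raise ValueError("num_simulators must be >= 1")
        if not PurePosixPath(self.work_dir).is_absolute():
            raise ValueError(f"work_dir must be absolute: {self.work_dir!r}")
        if not self.name:
            self.name = self.machine_type

    def make_transport(self) -> Transport:
        if self.address in ("localhost", "127.0.0.1", ""):
            return LocalTransport()
        user, _, host = self.address.rpartition("@")
        return SSHTransport(host or self.address, user or "",
                            key_path=self.auth_ref)


@dataclass
class MachineSetConfig:
    """Ordered set of machines; insertion order defines the pool order."""

    entries: list[MachineConfig] = field(default_factory=list)

    def add_machine(self, machine_type: str, num_simulators: int,
                    work_dir: str, *, name: str = "",
                    address: str = "localhost",
                    simcore_paths: Optional[dict[str, str]] = None,
                    job_defaults: Optional[dict[str, str]] = None,
                    auth_ref: Optional[str] = None) -> "MachineSetConfig":
        """Append a machine; rejects unknown types, non-positive simulator
        counts, and duplicate (address, work_dir) pairs."""
        if machine_type not in MACHINE_TYPES:
            raise KeyError(f"unknown machine_type {machine_type!r}; "
                           f"registered: {sorted(MACHINE_TYPES)}")
        for e in self.entries:
            if (e.address, e.work_dir) == (address, work_dir):
                raise ValueError(
                    f"duplicate machine (address, work_dir): "
                    f"({address!r}, {work_dir!r})")
        cfg = MachineConfig(
            machine_type=machine_type,
            num_simulators=num_simulators,
            work_dir=work_dir,
            name=name or f"{machine_type}{len(self.entries) + 1}",
            address=address,
            auth_ref=auth_ref,
            submission_kind=MACHINE_TYPES[machine_type],
            simcore_paths=dict(simcore_paths or {}),
            job_defaults=dict(job_defaults or {}),
        )
        self.entries.append(cfg)
        return self

    @property
    def capacity(self) -> int:
        """Total simulator-pool capacity across all machines."""
        return sum(e.num_simulators for e in self.entries)


# ---------------------------------------------------------------------------
# Job scripts
# ---------------------------------------------------------------------------

def _hms(seconds: float) -> str:
    s = int(round(seconds))
    return f"{s // 3600:02d}:{(s % 3600) // 60:02d}:{s % 60:02d}"


# Epilogue shared by all script kinds: record the exit status and make sure
# exactly one sentinel exists (the entry point's own sentinel wins).
_EPILOGUE = """rc=$?
if [ ! -e {success} ] && [ ! -e {fail} ]; then
  if [ $rc -eq 0 ]; then : > {success}; else echo "exit status $rc" > {fail}; fi
fi
echo $rc > {exit_file}
""".format(success=SUCCESS_SENTINEL, fail=FAIL_SENTINEL,
           exit_file=EXIT_STATUS_FILE)


def render_job_script(desc: JobDescriptor, kind: SubmissionKind) -> str:
    """Render the job script for one run; a pure function of its inputs.

    SGE scripts get one ``#$`` directive per set field, SLURM scripts one
    ``#SBATCH`` directive each; DIRECT scripts are plain shell.  The script
    runs with the run directory as working directory.
    """
    lines = ["#!/bin/sh", f"# job: {desc.job_name}"]
    if kind is SubmissionKind.SGE:
        lines += [
            f"#$ -N {desc.job_name}",
            "#$ -cwd",
        ]
        if desc.queue:
            lines.append(f"#$ -q {desc.queue}")
        if desc.cores_or_nodes > 1:
            lines.append(f"#$ -pe {desc.parallel_env} {desc.cores_or_nodes}")
        lines += [
            f"#$ -o {desc.stdout_path}",
            f"#$ -e {desc.stderr_path}",
            f"#$ -l h_rt={_hms(desc.wall_time)}",
        ]
        lines += list(desc.extra_directives)
        lines.append(desc.command)
    elif kind is SubmissionKind.SLURM:
        lines += [f"#SBATCH --job-name={desc.job_name}"]
        if desc.queue:
            lines.append(f"#SBATCH --partition={desc.queue}")
        lines += [
            f"#SBATCH --ntasks={desc.cores_or_nodes}",
            f"#SBATCH --output={desc.stdout_path}",
            f"#SBATCH --error={desc.stderr_path}",
            f"#SBATCH --time={_hms(desc.wall_time)}",
        ]
        lines += list(desc.extra_directives)
        lines.append(desc.command)
    else:
        if desc.queue:
            warnings.warn(
                f"queue {desc.queue!r} is ignored for DIRECT submission",
                UserWarning, stacklevel=2)
        lines.append(
            f"( {desc.command} ) > {desc.stdout_path} 2> {desc.stderr_path}")
    return "\n".join(lines) + "\n" + _EPILOGUE


# ---------------------------------------------------------------------------
# Submission and polling
# ---------------------------------------------------------------------------

@dataclass
class JobHandle:
    descriptor: JobDescriptor
    kind: SubmissionKind
    run_dir: str
    transport: Optional[Transport] = None
    job_id: Optional[str] = None          # queue job id or local pid
    submitted_at: float = 0.0             # monotonic seconds
    grace: float = 10.0
    poll_retries: int = 3
    dry_run_command: Optional[str] = None
    last_error: Optional[str] = None
    clock: object = time.monotonic


class SubmissionError(RuntimeError):
    def __init__(self, message: str, stderr: str = ""):
        super().__init__(message)
        self.stderr = stderr


_SUBMIT_COMMANDS = {
    SubmissionKind.SGE: "qsub",
    SubmissionKind.SLURM: "sbatch",
}


def submit_job(transport: Transport, script_text: str, desc: JobDescriptor,
               run_dir: str, kind: SubmissionKind = SubmissionKind.DIRECT,
               dry_run: bool = False) -> JobHandle:
    """Upload the job script into ``run_dir`` and start it.

    DIRECT: the script is started as a background process and its exit
    status captured via the script epilogue.  SGE/SLURM: the submission
    command (``qsub``/``sbatch`` plus script path) is issued and the
    returned job id is parsed into the handle.  In dry-run mode the exact
    submission command string is returned unexecuted and nothing is
    uploaded.
    """
    script_path = str(PurePosixPath(run_dir) / "job.sh")
    qdir, qscript = shlex.quote(run_dir), shlex.quote(script_path)
    if kind is SubmissionKind.DIRECT:
        submit_cmd = (f"cd {qdir} && nohup sh {qscript} "
                      f">/dev/null 2>&1 & echo $!")
    else:
        submit_cmd = (f"cd {qdir} && {_SUBMIT_COMMANDS[kind]} {qscript}")

    handle = JobHandle(descriptor=desc, kind=kind, run_dir=run_dir,
                       grace=max(10.0, 0.1 * desc.wall_time))
    if dry_run:
        handle.dry_run_command = submit_cmd
        return handle

    if not transport.exists(run_dir):
        raise SubmissionError(f"run directory does not exist: {run_dir}")
    import tempfile
    with tempfile.NamedTemporaryFile("w", suffix=".sh", delete=False) as fh:
        fh.write(script_text)
        local_script = fh.name
    try:
        transport.upload(Path(local_script), script_path)
    finally:
        Path(local_script).unlink(missing_ok=True)

    rc, out, err = transport.run_command(submit_cmd)
    if rc != 0:
        raise SubmissionError(
            f"job submission failed with exit status {rc}", stderr=err)
    handle.transport = transport
    handle.job_id = _parse_job_id(out, kind)
    handle.submitted_at = handle.clock()
    return handle


def _parse_job_id(stdout: str, kind: SubmissionKind) -> str:
    # qsub: "Your job 12345 (...) has been submitted"
    # sbatch: "Submitted batch job 12345"; DIRECT: echoed pid
    for tok in stdout.split():
        if tok.isdigit():
            return tok
    return stdout.strip()


def poll_job(handle: JobHandle) -> JobStatus:
    """Check one in-flight job: sentinel files first, then exit status, then
    the wall-time deadline.  Transport failures are retried up to
    ``handle.poll_retries`` times, then reported as FAILED."""
    if handle.dry_run_command is not None:
        return JobStatus.QUEUED
    rd = PurePosixPath(handle.run_dir)
    last_exc: Optional[Exception] = None
    for _ in range(handle.poll_retries):
        try:
            if handle.transport.exists(str(rd / FAIL_SENTINEL)):
                handle.last_error = "FAIL sentinel present"
                return JobStatus.FAILED
            if handle.transport.exists(str(rd / SUCCESS_SENTINEL)):
                return JobStatus.COMPLETE
            if handle.transport.exists(str(rd / EXIT_STATUS_FILE)):
                # epilogue ran but wrote no sentinel; exit status decides
                _, out, _ = handle.transport.run_command(
                    f"cat {shlex.quote(str(rd / EXIT_STATUS_FILE))}")
                rc = int(out.strip() or "1")
                if rc != 0:
                    handle.last_error = f"exit status {rc}"
                    return JobStatus.FAILED
                return JobStatus.COMPLETE
            break
        except Exception as exc:  # transport hiccup
            last_exc = exc
    else:
        handle.last_error = f"transport failure during poll: {last_exc}"
        return JobStatus.FAILED
    elapsed = handle.clock() - handle.submitted_at
    if elapsed > handle.descriptor.wall_time + handle.grace:
        handle.last_error = "wall time exceeded"
        return JobStatus.TIMEOUT
    return JobStatus.RUNNING


def test_communications(config: MachineConfig,
                        transport: Transport) -> list[str]:
    """Verify a machine is usable: shell echo works, the work directory is
    creatable and writable, and every simcore path exists.  Returns a list
    of diagnostics; empty means ok."""
    diagnostics: list[str] = []
    try:
        rc, out, _ = transport.run_command("echo simbatch-ping")
        if rc != 0 or "simbatch-ping" not in out:
            diagnostics.append(f"{config.name}: echo test failed (rc={rc})")
    except Exception as exc:
        diagnostics.append(f"{config.name}: command transport failed: {exc}")
        return diagnostics
    probe = str(PurePosixPath(config.work_dir) / ".simbatch_probe")
    try:
        transport.mkdir(config.work_dir)
        rc, _, err = transport.run_command(
            f": > {shlex.quote(probe)} && rm -f {shlex.quote(probe)}")
        if rc != 0:
            diagnostics.append(
                f"{config.name}: work_dir not writable: {config.work_dir}"
                f" ({err.strip()})")
    except Exception as exc:
        diagnostics.append(
            f"{config.name}: work_dir not creatable: {config.work_dir}"
            f" ({exc})")
    for core, path in sorted(config.simcore_paths.items()):
        if not transport.exists(path):
            diagnostics.append(
                f"{config.name}: simcore {core!r} path missing: {path}")
    return diagnostics
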