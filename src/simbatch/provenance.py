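"""Session provenance: time-stamped directories, activity log, snapshots,
version manifest, status page, and notifications.

Every session gets its own time/date-stamped directory holding all program
output and simulation results.  The ledger keeps a detailed, append-only
activity log; copies of the input parameter vector file and of every
dynamically constructed or modified model file (with sha-256 digests so the
copies are verifiable); a manifest of all related software versions; and a
record of every notification dispatched.

All timestamps are UTC, ISO-8601.  Directory-name collisions are resolved
with numeric suffixes rather than sub-second precision so behaviour is
deterministic under a frozen test clock.
"""

from __future__ import annotations

import hashlib
import html
import json
import platform
import shutil
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from . import __version__
from .core import SimSet, SimState

__all__ = [
    "Clock",
    "utc_now",
    "SessionLedger",
    "LogRecord",
    "Snapshot",
    "NotificationSink",
    "FileSink",
    "create_session_dir",
    "parse_log",
    "sha256_file",
]

Clock = Callable[[], datetime]

NOTIFY_EVENTS = ("SESSION_START", "SIMULATION_COMPLETE", "SIMULATION_FAILED",
                 "SESSION_END")

_TS_FMT = "%Y%m%dT%H%M%SZ"


def utc_now() -> datetime:
    return datetime.now(timezone.utc)


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def unique_path(parent: Path, base: str) -> Path:
    """``parent/base``, or ``parent/base_N`` on collision (N = 1, 2, ...)."""
    cand = parent / base
    n = 0
    while cand.exists():
        n += 1
        cand = parent / f"{base}_{n}"
    return cand


def create_session_dir(root: Path, clock: Clock = utc_now,
                       name: str = "session") -> Path:
    """Create ``<root>/<name>_<UTC timestamp>/`` with the standard subdirs.

    Two calls within the same second get ``_1``, ``_2`` ... suffixes.
    """
    root = Path(root)
    if not root.exists():
        root.mkdir(parents=True)
    stamp = clock().strftime(_TS_FMT)
    session_dir = unique_path(root, f"{name}_{stamp}")
    session_dir.mkdir()
    for sub in ("log", "snapshots", "results", "reports"):
        (session_dir / sub).mkdir()
    return session_dir


@dataclass(frozen=True)
class LogRecord:
    timestamp: datetime
    stage_index: int
    stage_name: str
    sim_id: Optional[str]
    detail: str


@dataclass(frozen=True)
class Snapshot:
    original: str
    stored: str
    digest: str


class NotificationSink:
    """Interface for notification transports (e-mail, SMS, file, ...)."""

    name = "sink"

    def send(self, event: str, scope: str, sim_id: Optional[str],
             message: str, attachments: Sequence[str] = ()) -> None:
        raise NotImplementedError


class FileSink(NotificationSink):
    """Appends one JSON line per notification to a file; the test transport."""

    name = "file"

    def __init__(self, path: Path):
        self.path = Path(path)

    def send(self, event, scope, sim_id, message, attachments=()):
        rec = {
            "event": event,
            "scope": scope,
            "sim_id": sim_id,
            "message": message,
            "attachments": list(attachments),
        }
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(rec) + "\n")


class SessionLedger:
    """The provenance record for one session."""

    def __init__(self, session_dir: Path, clock: Clock = utc_now,
                 sinks: Sequence[NotificationSink] = ()):
        self.session_dir = Path(session_dir)
        self.clock = clock
        self.log_path = self.session_dir / "log" / "activity.log"
        self.snapshots: list[Snapshot] = []
        self.version_manifest: dict[str, str] = {}
        self.notification_log: list[dict] = []
        self.sinks = list(sinks)
        self._events: list[LogRecord] = []

    # -- activity log ------------------------------------------------------

    def log_event(self, stage, sim_id: Optional[str], detail: str) -> LogRecord:
        """Append one tab-separated line: timestamp, stage idx, stage name,
        sim_id or "-", detail.  The log file is append-only."""
        detail = detail.replace("\t", " ").replace("\n", " ")
        rec = LogRecord(self.clock(), stage.index, stage.name, sim_id, detail)
        line = "\t".join([
            rec.timestamp.isoformat(),
            str(rec.stage_index),
            rec.stage_name,
            sim_id if sim_id is not None else "-",
            detail,
        ])
        with open(self.log_path, "a", encoding="utf-8") as fh:
            fh.write(line + "\n")
        self._events.append(rec)
        return rec

    @property
    def events(self) -> list[LogRecord]:
        return list(self._events)

    # -- snapshots ---------------------------------------------------------

    def snapshot_inputs(self, files: Iterable[Path],
                        prefix: Optional[str] = None) -> list[Snapshot]:
        """Copy input files under snapshots/ and record sha-256 digests.

        Provenance is mandatory: a missing file raises (the engine turns
        that into a session abort).  Name collisions are resolved by
        prefixing with ``prefix`` (typically the sim_id), then suffixing.
        """
        out: list[Snapshot] = []
        snapdir = self.session_dir / "snapshots"
        for f in files:
            f = Path(f)
            if not f.is_file():
                raise FileNotFoundError(f"cannot snapshot missing file: {f}")
            base = f.name
            if (snapdir / base).exists() and prefix:
                base = f"{prefix}_{base}"
            dest = unique_path(snapdir, base)
            shutil.copyfile(f, dest)
            snap = Snapshot(str(f), str(dest), sha256_file(dest))
            self.snapshots.append(snap)
            out.append(snap)
        return out

    def verify_snapshots(self) -> list[Snapshot]:
        """Return the snapshots whose stored copy no longer matches its digest."""
        return [s for s in self.snapshots
                if sha256_file(Path(s.stored)) != s.digest]

    # -- version manifest ----------------------------------------------------

    def record_versions(self, components: dict[str, str]) -> Path:
        """Write the version manifest: engine version, each sim_type version
        used, host platform, machine-registry digest, plus ``components``."""
        self.version_manifest = {
            "engine": __version__,
            "host_platform": platform.platform(),
            **components,
        }
        manifest = self.session_dir / "versions.txt"
        with open(manifest, "w", encoding="utf-8") as fh:
            for k, v in sorted(self.version_manifest.items()):
                fh.write(f"{k}={v}\n")
        return manifest

    # -- status page -------------------------------------------------------

    def render_status_page(self, simset: Optional[SimSet],
                           pool_summary: str = "") -> Path:
        """Regenerate the static status page listing every simulation's state."""
        rows = []
        if simset is not None:
            for sim in simset:
                started = sim.stage_timestamps.get("FetchParameterVector")
                ended = max(sim.stage_timestamps.values()) \
                    if sim.stage_timestamps else None
                elapsed = ""
                if started is not None and ended is not None:
                    elapsed = f"{(ended - started).total_seconds():.1f}"
                link = ""
                if sim.result_dir:
                    link = (f'<a href="{html.escape(sim.result_dir)}">'
                            f'{html.escape(Path(sim.result_dir).name)}</a>')
                rows.append(
                    "<tr>"
                    f"<td>{html.escape(sim.sim_id)}</td>"
                    f"<td>{sim.state.name}</td>"
                    f"<td>{html.escape(sim.simulator_id or '')}</td>"
                    f"<td>{elapsed}</td>"
                    f"<td>{link}</td>"
                    "</tr>"
                )
        page = (
            "<!DOCTYPE html>\n<html><head><title>Session status</title></head>"
            "<body>\n"
            f"<p>{html.escape(pool_summary)}</p>\n"
            "<table>\n<tr><th>sim_id</th><th>state</th><th>simulator</th>"
            "<th>elapsed (s)</th><th>results</th></tr>\n"
            + "\n".join(rows)
            + "\n</table>\n</body></html>\n"
        )
        path = self.session_dir / "reports" / "status.html"
        path.write_text(page, encoding="utf-8")
        return path

    # -- notifications -----------------------------------------------------

    def notify(self, event: str, scope: str = "global",
               sim_id: Optional[str] = None, message: str = "",
               attachments: Sequence[str] = ()) -> list[dict]:
        """Dispatch an event to every configured sink.

        A failing sink is logged and never aborts the session.  Every
        dispatch (and failure) is mirrored into the notification log.
        """
        if event not in NOTIFY_EVENTS:
            raise ValueError(f"unknown notification event {event!r}")
        dispatched = []
        for sink in self.sinks:
            rec = {
                "event": event, "scope": scope, "sim_id": sim_id,
                "sink": sink.name, "ok": True,
            }
            try:
                sink.send(event, scope, sim_id, message, attachments)
            except Exception as exc:  # sink failure must not kill the session
                rec["ok"] = False
                rec["error"] = str(exc)
            self.notification_log.append(rec)
            dispatched.append(rec)
        return dispatched


def parse_log(text: str) -> list[LogRecord]:
    """Parse activity-log text back into its event sequence (round-trip
    inverse of :meth:`SessionLedger.log_event`)."""
    records = []
    for line in text.splitlines():
        if not line.strip():
            continue
        ts, idx, name, sim_id, detail = line.split("\t", 4)
        records.append(LogRecord(
            timestamp=datetime.fromisoformat(ts),
            stage_index=int(idx),
            stage_name=name,
            sim_id=None if sim_id == "-" else sim_id,
            detail=detail,
        ))
    return records
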