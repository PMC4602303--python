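"""Core domain types: parameter vectors, simulations, SimSets, session results.

A *SimSet* is an ordered batch of simulations, one per *input parameter
vector* (IPV).  An IPV is an ordered list of free-parameter **strings** —
the engine never interprets them numerically; units and meaning belong to
the simulator that consumes them.  SimSets are written down as *SimSpec*
text files, one vector per line.

SimSpec dialect
---------------
UTF-8 text; fields are tab-separated; ``#`` starts a comment running to end
of line; blank lines are ignored.  The first field of a line is the
simulation id, the remaining fields are the parameters.  There is no
quoting dialect, so a parameter may contain spaces but never a tab or a
line break.
"""

from __future__ import annotations

import csv
import enum
import io
import json
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional

__all__ = [
    "SimState",
    "InputParameterVector",
    "Simulation",
    "SimSet",
    "SimRecord",
    "SessionResult",
    "SimSpecError",
    "parse_simspec",
    "write_simspec",
    "summarize",
]

FIELD_SEP = "\t"
COMMENT_CHAR = "#"


class SimSpecError(ValueError):
    """Raised for malformed SimSpec text or unserializable SimSets."""


class SimState(enum.Enum):
    """Lifecycle of a single simulation.

    States advance strictly in the order below; FAILED is reachable from
    any state after PENDING.  No transition moves backwards.
    """

    PENDING = 0
    ASSIGNED = 1
    STAGED = 2
    RUNNING = 3
    DOWNLOADING = 4
    COMPLETE = 5
    FAILED = 6

    @property
    def terminal(self) -> bool:
        return self in (SimState.COMPLETE, SimState.FAILED)


# Forward transitions only; FAILED allowed from anything past PENDING.
def _transition_allowed(src: SimState, dst: SimState) -> bool:
    if src.terminal:
        return False
    if dst is SimState.FAILED:
        return src is not SimState.PENDING
    return dst.value == src.value + 1 and dst is not SimState.FAILED


@dataclass(frozen=True)
class InputParameterVector:
    """One simulation's identity plus its ordered free-parameter strings."""

    sim_id: str
    params: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sim_id or any(c.isspace() for c in self.sim_id):
            raise ValueError(
                f"sim_id must be non-empty with no whitespace: {self.sim_id!r}"
            )
        object.__setattr__(self, "params", tuple(self.params))
        for p in self.params:
            if "\n" in p or "\r" in p:
                raise ValueError(f"parameter contains a line break: {p!r}")

    @property
    def arity(self) -> int:
        return len(self.params)


@dataclass
class Simulation:
    """One run of a simulator with a specific parameter vector."""

    ipv: InputParameterVector
    state: SimState = SimState.PENDING
    simulator_id: Optional[str] = None
    result_dir: Optional[str] = None
    failure_reason: Optional[str] = None
    stage_timestamps: dict[str, datetime] = field(default_factory=dict)

    @property
    def sim_id(self) -> str:
        return self.ipv.sim_id

    def advance(self, dst: SimState, reason: Optional[str] = None) -> None:
        """Move to ``dst``, enforcing the forward-only state machine."""
        if not _transition_allowed(self.state, dst):
            raise ValueError(
                f"illegal transition {self.state.name} -> {dst.name} "
                f"for simulation {self.sim_id!r}"
            )
        self.state = dst
        if dst is SimState.FAILED:
            self.failure_reason = reason or "unspecified"


@dataclass
class SimSet:
    """Ordered batch of simulations; list order is the scheduling order."""

    name: str
    simulations: list[Simulation] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sim in self.simulations:
            if sim.sim_id in seen:
                raise ValueError(f"duplicate sim_id in SimSet: {sim.sim_id!r}")
            seen.add(sim.sim_id)

    def __len__(self) -> int:
        return len(self.simulations)

    def __iter__(self):
        return iter(self.simulations)

    @property
    def sim_ids(self) -> list[str]:
        return [s.sim_id for s in self.simulations]


@dataclass(frozen=True)
class SimRecord:
    sim_id: str
    result_location: Optional[str]
    success: bool
    failure_reason: Optional[str] = None


@dataclass
class SessionResult:
    """Per-simulation outcome record for one session.

    Exactly one record per simulation in the SimSet, in SimSet order;
    ``success`` is true iff the simulation finished COMPLETE.
    """

    records: list[SimRecord] = field(default_factory=list)

    @classmethod
    def from_simset(cls, simset: SimSet) -> "SessionResult":
        recs = []
        for sim in simset:
            if not sim.state.terminal:
                raise ValueError(f"simulation {sim.sim_id!r} is not terminal")
            recs.append(
                SimRecord(
                    sim_id=sim.sim_id,
                    result_location=sim.result_dir,
                    success=sim.state is SimState.COMPLETE,
                    failure_reason=sim.failure_reason,
                )
            )
        return cls(records=recs)

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["sim_id", "result_location", "success", "failure_reason"])
        for r in self.records:
            w.writerow(
                [r.sim_id, r.result_location or "", str(r.success).lower(),
                 r.failure_reason or ""]
            )
        return buf.getvalue()

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "sim_id": r.sim_id,
                    "result_location": r.result_location,
                    "success": r.success,
                    "failure_reason": r.failure_reason,
                }
                for r in self.records
            ],
            indent=2,
        )


def parse_simspec(text: str, name: str) -> SimSet:
    """Parse SimSpec text into a SimSet of PENDING simulations.

    One simulation per non-comment, non-blank line, in file order.  The
    first tab-separated field is the sim_id; the rest are parameters.  A
    lone sim_id yields an empty parameter list.  A duplicate sim_id is
    rejected naming the offending line.
    """
    sims: list[Simulation] = []
    seen: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(COMMENT_CHAR, 1)[0].strip()
        if not line:
            continue
        fields = line.split(FIELD_SEP)
        sim_id, params = fields[0], fields[1:]
        if not sim_id:
            raise SimSpecError(f"line {lineno}: empty sim_id field")
        if sim_id in seen:
            raise SimSpecError(
                f"line {lineno}: duplicate sim_id {sim_id!r} "
                f"(first seen on line {seen[sim_id]})"
            )
        seen[sim_id] = lineno
        try:
            ipv = InputParameterVector(sim_id=sim_id, params=tuple(params))
        except ValueError as exc:
            raise SimSpecError(f"line {lineno}: {exc}") from exc
        sims.append(Simulation(ipv=ipv))
    return SimSet(name=name, simulations=sims)


def write_simspec(simset: SimSet) -> str:
    """Serialize a SimSet to SimSpec text (inverse of :func:`parse_simspec`).

    Rejects any parameter containing the tab field separator, since the
    dialect has no quoting.
    """
    lines = [f"{COMMENT_CHAR} SimSpec: {simset.name}"]
    for sim in simset:
        for p in sim.ipv.params:
            if FIELD_SEP in p:
                raise SimSpecError(
                    f"parameter contains the field separator (tab): {p!r} "
                    f"in simulation {sim.sim_id!r}"
                )
            if COMMENT_CHAR in p:
                raise SimSpecError(
                    f"parameter contains the comment character: {p!r} "
                    f"in simulation {sim.sim_id!r}"
                )
        lines.append(FIELD_SEP.join([sim.sim_id, *sim.ipv.params]))
    return "\n".join(lines) + "\n"


def summarize(result: SessionResult) -> dict[str, int]:
    """Count totals over a session result: n_total = n_complete + n_failed."""
    n_complete = sum(1 for r in result.records if r.success)
    return {
        "n_total": len(result.records),
        "n_complete": n_complete,
        "n_failed": len(result.records) - n_complete,
    }
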