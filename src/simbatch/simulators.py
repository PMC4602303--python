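"""Simulator lifecycle and the simulator-type registry.

A *simulator* is a constructed slot on a machine: its payload (the remote
entry point plus supporting files) is uploaded once, an optional build
command is run once, and the slot then cycles AVAILABLE <-> BUSY, executing
one simulation at a time.  A *SimType* registry key identifies one concrete
simulator configuration (entry point, static parameters, model files, free
parameters); new behaviour gets a new key, giving a usable track of
simulator evolution, and the descriptor's version string is recorded in
provenance.

Three families ship in-repo, mirroring common usage:

* ``sine01``  — a no-model toy: two free parameters (frequency, duration),
  samples a sine wave on the remote.
* ``khmodel01`` — a model-file simulator: assembles a hoc-style model file
  from a template on the host, inserting per-simulation Kh channel
  densities into the soma, smooth-dendrite, and spiny-dendrite sections.
* ``channel01`` — an XML-channel-editing simulator: edits eight gate-rate
  free parameters in a channel document, renders it to mod-format text,
  and ships the result to the remote.
"""

from __future__ import annotations

import copy
import json
import re
import shlex
import string
import sys
import tempfile
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path, PurePosixPath
from typing import Callable, Optional

from lxml import etree

from .core import InputParameterVector, Simulation
from .machines import MachineConfig, Transport
from .payloads import payload_path
from .provenance import Clock, unique_path, utc_now

__all__ = [
    "SimulatorState",
    "ModelFileSpec",
    "SimulatorDescriptor",
    "SimulatorInstance",
    "SIMTYPES",
    "register_simtype",
    "make_descriptor",
    "construct_simulator",
    "prerun_model_processing",
    "edit_channel_xml",
    "render_channel_to_simcore_input",
    "build_run_command",
    "download_results",
    "reset_simulator",
    "ModelProcessingError",
    "ChannelEditError",
]

_TS_FMT = "%Y%m%dT%H%M%SZ"


class SimulatorState(Enum):
    CONSTRUCTING = "CONSTRUCTING"
    AVAILABLE = "AVAILABLE"
    BUSY = "BUSY"
    RETIRED = "RETIRED"


class ModelProcessingError(ValueError):
    pass


class ChannelEditError(ValueError):
    pass


@dataclass(frozen=True)
class ModelFileSpec:
    """A model file assembled from a template before each run.

    The template uses ``{name}`` placeholders (literal braces doubled),
    filled from the simulator's static parameters and the simulation's free
    parameters.
    """

    template: str          # host path of the template
    output_name: str       # file name written into the per-run workspace


@dataclass(frozen=True)
class SimulatorDescriptor:
    """Full definition of one simulator type."""

    sim_type: str
    entry_point: str                       # payload file name run remotely
    version: str = "1"
    static_params: dict = field(default_factory=dict)
    payload_files: tuple[str, ...] = ()    # host paths, incl. entry point
    model_files: tuple[ModelFileSpec, ...] = ()
    simcore_name: str = "python"
    build_command: Optional[str] = None
    n_free_params: int = 0
    free_param_names: tuple[str, ...] = ()
    declared_outputs: tuple[str, ...] = ()
    pre_hook: Optional[str] = None         # name in HOOKS
    post_hook: Optional[str] = None
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "payload_files", tuple(self.payload_files))
        object.__setattr__(self, "model_files", tuple(self.model_files))
        entries = [p for p in self.payload_files
                   if Path(p).name == self.entry_point]
        if len(entries) != 1:
            raise ValueError(
                f"payload must include exactly one entry point "
                f"{self.entry_point!r}; got {self.payload_files}")
        if self.free_param_names and \
                len(self.free_param_names) != self.n_free_params:
            raise ValueError("free_param_names length != n_free_params")


@dataclass
class SimulatorInstance:
    """A constructed simulator slot on one machine."""

    simulator_id: str
    machine: MachineConfig
    descriptor: SimulatorDescriptor
    transport: Transport
    install_dir: str
    run_dir: str
    state: SimulatorState = SimulatorState.CONSTRUCTING
    build_log: str = ""
    consecutive_failures: int = 0


# ---------------------------------------------------------------------------
# SimType registry
# ---------------------------------------------------------------------------

#: sim_type key -> factory(options: dict) -> SimulatorDescriptor
SIMTYPES: dict[str, Callable[[dict], SimulatorDescriptor]] = {}


def register_simtype(key: str,
                     factory: Callable[[dict], SimulatorDescriptor]) -> None:
    SIMTYPES[key] = factory


def make_descriptor(sim_type: str,
                    options: Optional[dict] = None) -> SimulatorDescriptor:
    if sim_type not in SIMTYPES:
        raise KeyError(f"unknown sim_type {sim_type!r}; "
                       f"registered: {sorted(SIMTYPES)}")
    return SIMTYPES[sim_type](dict(options or {}))


def _data_path(name: str) -> Path:
    return Path(str(resources.files("simbatch") / "data" / name))


def _sine_factory(options: dict) -> SimulatorDescriptor:
    return SimulatorDescriptor(
        sim_type="sine01",
        version="1.0",
        entry_point="sine_entry.py",
        payload_files=(str(payload_path("sine_entry.py")),),
        static_params={"sample_rate": options.get("sample_rate", "1000")},
        n_free_params=2,
        free_param_names=("frequency", "duration"),
        declared_outputs=("sine.csv", "sine.svg"),
        options=options,
    )


def _noop_factory(options: dict) -> SimulatorDescriptor:
    return SimulatorDescriptor(
        sim_type="noop01",
        version="1.0",
        entry_point="noop_entry.py",
        payload_files=(str(payload_path("noop_entry.py")),),
        static_params={"delay": options.get("delay", "0")},
        n_free_params=0,
        options=options,
    )


def _khmodel_factory(options: dict) -> SimulatorDescriptor:
    template = options.get("template")
    if not template:
        raise ValueError("khmodel01 requires a 'template' option "
                         "(host path of the hoc-style model template)")
    return SimulatorDescriptor(
        sim_type="khmodel01",
        version="1.0",
        entry_point="model_entry.py",
        payload_files=(str(payload_path("model_entry.py")),),
        model_files=(ModelFileSpec(template=str(template),
                                   output_name="purkinje.hoc"),),
        n_free_params=3,
        free_param_names=("kh_soma", "kh_smooth", "kh_spiny"),
        declared_outputs=("kh_summary.json", "kh_summary.csv"),
        options=options,
    )


CHANNEL_FREE_PARAMS = ("mAlphaA", "mAlphak", "mBetaA", "mBetak",
                       "hAlphaA", "hAlphak", "hBetaA", "hBetak")


def _channel_factory(options: dict) -> SimulatorDescriptor:
    channel = options.get("channel")
    if not channel:
        raise ValueError("channel01 requires a 'channel' option "
                         "(host path of the channel XML document)")
    options.setdefault("mod_template", str(_data_path("naf_template.mod")))
    return SimulatorDescriptor(
        sim_type="channel01",
        version="1.0",
        entry_point="channel_entry.py",
        payload_files=(str(payload_path("channel_entry.py")),),
        n_free_params=8,
        free_param_names=CHANNEL_FREE_PARAMS,
        declared_outputs=("rates.json",),
        pre_hook="channel_xml_edit",
        options=options,
    )


register_simtype("sine01", _sine_factory)
register_simtype("noop01", _noop_factory)
register_simtype("khmodel01", _khmodel_factory)
register_simtype("channel01", _channel_factory)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def simcore_command(desc: SimulatorDescriptor, machine: MachineConfig) -> str:
    """The interpreter/engine path used to run the entry point on this
    machine; falls back to the host interpreter (host == remote case)."""
    return machine.simcore_paths.get(desc.simcore_name, sys.executable)


def construct_simulator(desc: SimulatorDescriptor, machine: MachineConfig,
                        transport: Transport, slot: int = 1,
                        machine_index: int = 1) -> SimulatorInstance:
    """Build one simulator slot: create its directories under the machine's
    work directory, upload the payload, write the static parameters, and
    run the build command if any.  A failed build retires the instance with
    the build log attached instead of raising."""
    simulator_id = f"{machine.name}{slot}"
    base = PurePosixPath(machine.work_dir) / "simulators" / \
        f"{desc.sim_type}_{simulator_id}"
    inst = SimulatorInstance(
        simulator_id=simulator_id,
        machine=machine,
        descriptor=desc,
        transport=transport,
        install_dir=str(base / "install"),
        run_dir=str(base / "run"),
    )
    transport.mkdir(inst.install_dir)
    transport.mkdir(inst.run_dir)
    for payload in desc.payload_files:
        transport.upload(Path(payload),
                         str(PurePosixPath(inst.install_dir) /
                             Path(payload).name))
    with tempfile.NamedTemporaryFile("w", suffix=".json",
                                     delete=False) as fh:
        json.dump(desc.static_params, fh)
        tmp = fh.name
    try:
        transport.upload(Path(tmp), str(PurePosixPath(inst.install_dir) /
                                        "static_params.json"))
    finally:
        Path(tmp).unlink(missing_ok=True)

    if desc.build_command:
        cmd = desc.build_command.format(
            install_dir=inst.install_dir,
            simcore=simcore_command(desc, machine))
        rc, out, err = transport.run_command(
            f"cd {shlex.quote(inst.install_dir)} && {cmd}")
        inst.build_log = out + err
        if rc != 0:
            inst.state = SimulatorState.RETIRED
            return inst
    entry = str(PurePosixPath(inst.install_dir) / desc.entry_point)
    if not transport.exists(entry):
        inst.state = SimulatorState.RETIRED
        inst.build_log += f"\nentry point missing after construction: {entry}"
        return inst
    inst.state = SimulatorState.AVAILABLE
    return inst


# ---------------------------------------------------------------------------
# Pre-run model processing (host side)
# ---------------------------------------------------------------------------

class _StrictFormatter(string.Formatter):
    def get_value(self, key, args, kwargs):
        if isinstance(key, str) and key not in kwargs:
            raise ModelProcessingError(
                f"template placeholder {{{key}}} has no matching parameter")
        return super().get_value(key, args, kwargs)


def assemble_template(template_text: str, mapping: dict) -> str:
    """Expand ``{name}`` placeholders; ``{{``/``}}`` are literal braces.
    A placeholder with no matching parameter raises, naming it."""
    return _StrictFormatter().vformat(template_text, (), dict(mapping))


#: named pre/post hooks: name -> fn(desc, ipv, workspace) -> list[Path]
HOOKS: dict[str, Callable] = {}


def prerun_model_processing(desc: SimulatorDescriptor,
                            ipv: InputParameterVector,
                            workspace: Path) -> list[Path]:
    """Assemble this simulation's model files on the host.

    Each model file is built from its template with the simulation-specific
    substitutions (static parameters plus the free parameters bound to this
    input parameter vector) and written under ``workspace``.  Simulators
    with a pre-hook (e.g. XML channel editing) delegate to it.  Returns the
    generated files, which the engine snapshots for provenance.
    """
    workspace = Path(workspace)
    if desc.pre_hook:
        return HOOKS[desc.pre_hook](desc, ipv, workspace)
    if not desc.model_files:
        return []
    if ipv.arity != desc.n_free_params:
        raise ModelProcessingError(
            f"simulation {ipv.sim_id!r} has {ipv.arity} parameters, "
            f"simulator {desc.sim_type!r} expects {desc.n_free_params}")
    mapping = {**desc.static_params,
               **dict(zip(desc.free_param_names, ipv.params))}
    workspace.mkdir(parents=True, exist_ok=True)
    out: list[Path] = []
    for spec in desc.model_files:
        text = Path(spec.template).read_text(encoding="utf-8")
        dest = workspace / spec.output_name
        dest.write_text(assemble_template(text, mapping), encoding="utf-8")
        out.append(dest)
    return out


# ---------------------------------------------------------------------------
# XML channel editing
# ---------------------------------------------------------------------------

_PARAM_RE = re.compile(r"^([a-z]+)(Alpha|Beta)([Ak])$")
_KIND = {"Alpha": "alpha", "Beta": "beta"}


def _resolve_rate(root, name: str):
    m = _PARAM_RE.match(name)
    if not m:
        raise ChannelEditError(f"unparseable channel parameter name {name!r}")
    gate_name, kind, attr = m.group(1), _KIND[m.group(2)], m.group(3)
    rate = root.find(f"gate[@name='{gate_name}']/rate[@kind='{kind}']")
    if rate is None:
        raise ChannelEditError(
            f"parameter {name!r} declared but absent from document "
            f"(gate {gate_name!r}, {kind} rate)")
    return rate, attr


def edit_channel_xml(doc, assignments: dict) -> "etree._ElementTree":
    """Return a copy of the channel document with each named gate-rate
    attribute set to its assigned value string; everything else unchanged.

    Parameter names follow the ``<gate><Alpha|Beta><A|k>`` grammar, e.g.
    ``mAlphaA`` is the A constant of gate m's forward (alpha) rate.
    """
    tree = doc if hasattr(doc, "getroot") else etree.ElementTree(doc)
    new = copy.deepcopy(tree)
    root = new.getroot()
    for name, value in assignments.items():
        rate, attr = _resolve_rate(root, name)
        rate.set(attr, str(value))
    return new


def read_channel_param(doc, name: str) -> str:
    tree = doc if hasattr(doc, "getroot") else etree.ElementTree(doc)
    rate, attr = _resolve_rate(tree.getroot(), name)
    value = rate.get(attr)
    if value is None:
        raise ChannelEditError(f"attribute {attr!r} missing for {name!r}")
    return value


def channel_param_names(doc) -> list[str]:
    """All editable free-parameter slot names exposed by a channel document."""
    tree = doc if hasattr(doc, "getroot") else etree.ElementTree(doc)
    names = []
    for gate in tree.getroot().findall("gate"):
        for rate in gate.findall("rate"):
            kind = "Alpha" if rate.get("kind") == "alpha" else "Beta"
            for attr in ("A", "k"):
                names.append(f"{gate.get('name')}{kind}{attr}")
    return names


def render_channel_to_simcore_input(doc, template_text: str,
                                    transform: Optional[Callable] = None
                                    ) -> str:
    """Render an (edited) channel document to simulator-core input text.

    The default transform is template expansion over the document's
    gate-rate values; ``transform(doc, template_text) -> str`` may be
    supplied to delegate to an external stylesheet processor instead.
    """
    if transform is not None:
        return transform(doc, template_text)
    tree = doc if hasattr(doc, "getroot") else etree.ElementTree(doc)
    mapping = {name: read_channel_param(tree, name)
               for name in channel_param_names(tree)}
    try:
        return assemble_template(template_text, mapping)
    except ModelProcessingError as exc:
        raise ModelProcessingError(
            f"channel document is missing a value the template requires: "
            f"{exc}") from exc


def _channel_edit_hook(desc: SimulatorDescriptor, ipv: InputParameterVector,
                       workspace: Path) -> list[Path]:
    if ipv.arity != desc.n_free_params:
        raise ModelProcessingError(
            f"simulation {ipv.sim_id!r} has {ipv.arity} parameters, "
            f"simulator {desc.sim_type!r} expects {desc.n_free_params}")
    assignments = dict(zip(desc.free_param_names, ipv.params))
    unknown = set(assignments) - set(desc.free_param_names)
    if unknown:
        raise ChannelEditError(f"unknown parameter names: {sorted(unknown)}")
    doc = etree.parse(desc.options["channel"])
    edited = edit_channel_xml(doc, assignments)
    template_text = Path(desc.options["mod_template"]).read_text(
        encoding="utf-8")
    mod_text = render_channel_to_simcore_input(edited, template_text)
    workspace = Path(workspace)
    workspace.mkdir(parents=True, exist_ok=True)
    xml_out = workspace / "channel.xml"
    edited.write(str(xml_out), xml_declaration=True, encoding="UTF-8")
    mod_out = workspace / "naf.mod"
    mod_out.write_text(mod_text, encoding="utf-8")
    return [xml_out, mod_out]


HOOKS["channel_xml_edit"] = _channel_edit_hook


# ---------------------------------------------------------------------------
# Run command, result retrieval, reset
# ---------------------------------------------------------------------------

def build_run_command(inst: SimulatorInstance,
                      ipv: InputParameterVector) -> str:
    """Shell command executing this instance's entry point with the
    simulation's parameters, in the run directory."""
    desc = inst.descriptor
    simcore = simcore_command(desc, inst.machine)
    entry = str(PurePosixPath(inst.install_dir) / desc.entry_point)
    parts = [shlex.quote(simcore), shlex.quote(entry)]
    parts += [shlex.quote(p) for p in ipv.params]
    return " ".join(parts)


def download_results(inst: SimulatorInstance, simulation: Simulation,
                     transport: Transport, session_dir: Path,
                     clock: Clock = utc_now) -> Path:
    """Move the run directory's contents into an isolated time-stamped
    directory under ``<session_dir>/results/`` on the host.

    The directory name embeds the sim_id and a UTC timestamp; a numeric
    suffix keeps names unique when two simulations finish within the same
    second.  On transport failure the partially downloaded files are
    retained and the error propagates (the engine marks the simulation
    FAILED)."""
    stamp = clock().strftime(_TS_FMT)
    result_dir = unique_path(Path(session_dir) / "results",
                             f"{simulation.sim_id}_{stamp}")
    result_dir.mkdir(parents=True)
    simulation.result_dir = str(result_dir)
    for name in transport.listdir(inst.run_dir):
        remote = str(PurePosixPath(inst.run_dir) / name)
        transport.download(remote, result_dir / name)
    return result_dir


def reset_simulator(inst: SimulatorInstance, transport: Transport) -> None:
    """Empty the run directory and return the instance to AVAILABLE.

    The install directory is untouched, so the next simulation reuses the
    built payload.  Idempotent; resetting a RETIRED instance is an error;
    a cleanup failure retires the instance."""
    if inst.state is SimulatorState.RETIRED:
        raise ValueError(
            f"cannot reset retired simulator {inst.simulator_id!r}")
    try:
        transport.remove_tree(inst.run_dir)
        transport.mkdir(inst.run_dir)
    except Exception:
        inst.state = SimulatorState.RETIRED
        raise
    inst.state = SimulatorState.AVAILABLE
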