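"""XML session documents: one file describing a complete session.

A session document specifies the SimSet (inline parameter vectors or a
SimSpec file reference), the simulator type, the machines composing the
machine set, user notification info, and file locations.  The format is
host-OS- and language-independent; a shipped XML Schema validates it, and a
deterministic transform turns a valid document into the two artifacts the
engine runs from: a SimSpec text file and an engine config file.

Vocabulary::

    <session name="...">
      <simtype key="..."/>
      <simset [file="..."]> <vector simid="..."><p>...</p>...</vector>* </simset>
      <machineset> <machine machine_type=".." num_simulators=".."
                            work_dir=".." [name= address= queue= wall_time=]/>+
      </machineset>
      [<simulator> <option name=".." value=".."/>* </simulator>]
      [<user> <notify address=".." [events=".." scope=".."]/>* </user>]
      <locations root="..."/>
    </session>
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from lxml import etree

from .core import InputParameterVector, SimSet, Simulation, write_simspec
from .engine import EngineConfig, dump_config
from .machines import MACHINE_TYPES, MachineSetConfig
from .simulators import SIMTYPES

__all__ = [
    "SessionDocument",
    "load_session_xml",
    "validate_session_xml",
    "transform_session",
    "build_session_xml",
]

DocLike = Union[str, Path, etree._ElementTree]


def _schema() -> etree.XMLSchema:
    path = Path(str(resources.files("simbatch") / "data" / "session.xsd"))
    return etree.XMLSchema(etree.parse(str(path)))


def load_session_xml(source: DocLike) -> etree._ElementTree:
    """Load a session document from a path, XML text, or parsed tree."""
    if isinstance(source, str) and source.lstrip().startswith("<"):
        return etree.ElementTree(etree.fromstring(source.encode()))
    if isinstance(source, (str, Path)):
        return etree.parse(str(source))
    return source


@dataclass
class SessionDocument:
    """Parsed view of a validated session document."""

    name: str
    sim_type: str
    vectors: list[InputParameterVector] = field(default_factory=list)
    simspec_file: Optional[str] = None
    machines: list[dict] = field(default_factory=list)
    simulator_options: dict = field(default_factory=dict)
    notify: list[dict] = field(default_factory=list)
    root: str = ""


def validate_session_xml(source: DocLike) -> list[str]:
    """Validate a session document; returns violations (empty means ok).

    Schema validation first, then the semantic checks: a registered
    simulator type, at least one machine of a registered type, sim_id
    uniqueness, exactly one SimSet source (inline vectors or a file
    reference), and uniform vector arity when the simulator type declares
    one.  Each violation carries the element path and a message.
    """
    tree = load_session_xml(source)
    schema = _schema()
    if not schema.validate(tree):
        return [f"{e.path or '/'}: {e.message}" for e in schema.error_log]
    violations: list[str] = []
    root = tree.getroot()
    simtype = root.find("simtype").get("key")
    arity: Optional[int] = None
    if simtype not in SIMTYPES:
        violations.append(
            f"{tree.getpath(root.find('simtype'))}: "
            f"unregistered sim_type {simtype!r}")
    else:
        # descriptor construction may need options we cannot assume here;
        # arity is fixed per sim_type for the shipped families
        arity = {"sine01": 2, "noop01": 0, "khmodel01": 3,
                 "channel01": 8}.get(simtype)
    simset = root.find("simset")
    vectors = simset.findall("vector")
    has_file = simset.get("file") is not None
    if has_file and vectors:
        violations.append(f"{tree.getpath(simset)}: simset must use either "
                          "a file reference or inline vectors, not both")
    if not has_file and not vectors:
        violations.append(f"{tree.getpath(simset)}: simset is empty: "
                          "provide inline vectors or a file reference")
    seen: set[str] = set()
    for v in vectors:
        simid = v.get("simid")
        if simid in seen:
            violations.append(f"{tree.getpath(v)}: duplicate sim_id "
                              f"{simid!r}")
        seen.add(simid)
        if not simid or any(c.isspace() for c in simid):
            violations.append(f"{tree.getpath(v)}: invalid sim_id "
                              f"{simid!r}")
        if arity is not None and len(v.findall("p")) != arity:
            violations.append(
                f"{tree.getpath(v)}: vector has {len(v.findall('p'))} "
                f"parameters, sim_type {simtype!r} declares {arity}")
    for m in root.find("machineset").findall("machine"):
        if m.get("machine_type") not in MACHINE_TYPES:
            violations.append(f"{tree.getpath(m)}: unknown machine_type "
                              f"{m.get('machine_type')!r}")
    return violations


def _parse_document(tree: etree._ElementTree) -> SessionDocument:
    root = tree.getroot()
    simset = root.find("simset")
    doc = SessionDocument(
        name=root.get("name"),
        sim_type=root.find("simtype").get("key"),
        simspec_file=simset.get("file"),
        root=root.find("locations").get("root"),
    )
    for v in simset.findall("vector"):
        doc.vectors.append(InputParameterVector(
            sim_id=v.get("simid"),
            params=tuple(p.text or "" for p in v.findall("p"))))
    for m in root.find("machineset").findall("machine"):
        doc.machines.append({
            "machine_type": m.get("machine_type"),
            "name": m.get("name") or "",
            "address": m.get("address") or "localhost",
            "num_simulators": int(m.get("num_simulators")),
            "work_dir": m.get("work_dir"),
            "queue": m.get("queue") or "",
            "wall_time": m.get("wall_time") or "",
        })
    sim = root.find("simulator")
    if sim is not None:
        for opt in sim.findall("option"):
            doc.simulator_options[opt.get("name")] = opt.get("value")
    user = root.find("user")
    if user is not None:
        for n in user.findall("notify"):
            doc.notify.append({
                "address": n.get("address"),
                "events": n.get("events") or "",
                "scope": n.get("scope") or "global",
            })
    return doc


def transform_session(source: DocLike) -> tuple[Optional[str], str]:
    """Transform a valid session document into its run artifacts.

    Returns ``(simspec_text, config_text)``.  With inline vectors the
    SimSpec text round-trips exactly through the SimSpec parser; with an
    external file reference the config points at it and ``simspec_text`` is
    None.  The transform is deterministic and implemented natively as
    template/structure expansion; callers may substitute an external
    stylesheet processor by transforming the document themselves.
    """
    tree = load_session_xml(source)
    violations = validate_session_xml(tree)
    if violations:
        raise ValueError("invalid session document: "
                         + "; ".join(violations))
    doc = _parse_document(tree)
    cfg = EngineConfig(
        session_name=doc.name,
        sim_type=doc.sim_type,
        root=doc.root,
        simulator_options=dict(doc.simulator_options),
    )
    for m in doc.machines:
        job_defaults = {}
        if m["queue"]:
            job_defaults["queue"] = m["queue"]
        if m["wall_time"]:
            job_defaults["wall_time"] = m["wall_time"]
        cfg.machines.add_machine(
            m["machine_type"], m["num_simulators"], m["work_dir"],
            name=m["name"], address=m["address"], job_defaults=job_defaults)
    for n in doc.notify:
        if n["address"].startswith("file:"):
            cfg.notify_file = n["address"][len("file:"):]
            cfg.notify_events = tuple(
                e for e in n["events"].replace(",", " ").split() if e)
            cfg.notify_scope = n["scope"]
    simspec_text: Optional[str] = None
    if doc.simspec_file:
        cfg.simspec = doc.simspec_file
    else:
        simset = SimSet(doc.name,
                        [Simulation(ipv=v) for v in doc.vectors])
        simspec_text = write_simspec(simset)
    return simspec_text, dump_config(cfg)


def build_session_xml(name: str, sim_type: str, *,
                      vectors: Optional[list[InputParameterVector]] = None,
                      simspec_file: Optional[str] = None,
                      machines: list[dict],
                      root: str,
                      simulator_options: Optional[dict] = None,
                      notify: Optional[list[dict]] = None) -> str:
    """Construct session-document XML text programmatically."""
    session = etree.Element("session", name=name)
    etree.SubElement(session, "simtype", key=sim_type)
    simset = etree.SubElement(session, "simset")
    if simspec_file:
        simset.set("file", simspec_file)
    for v in vectors or []:
        vec = etree.SubElement(simset, "vector", simid=v.sim_id)
        for p in v.params:
            etree.SubElement(vec, "p").text = p
    machineset = etree.SubElement(session, "machineset")
    for m in machines:
        attrs = {"machine_type": m["machine_type"],
                 "num_simulators": str(m["num_simulators"]),
                 "work_dir": m["work_dir"]}
        for key in ("name", "address", "queue", "wall_time"):
            if m.get(key):
                attrs[key] = str(m[key])
        etree.SubElement(machineset, "machine", **attrs)
    if simulator_options:
        sim = etree.SubElement(session, "simulator")
        for k, v in simulator_options.items():
            etree.SubElement(sim, "option", name=k, value=str(v))
    if notify:
        user = etree.SubElement(session, "user")
        for n in notify:
            attrs = {"address": n["address"]}
            if n.get("events"):
                attrs["events"] = n["events"]
            if n.get("scope"):
                attrs["scope"] = n["scope"]
            etree.SubElement(user, "notify", **attrs)
    etree.SubElement(session, "locations", root=root)
    return etree.tostring(session, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()
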