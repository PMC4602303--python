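"""Deterministic, seeded generators for every test input.

These synthetic artifacts stand in for external model resources (published
morphology/mechanism files, channel specifications in NeuroML, stylesheet
chains): they reproduce the *shape* those inputs impose on the engine — an
XML channel with eight editable gate-rate parameters, a hoc-style model
template with three section placeholders, SimSpec files of arbitrary size —
without requiring any download.  The same seed always yields byte-identical
output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from lxml import etree

__all__ = [
    "FixtureSpec",
    "make_channel_fixture",
    "make_broken_channel_fixture",
    "make_simspec_fixture",
    "make_model_template_fixture",
    "make_local_machineset",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for a generated SimSpec file."""

    seed: int
    n_simulations: int
    n_params: int
    failure_injection: float = 0.0   # fraction of vectors with bad arity

    def __post_init__(self) -> None:
        if self.n_simulations < 0:
            raise ValueError("n_simulations must be >= 0")
        if not 0.0 <= self.failure_injection <= 1.0:
            raise ValueError("failure_injection must be in [0, 1]")


def make_channel_fixture(seed: int) -> str:
    """Synthetic ion-channel XML: a NaF-style fast sodium channel with m
    (activation) and h (inactivation) gates, each with exponential alpha
    and beta rates — exactly 8 editable free-parameter slots (mAlphaA,
    mAlphak, mBetaA, mBetak, hAlphaA, hAlphak, hBetaA, hBetak) — plus a
    static leak.  Schema-valid against the shipped channel schema."""
    rng = random.Random(seed)

    def amp() -> str:
        return f"{rng.uniform(0.1, 9000.0):.4f}"

    def slope(sign: int) -> str:
        return f"{sign * rng.uniform(3.0, 30.0):.4f}"

    channel = etree.Element("channel", name="NaF", species="na")
    for gate_name, inst, signs in (("m", "3", (1, -1)), ("h", "1", (-1, 1))):
        gate = etree.SubElement(channel, "gate", name=gate_name,
                                instances=inst)
        etree.SubElement(gate, "rate", kind="alpha", A=amp(),
                         k=slope(signs[0]))
        etree.SubElement(gate, "rate", kind="beta", A=amp(),
                         k=slope(signs[1]))
    etree.SubElement(channel, "leak",
                     conductance=f"{rng.uniform(0.05, 0.5):.4f}")
    return etree.tostring(channel, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()


def make_broken_channel_fixture(seed: int) -> str:
    """A channel document missing its h gate: for error-path tests of
    editing parameters that are declared but absent from the document."""
    tree = etree.fromstring(make_channel_fixture(seed).encode())
    for gate in tree.findall("gate"):
        if gate.get("name") == "h":
            tree.remove(gate)
    return etree.tostring(tree, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()


def validate_channel_fixture(xml_text: str) -> bool:
    schema_path = Path(str(resources.files("simbatch") / "data"
                           / "channel.xsd"))
    schema = etree.XMLSchema(etree.parse(str(schema_path)))
    return schema.validate(etree.fromstring(xml_text.encode()))


def make_simspec_fixture(spec: FixtureSpec) -> str:
    """A SimSpec file of ``n_simulations`` vectors (sim0001, sim0002, ...)
    with ``n_params`` random numeric parameter strings each; a
    ``failure_injection`` fraction of the vectors (rounded) get one extra
    parameter, i.e. the wrong arity for the simulator under test."""
    rng = random.Random(spec.seed)
    n_bad = int(round(spec.n_simulations * spec.failure_injection))
    bad = set(rng.sample(range(spec.n_simulations), n_bad)) \
        if n_bad else set()
    lines = [f"# generated SimSpec (seed={spec.seed})"]
    for i in range(spec.n_simulations):
        arity = spec.n_params + (1 if i in bad else 0)
        params = [f"{rng.uniform(0.1, 10.0):.4f}" for _ in range(arity)]
        lines.append("\t".join([f"sim{i + 1:04d}", *params]))
    return "\n".join(lines) + "\n"


_MODEL_TEMPLATE = """\
// synthetic Purkinje-style model template: morphology, passive properties,
// and per-section Kh (anomalous rectifier) densities filled per simulation
create soma, smooth[2], spiny[4]

soma {{
    diam = 20  L = 20  Ra = 250
    insert pas
    insert kh
    gkhbar_kh = {kh_soma}
}}

forsec "smooth" {{
    diam = 3  L = 100  Ra = 250
    insert pas
    insert kh
    gkhbar_kh = {kh_smooth}
}}

forsec "spiny" {{
    diam = 1  L = 150  Ra = 250
    insert pas
    insert kh
    gkhbar_kh = {kh_spiny}
}}
"""


def make_model_template_fixture() -> str:
    """Hoc-style model template with three section blocks (soma, smooth
    dendrites, spiny dendrites), each carrying one Kh-density placeholder."""
    return _MODEL_TEMPLATE


def make_local_machineset(base_dir: Path, counts=(2, 5)):
    """A machine set of local stub machines with distinct work directories
    (host == remote), one entry per element of ``counts``."""
    from .machines import MachineSetConfig

    ms = MachineSetConfig()
    base_dir = Path(base_dir)
    for i, n in enumerate(counts, start=1):
        work = base_dir / f"machine{i}"
        work.mkdir(parents=True, exist_ok=True)
        ms.add_machine("generic_unix", n, str(work), name=f"M{i}")
    return ms
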