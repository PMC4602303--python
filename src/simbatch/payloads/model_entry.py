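"""Toy model-file simulator (remote entry point).

Stands in for a morphology-based neuron simulation whose model file was
assembled on the host with per-simulation channel densities.  Reads the
assembled hoc-style model file from the run directory, extracts the Kh
conductance density set in each section block (soma, smooth dendrites,
spiny dendrites), and writes them plus a simple summary as output.
"""

import json
import re
import sys
from pathlib import Path

MODEL_FILE = "purkinje.hoc"
DENSITY_RE = re.compile(r"gkhbar_kh\s*=\s*([-+0-9.eE]+)")
SECTIONS = ("kh_soma", "kh_smooth", "kh_spiny")


def fail(reason):
    Path("FAIL").write_text(reason + "\n")
    sys.exit(1)


def main(argv):
    model = Path(MODEL_FILE)
    if not model.is_file():
        fail(f"missing model file {MODEL_FILE}")
    densities = DENSITY_RE.findall(model.read_text())
    if len(densities) != len(SECTIONS):
        fail(f"expected {len(SECTIONS)} Kh insertions, found {len(densities)}")
    values = dict(zip(SECTIONS, densities))
    Path("kh_summary.json").write_text(
        json.dumps(values, indent=2, sort_keys=True) + "\n")
    with open("kh_summary.csv", "w") as fh:
        fh.write("section,gkhbar\n")
        for k in SECTIONS:
            fh.write(f"{k},{values[k]}\n")
    Path("SUCCESS").write_text("ok\n")


if __name__ == "__main__":
    main(sys.argv[1:])
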