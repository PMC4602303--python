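"""Toy ion-channel simulator (remote entry point).

Stands in for compiling and running a mod-format channel description.  The
host edited the channel XML per the input parameter vector and rendered it
to mod-format text; this script parses the eight gate-rate constants back
out of the mod file and writes them as JSON plus steady-state activation
values at 0 mV, so outputs are a pure function of the parameters.
"""

import json
import math
import re
import sys
from pathlib import Path

MOD_FILE = "naf.mod"
RATE_NAMES = ("mAlphaA", "mAlphak", "mBetaA", "mBetak",
              "hAlphaA", "hAlphak", "hBetaA", "hBetak")


def fail(reason):
    Path("FAIL").write_text(reason + "\n")
    sys.exit(1)


def steady_state(alpha_a, alpha_k, beta_a, beta_k, v=0.0):
    # exponential voltage-dependent rates; x_inf = alpha / (alpha + beta)
    alpha = alpha_a * math.exp(v / alpha_k if alpha_k else 0.0)
    beta = beta_a * math.exp(v / beta_k if beta_k else 0.0)
    return alpha / (alpha + beta) if (alpha + beta) else 0.0


def main(argv):
    mod = Path(MOD_FILE)
    if not mod.is_file():
        fail(f"missing mod file {MOD_FILE}")
    text = mod.read_text()
    rates = {}
    for name in RATE_NAMES:
        m = re.search(rf"^\s*{name}\s*=\s*(\S+)", text, re.MULTILINE)
        if not m:
            fail(f"rate {name} not found in {MOD_FILE}")
        rates[name] = m.group(1)
    out = {
        "rates": rates,
        "m_inf_0mV": steady_state(*(float(rates[n]) for n in RATE_NAMES[:4])),
        "h_inf_0mV": steady_state(*(float(rates[n]) for n in RATE_NAMES[4:])),
    }
    Path("rates.json").write_text(
        json.dumps(out, indent=2, sort_keys=True) + "\n")
    Path("SUCCESS").write_text("ok\n")


if __name__ == "__main__":
    main(sys.argv[1:])
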