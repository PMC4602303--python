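"""No-op simulator (remote entry point): optionally sleeps, then succeeds.

Zero free parameters; the sleep duration (seconds) comes from the static
parameter ``delay`` so scheduling tests can hold simulators busy.
"""

import json
import sys
import time
from pathlib import Path


def main(argv):
    static = Path(__file__).resolve().parent / "static_params.json"
    params = json.loads(static.read_text()) if static.is_file() else {}
    delay = float(params.get("delay", "0"))
    if delay > 0:
        time.sleep(delay)
    Path("SUCCESS").write_text("ok\n")


if __name__ == "__main__":
    main(sys.argv[1:])
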