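"""Toy sine-wave simulator (remote entry point).

Two free parameters: frequency (Hz) and duration (s).  Samples
sin(2*pi*frequency*t) at the configured rate, writing the samples as CSV
and a plot of the waveform as a deterministic SVG.
"""

import json
import math
import sys
from pathlib import Path

SUCCESS, FAIL = "SUCCESS", "FAIL"


def fail(reason: str) -> "NoReturn":
    Path(FAIL).write_text(reason + "\n")
    sys.exit(1)


def load_static() -> dict:
    static = Path(__file__).resolve().parent / "static_params.json"
    if static.is_file():
        return json.loads(static.read_text())
    return {}


def render_svg(ts, values, width=400, height=200) -> str:
    lo, hi = -1.0, 1.0
    span = (ts[-1] - ts[0]) or 1.0
    pts = " ".join(
        f"{(t - ts[0]) / span * width:.2f},"
        f"{(1.0 - (v - lo) / (hi - lo)) * height:.2f}"
        for t, v in zip(ts, values)
    )
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{width}" height="{height}">\n'
        f'<polyline fill="none" stroke="black" points="{pts}"/>\n'
        "</svg>\n"
    )


def main(argv):
    if len(argv) != 2:
        fail("arity")
    try:
        frequency, duration = float(argv[0]), float(argv[1])
    except ValueError:
        fail("parse")
    if duration <= 0:
        fail("duration must be positive")
    rate = float(load_static().get("sample_rate", "1000"))
    n = int(round(duration * rate))
    ts = [k / rate for k in range(n)]
    values = [math.sin(2.0 * math.pi * frequency * t) for t in ts]
    with open("sine.csv", "w") as fh:
        fh.write("t,value\n")
        for t, v in zip(ts, values):
            fh.write(f"{t!r},{v!r}\n")
    if ts:
        Path("sine.svg").write_text(render_svg(ts, values))
    else:
        Path("sine.svg").write_text(render_svg([0.0, 1.0], [0.0, 0.0]))
    Path(SUCCESS).write_text("ok\n")


if __name__ == "__main__":
    main(sys.argv[1:])
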