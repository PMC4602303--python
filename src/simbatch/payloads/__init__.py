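"""Remote-side entry-point scripts shipped as simulator payloads.

Each script honours the remote entry-point contract: it receives the input
parameter vector as command-line arguments, runs with the run directory as
working directory, writes its declared outputs there, then writes a
``SUCCESS`` sentinel file — or a ``FAIL`` sentinel with a reason line on
any error.  Scripts are stdlib-only so any machine with a Python
interpreter can run them.
"""

from importlib import resources
from pathlib import Path


def payload_path(name: str) -> Path:
    """Host path of a shipped entry-point script."""
    p = Path(str(resources.files(__package__) / name))
    if not p.is_file():
        raise FileNotFoundError(f"no such payload: {name}")
    return p
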