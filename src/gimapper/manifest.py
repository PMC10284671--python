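"""Per-run provenance manifests.

DepMap releases change bi-annually, so every result table is written with a
sibling ``<output>.manifest.json`` recording the subcommand, all parameters,
the SHA-256 digest of every input file, the seed (when randomness is
involved), the package version and a timestamp — enough to replay the run
exactly.  The timestamp is informational; replaying with the same inputs and
parameters reproduces the result table itself bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    output_path: str | Path,
    subcommand: str,
    inputs: Mapping[str, str | Path],
    parameters: Mapping[str, object],
    seed: int | None = None,
) -> Path:
    """Write ``<output_path>.manifest.json`` and return its path."""
    from . import __version__

    manifest = {
        "subcommand": subcommand,
        "inputs": {
            name: {"path": str(p), "sha256": sha256_of(p)}
            for name, p in inputs.items()
            if p is not None
        },
        "parameters": {k: _jsonable(v) for k, v in parameters.items()},
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    out = Path(str(output_path) + ".manifest.json")
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _jsonable(v):
    if isinstance(v, (str, int, float, bool)) or v is None:
        return v
    if isinstance(v, (list, tuple, set, frozenset)):
        return sorted(map(str, v)) if isinstance(v, (set, frozenset)) else [
            _jsonable(x) for x in v
        ]
    return str(v)
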