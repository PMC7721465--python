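"""Run manifests: what ran, on which inputs, with which seed.

Every CLI pipeline run emits one JSON manifest next to its outputs.  The
manifest is deterministic by default (no wall-clock timestamp) so that
reruns with identical inputs and seeds produce byte-identical manifests;
pass ``timestamp=True`` to record the time of the run.
"""
from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

__version__ = "0.1.0"

__all__ = ["file_digest", "build_manifest", "write_manifest"]


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    command: str,
    inputs: dict[str, str] | None = None,
    config: dict | None = None,
    seed: int | None = None,
    extra: dict | None = None,
    timestamp: bool = False,
) -> dict:
    config_blob = json.dumps(config or {}, sort_keys=True)
    manifest = {
        "command": command,
        "software_version": __version__,
        "seed": seed,
        "config": config or {},
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "input_sha256": {name: file_digest(p) for name, p in (inputs or {}).items()},
        "timestamp": datetime.now(timezone.utc).isoformat() if timestamp else None,
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
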