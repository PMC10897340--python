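"""Deterministic report serialisation.

Machine reports are JSON with sorted keys and all floats rounded to 6
significant digits, so identical inputs produce byte-identical files. Every
artifact embeds the package version, a hash of the configuration, and the
master seed.
"""

from __future__ import annotations

import hashlib
import json
import math

import numpy as np


def round_sig(x: float, sig: int = 6) -> float:
    """Round to ``sig`` significant digits (0, nan and inf pass through)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _canonical(obj, sig: int = 6):
    if isinstance(obj, dict):
        return {str(k): _canonical(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v, sig) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else round_sig(v, sig)
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_canonical(v, sig) for v in obj.tolist()]
    if obj is None or isinstance(obj, (str, bool)):
        return obj
    return str(obj)


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(_canonical(config_dict, sig=12), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def serialize_report(report: dict, *, seed: int, config: dict | None = None,
                     sig: int = 6) -> str:
    """Render a report as deterministic JSON text with embedded metadata."""
    from . import __version__

    payload = {
        "meta": {
            "package_version": __version__,
            "master_seed": int(seed),
            "config_hash": config_hash(config or {}),
        },
        "report": _canonical(report, sig),
    }
    return json.dumps(payload, sort_keys=True, indent=1) + "\n"


def write_report(report: dict, path, *, seed: int, config: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_report(report, seed=seed, config=config))
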