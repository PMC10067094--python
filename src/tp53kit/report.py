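"""Report assembly helpers: plain-JSON conversion, provenance blocks, and
TSV output with a provenance header line."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


def plain(obj):
    """Recursively convert numpy/pandas values to plain JSON-able types."""
    if isinstance(obj, dict):
        return {str(k): plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [plain(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return plain(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return plain(obj.to_dict())
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, np.ndarray):
        return plain(obj.tolist())
    return obj


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def provenance_block(version: str, inputs: dict, config: dict) -> dict:
    """Provenance: software version, input checksums + row counts, config echo."""
    # no timestamp: reruns on identical inputs must be byte-identical
    block = {"software": "tp53kit", "version": version,
             "inputs": {}, "config": plain(config)}
    for name, path in inputs.items():
        p = Path(path)
        n_rows = sum(1 for line in p.read_text().splitlines()
                     if line and not line.startswith("#")) - 1
        block["inputs"][name] = {"path": str(p), "sha256": sha256_of(p),
                                 "data_rows": max(n_rows, 0)}
    return block


def provenance_header(version: str, extra: str = "") -> str:
    return f"# tp53kit v{version} {extra}".rstrip() + "\n"


def write_tsv(df: pd.DataFrame, path, version: str, extra: str = "") -> None:
    Path(path).write_text(
        provenance_header(version, extra) + df.to_csv(sep="\t", index=False)
    )


def write_json(obj, path, version: str, provenance: dict | None = None) -> None:
    payload = {"provenance": provenance or {"software": "tp53kit", "version": version}}
    payload.update(plain(obj))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
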