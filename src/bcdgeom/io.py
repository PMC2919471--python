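"""Configuration and artifact IO: TSV/JSON writers with provenance headers.

Canonical tabular format is TSV (header row, '.' decimal); scalar result
bundles are JSON.  Every artifact written through this module carries a
provenance header (package version, seed, config hash) as '#'-prefixed
comment lines, which the readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__

__all__ = ["load_config", "dump_config", "config_hash", "write_tsv",
           "write_json", "ensure_writable"]


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def dump_config(config: dict, path: str | Path) -> None:
    p = Path(path)
    if p.suffix in (".yaml", ".yml"):
        p.write_text(yaml.safe_dump(config, sort_keys=True))
    else:
        p.write_text(json.dumps(config, indent=1, sort_keys=True))


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed: int | None, config: dict | None) -> str:
    lines = [f"# bcdgeom version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    return "\n".join(lines) + "\n"


def ensure_writable(path: str | Path, force: bool) -> Path:
    p = Path(path)
    if p.exists() and not force:
        raise FileExistsError(f"{p} exists; pass --force to overwrite")
    p.parent.mkdir(parents=True, exist_ok=True)
    return p


def write_tsv(df: pd.DataFrame, path: str | Path, seed: int | None = None,
              config: dict | None = None, force: bool = True) -> None:
    p = ensure_writable(path, force)
    with open(p, "w") as fh:
        fh.write(provenance_header(seed, config))
        df.to_csv(fh, sep="\t", index=False)


def write_json(obj: dict, path: str | Path, seed: int | None = None,
               config: dict | None = None, force: bool = True) -> None:
    p = ensure_writable(path, force)
    payload = {"_provenance": {"version": __version__, "seed": seed,
                               "config_hash": config_hash(config) if config else None}}
    payload.update(obj)
    p.write_text(json.dumps(payload, indent=1, default=_jsonable))


def _jsonable(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "__dict__"):
        return {k: v for k, v in o.__dict__.items() if not k.startswith("_")}
    return str(o)
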