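"""Plain-file handoff between pipeline stages: stamped TSVs and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["write_tsv", "read_tsv", "write_manifest", "read_metadata"]


def write_tsv(df: pd.DataFrame, path: str | Path, stage: str, params: dict) -> None:
    """Write a stage output TSV with a provenance comment line on top."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    param_str = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    with open(path, "w") as fh:
        fh.write(f"# readzs {__version__} stage={stage} {param_str}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Cell metadata TSV; requires a `cell` column."""
    meta = pd.read_csv(path, sep="\t", comment="#", dtype={"cell": str})
    if "cell" not in meta.columns:
        raise ValueError(f"metadata {path} lacks required column 'cell'")
    return meta


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path, stage: str, params: dict, inputs: list[str | Path]
) -> Path:
    """Record version, parameters, seeds and input digests for a stage run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "stage": stage,
        "params": {k: str(v) for k, v in sorted(params.items())},
        "inputs": {str(p): _digest(Path(p)) for p in inputs if Path(p).exists()},
    }
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
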