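"""Stable writers/readers for the JSON/CSV interfaces, plus run manifests.

CSV output uses a fixed column order and '.'-decimal formatting with no
locale dependence; JSON floats round-trip losslessly (Python's repr-based
serialization).  Every CLI run writes exactly one manifest JSON next to
its primary output.
"""

from __future__ import annotations

import datetime
import json
from importlib import metadata
from pathlib import Path

import pandas as pd

__all__ = [
    "write_json",
    "read_json",
    "write_dataset_csv",
    "read_dataset_csv",
    "write_prediction_csv",
    "write_manifest",
]

_DATASET_DTYPES = {
    "participant": "int64",
    "item": "string",
    "position": "int64",
    "trial_type": "string",
    "knowledgeability": "string",
    "exposure_condition": "string",
    "rating": "float64",
    "comp1_correct": "bool",
    "comp2_correct": "bool",
}


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_dataset_csv(dataset: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in _DATASET_DTYPES if c in dataset.columns]
    cols += [c for c in dataset.columns if c not in cols]
    dataset[cols].to_csv(path, index=False, lineterminator="\n")


def read_dataset_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    dtypes = {k: v for k, v in _DATASET_DTYPES.items() if k in df.columns}
    df = df.astype(dtypes)
    for col in ("item", "trial_type", "knowledgeability", "exposure_condition"):
        if col in df.columns:
            df[col] = df[col].astype(object)
    return df


def write_prediction_csv(table, path) -> None:
    """One row per design cell: condition,alternatives,p_not_all,percent."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "condition": know,
            "alternatives": alts,
            "p_not_all": repr(p),
            "percent": int(round(100.0 * p)),
        }
        for (know, alts), p in table.cells.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def _package_version() -> str:
    try:
        return metadata.version("altrsa")
    except metadata.PackageNotFoundError:
        return "unknown"


def write_manifest(command: str, out_path, config_snapshot: dict,
                   seeds: dict | None = None) -> Path:
    """Write the run manifest alongside the primary output file."""
    out_path = Path(out_path)
    manifest_path = out_path.with_name(out_path.stem + ".manifest.json")
    write_json(
        {
            "command": command,
            "config": config_snapshot,
            "seeds": seeds or {},
            "package_version": _package_version(),
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "outputs": [str(out_path)],
        },
        manifest_path,
    )
    return manifest_path
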