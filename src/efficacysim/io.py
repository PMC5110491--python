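"""Reading and writing the adherence-log CSV schema and sidecar metadata.

The standard log has one row per (participant, day, exercise) trial with
columns ``participant_id``, ``day`` (1-based integer), ``exercise_id``,
``success`` (0/1), ``condition``, and an optional ``difficulty`` in logits.
Sidecar JSON files carry seeds and generating parameters next to any
simulated output so runs can be reproduced.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED = ["participant_id", "day", "exercise_id", "success", "condition"]
OPTIONAL = ["difficulty"]


def read_adherence_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "exercise_id": str},
                     float_precision="round_trip")
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["day"] = df["day"].astype(int)
    df["success"] = df["success"].astype(int)
    if not set(df["success"].unique()) <= {0, 1}:
        raise ValueError("success must be coded 0/1")
    if (df["day"] < 1).any():
        raise ValueError("day must be 1-based")
    return df


def write_adherence_csv(records: pd.DataFrame, path) -> None:
    cols = [c for c in REQUIRED + OPTIONAL if c in records.columns]
    records[cols].to_csv(path, index=False)


def write_sidecar(path, metadata: dict) -> None:
    """Write run metadata (seed, parameters) next to an output file."""
    side = Path(str(path)).with_suffix(".meta.json")
    with open(side, "w") as fh:
        json.dump(_jsonable(metadata), fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
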