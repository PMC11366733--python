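"""Trial-table CSV and JSON-config round-tripping."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .simulator import SessionDesign, StrategyProfile

TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "phase",
    "has_advice",
    "truth",
    "first_response",
    "recommendation",
    "second_response",
]

_FLOAT_FMT = "%.10g"  # stable text form -> byte-identical rewrites


def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> Path:
    """Write a trial table (UTF-8, '.' decimal, empty field for absent)."""
    path = Path(path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    trials[TRIAL_COLUMNS].to_csv(
        path, index=False, float_format=_FLOAT_FMT, lineterminator="\n", encoding="utf-8"
    )
    return path


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "participant_id": str,
            "trial_index": "int64",
            "phase": str,
            "has_advice": bool,
            "truth": float,
            "first_response": float,
            "recommendation": float,
            "second_response": float,
        },
    )
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is not a trial table; missing columns {missing}")
    return df


def write_frame_csv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    frame.to_csv(path, index=index, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def design_to_json(design: SessionDesign, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(design.to_dict(), indent=2, sort_keys=True) + "\n")
    return path


def design_from_json(path: str | Path) -> SessionDesign:
    return SessionDesign.from_dict(json.loads(Path(path).read_text()))


def profiles_to_json(profiles: Sequence[StrategyProfile], path: str | Path) -> Path:
    path = Path(path)
    payload = [p.to_dict() for p in profiles]
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def profiles_from_json(path: str | Path) -> list[StrategyProfile]:
    payload = json.loads(Path(path).read_text())
    if isinstance(payload, dict):
        payload = [payload]
    return [StrategyProfile.from_dict(d) for d in payload]
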