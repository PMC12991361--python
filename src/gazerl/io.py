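"""CSV schemas, structured reports, and run manifests.

Trial tables are plain UTF-8 CSVs with one row per trial:

    participant, phase, trial, context, shown_ids, avail_ids, choice_id,
    rt_ms, outcome:<id>..., gaze:<id>...

``shown_ids`` / ``avail_ids`` are semicolon-joined option ids; outcome and
gaze columns exist per option id and are blank where not applicable (e.g.
outcomes on transfer trials). Fixation tables have columns participant,
trial, aoi, duration_ms, order. Times are milliseconds; option ids are
opaque strings. Reports serialize to JSON; every CLI run writes a manifest
recording the command, configuration hash, and seeds so that reruns are
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .gaze import FixationRecord
from .task import TrialRecord

__all__ = [
    "SchemaError",
    "read_trials",
    "write_trials",
    "trials_to_frame",
    "frame_to_trials",
    "read_fixations",
    "write_report",
    "RunManifest",
]

TRIAL_COLUMNS = ["participant", "phase", "trial", "context", "shown_ids", "avail_ids", "choice_id", "rt_ms"]


class SchemaError(ValueError):
    """A file violated the documented CSV schema; message names the row."""


def trials_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    option_ids: List[str] = []
    for tr in records:
        for oid in tr.shown:
            if oid not in option_ids:
                option_ids.append(oid)
    rows = []
    for tr in records:
        row = {
            "participant": tr.participant,
            "phase": tr.phase,
            "trial": tr.trial,
            "context": tr.context,
            "shown_ids": ";".join(tr.shown),
            "avail_ids": ";".join(tr.avail),
            "choice_id": tr.choice,
            "rt_ms": tr.rt_ms,
        }
        for oid in option_ids:
            row[f"outcome:{oid}"] = tr.outcomes.get(oid, np.nan)
            row[f"gaze:{oid}"] = tr.gaze.get(oid, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_trials(df: pd.DataFrame, source: str = "<frame>") -> List[TrialRecord]:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required columns {missing}")
    out_cols = {c[len("outcome:"):]: c for c in df.columns if c.startswith("outcome:")}
    gaze_cols = {c[len("gaze:"):]: c for c in df.columns if c.startswith("gaze:")}
    records = []
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based + header
        try:
            rt = float(row["rt_ms"])
        except (TypeError, ValueError):
            raise SchemaError(f"{source} row {rownum}: rt_ms {row['rt_ms']!r} is not numeric") from None
        shown = tuple(str(row["shown_ids"]).split(";"))
        avail = tuple(str(row["avail_ids"]).split(";"))
        choice = str(row["choice_id"])
        if choice not in avail:
            raise SchemaError(
                f"{source} row {rownum}: choice {choice!r} not among available options {avail}"
            )
        outcomes = {}
        for oid in shown:
            col = out_cols.get(oid)
            if col is not None and pd.notna(row[col]):
                outcomes[oid] = int(row[col])
        gaze = {}
        for oid in avail:
            col = gaze_cols.get(oid)
            if col is not None and pd.notna(row[col]):
                gaze[oid] = float(row[col])
        records.append(TrialRecord(
            participant=str(row["participant"]), phase=str(row["phase"]),
            trial=int(row["trial"]), context=str(row["context"]),
            shown=shown, avail=avail, choice=choice, rt_ms=rt,
            outcomes=outcomes, gaze=gaze,
        ))
    return records


def write_trials(records: Sequence[TrialRecord], path) -> None:
    trials_to_frame(records).to_csv(path, index=False)


def read_trials(path) -> Dict[str, List[TrialRecord]]:
    """Read a trial CSV; returns records grouped by participant (file order)."""
    df = pd.read_csv(path, dtype={"participant": str})
    records = frame_to_trials(df, source=str(path))
    out: Dict[str, List[TrialRecord]] = {}
    for tr in records:
        out.setdefault(tr.participant, []).append(tr)
    return out


def attach_gaze(records: Sequence[TrialRecord], fixations: Dict[tuple, List[FixationRecord]]) -> List[TrialRecord]:
    """Fill each trial's gaze columns from raw fixation records.

    ``fixations`` maps (participant, trial) to that trial's fixation list,
    as returned by :func:`read_fixations`. Trials without fixation rows get
    all-zero gaze (no available symbol fixated).
    """
    from dataclasses import replace

    from .gaze import proportional_gaze

    out = []
    for tr in records:
        fx = fixations.get((tr.participant, tr.trial), [])
        gv = proportional_gaze(fx, tr.avail)
        out.append(replace(tr, gaze={o: float(p) for o, p in zip(gv.options, gv.proportions)}))
    return out


def read_fixations(path, valid_ids: Optional[Sequence[str]] = None) -> Dict[tuple, List[FixationRecord]]:
    """Read a fixation CSV; returns records grouped by (participant, trial).

    If ``valid_ids`` is given, fixations with an unknown AOI label are
    treated as nonsymbol fixations (AOI None) with a warning, matching how
    nonsymbol fixations are excluded from the gaze denominator.
    """
    df = pd.read_csv(path, dtype={"participant": str, "aoi": str})
    required = ["participant", "trial", "aoi", "duration_ms", "order"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    valid = set(valid_ids) if valid_ids is not None else None
    out: Dict[tuple, List[FixationRecord]] = {}
    for i, row in df.iterrows():
        rownum = i + 2
        aoi = row["aoi"]
        aoi = None if pd.isna(aoi) or str(aoi).upper() == "NONE" else str(aoi)
        if aoi is not None and valid is not None and aoi not in valid:
            warnings.warn(
                f"{path} row {rownum}: unknown AOI label {aoi!r}; treating as nonsymbol fixation"
            )
            aoi = None
        try:
            dur = float(row["duration_ms"])
        except (TypeError, ValueError):
            raise SchemaError(f"{path} row {rownum}: duration_ms {row['duration_ms']!r} is not numeric") from None
        if dur < 0:
            raise SchemaError(f"{path} row {rownum}: negative duration {dur}")
        out.setdefault((str(row["participant"]), int(row["trial"])), []).append(
            FixationRecord(trial=int(row["trial"]), aoi=aoi, duration=dur, order=int(row["order"]))
        )
    return out


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return _jsonable(obj.to_dict())
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_report(obj, path) -> None:
    """Serialize a result object (dataclass / DataFrame / dict) as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)
        fh.write("\n")


@dataclass
class RunManifest:
    """Provenance for one CLI run: command, config hash, seeds, version."""

    command: str
    arguments: dict
    seed: Optional[int]
    config_hash: str = ""
    version: str = ""
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    @classmethod
    def create(cls, command: str, arguments: dict, seed: Optional[int]) -> "RunManifest":
        from . import __version__

        blob = json.dumps(_jsonable(arguments), sort_keys=True).encode()
        return cls(
            command=command,
            arguments=_jsonable(arguments),
            seed=seed,
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            version=__version__,
        )

    def write(self, path) -> None:
        write_report(dataclasses.asdict(self), path)
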