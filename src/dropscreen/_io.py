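"""CSV event tables, JSON configs/reports and run manifests.

Event tables are plain UTF-8 CSV with LF line endings, a required
header, the fixed column order of :data:`dropscreen.simulate.EVENT_COLUMNS`,
integer counts and True/False sort flags — chosen so that a
write → read → write cycle is byte-stable.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path
from typing import Union

import pandas as pd

from .simulate import EVENT_COLUMNS, ScreenConfig

__all__ = [
    "EventTableError",
    "read_events",
    "write_events",
    "read_config",
    "write_config",
    "config_hash",
    "RunManifest",
    "write_manifest",
]

_INT_COLS = [
    "droplet_id",
    "n_cells",
    "n_apoptotic",
    "n_colonies_recovered",
    "n_positive_colonies",
]
_CLONES = {"hit", "null", "empty"}


class EventTableError(ValueError):
    """Structured event-table failure naming the offending row/column."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(f"{message}" + (f" ({', '.join(loc)})" if loc else ""))
        self.row = row
        self.column = column


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check schema and per-row invariants; return the table unchanged."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise EventTableError(f"missing columns {missing}")
    for col in _INT_COLS:
        if len(events) and not pd.api.types.is_integer_dtype(events[col]):
            bad = events.index[pd.to_numeric(events[col], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else None
            raise EventTableError("non-integer count", row=row, column=col)
        if len(events) and (events[col] < 0).any():
            row = int(events.index[events[col] < 0][0])
            raise EventTableError("negative count", row=row, column=col)
    bad_clone = ~events["clone"].isin(_CLONES)
    if bad_clone.any():
        row = int(events.index[bad_clone][0])
        raise EventTableError(
            f"clone not in {sorted(_CLONES)}", row=row, column="clone"
        )
    over = events["n_apoptotic"] > events["n_cells"]
    if over.any():
        row = int(events.index[over][0])
        raise EventTableError("n_apoptotic > n_cells", row=row, column="n_apoptotic")
    over = events["n_positive_colonies"] > events["n_colonies_recovered"]
    if over.any():
        row = int(events.index[over][0])
        raise EventTableError(
            "n_positive_colonies > n_colonies_recovered",
            row=row,
            column="n_positive_colonies",
        )
    return events


def read_events(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate an event table CSV."""
    try:
        # keep_default_na: "null" is a clone label, not a missing value
        events = pd.read_csv(path, dtype={"clone": str}, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise EventTableError(f"cannot parse {path}: {exc}") from exc
    if len(events) == 0 and list(events.columns) != EVENT_COLUMNS:
        # header-only file must still carry the full schema
        validate_events(events)
    if "sorted_positive" in events.columns and events["sorted_positive"].dtype == object:
        events["sorted_positive"] = events["sorted_positive"].map(
            {"True": True, "False": False}
        )
    validate_events(events)
    return events[EVENT_COLUMNS]


def write_events(events: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a validated event table; returns the path written."""
    validate_events(events)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events[EVENT_COLUMNS].to_csv(path, index=False, lineterminator="\n")
    return path


def write_config(config: ScreenConfig, path: Union[str, Path], **extra) -> Path:
    """Serialize a ScreenConfig (plus optional metadata keys) as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"config": json.loads(config.model_dump_json()), **extra}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def read_config(path: Union[str, Path]) -> ScreenConfig:
    """Load a ScreenConfig from JSON; unknown keys are rejected."""
    doc = json.loads(Path(path).read_text())
    payload = doc.get("config", doc)
    return ScreenConfig.model_validate(payload)


def config_hash(config: ScreenConfig) -> str:
    """SHA-256 of the canonical JSON form of a config."""
    canon = json.dumps(
        json.loads(config.model_dump_json()), sort_keys=True, separators=(",", ":")
    )
    return hashlib.sha256(canon.encode()).hexdigest()


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Provenance record written once per output directory."""

    command: str
    config_sha256: str
    seed: int
    package_version: str
    created_utc: str


def write_manifest(
    out_dir: Union[str, Path], command: str, config: ScreenConfig, seed: int
) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        config_sha256=config_hash(config),
        seed=seed,
        package_version=__version__,
        created_utc=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")
    return path
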