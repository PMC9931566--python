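"""Delimited-text table I/O with header validation and run manifests.

Every table travels as a UTF-8 comma-delimited file with a header row
(RFC-4180 quoting via pandas). ``write_tables`` emits a ``manifest.json``
listing table names, row counts, seed, config hash and per-file SHA-256
checksums; ``read_tables`` validates required columns and preserves unknown
extra columns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from .synth import RawTables

#: required columns per table; extra columns are preserved on read
REQUIRED_COLUMNS: dict[str, list[str]] = {
    "persons": ["person_id", "birth_date", "sex", "race", "ethnicity", "zip",
                "deceased", "site_id"],
    "coded_events": ["person_id", "code", "vocabulary", "date",
                     "event_class", "inpatient"],
    "visits": ["person_id", "start_date", "end_date", "inpatient"],
    "tests": ["person_id", "test_date", "result"],
    "site_metadata": ["site_id", "lab_coverage", "valid_end_date_frac",
                      "date_shift_days"],
    "sdoh_by_zip": ["zip"],
    "truth": ["person_id", "subtype"],
}

#: columns kept as strings on read (leading-zero ZIPs, identifiers, dates)
_STRING_COLS = {"person_id", "zip", "code", "site_id", "birth_date", "date",
                "start_date", "end_date", "test_date"}


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def config_hash(obj) -> str:
    """Stable short hash of a config-like object (dataclass or dict)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_tables(tables: RawTables | dict[str, pd.DataFrame], out_dir,
                 seed: int | None = None, config=None) -> dict[str, Path]:
    """Write each table as <name>.csv plus a manifest; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(tables, RawTables):
        tables = tables.tables()
    paths: dict[str, Path] = {}
    manifest: dict = {"tables": {}, "seed": seed}
    if config is not None:
        manifest["config_hash"] = config_hash(config)
    for name, frame in tables.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False, encoding="utf-8")
        paths[name] = path
        manifest["tables"][name] = {
            "rows": int(len(frame)),
            "sha256": sha256_of(path),
        }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str), encoding="utf-8")
    return paths


def read_tables(in_dir) -> RawTables:
    """Read a generated table directory back into :class:`RawTables`.

    Missing required columns raise an error naming the table and column;
    unknown extra columns pass through untouched.
    """
    in_dir = Path(in_dir)
    frames: dict[str, pd.DataFrame] = {}
    for name, required in REQUIRED_COLUMNS.items():
        path = in_dir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing table file: {path}")
        dtype = {c: str for c in _STRING_COLS}
        frame = pd.read_csv(path, dtype=dtype, encoding="utf-8")
        for col in required:
            if col not in frame.columns:
                raise ValueError(f"{name}: {col} required")
        frames[name] = frame
    return RawTables(**frames)
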