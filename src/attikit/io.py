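"""CSV/JSON readers and writers plus run manifests.

CSV dialect: comma-separated, UTF-8, header row required, '.' decimal
separator.  Reports are versioned JSON; every pipeline run writes a
manifest (configuration, input hashes, package version, seed) sufficient
to reproduce deterministic outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import PairedMeasurements

__all__ = [
    "read_pairs_csv",
    "write_pairs_csv",
    "write_report_json",
    "read_report_json",
    "validate_report",
    "write_manifest",
]

REPORT_SCHEMA_VERSION = "1"
_REQUIRED_BLOCKS = (
    "normality",
    "ttest",
    "pearson",
    "icc",
    "bland_altman",
    "passing_bablok",
    "kappa",
)


class IOFormatError(ValueError):
    """Raised for malformed input files."""


def read_pairs_csv(path: str | Path) -> PairedMeasurements:
    """Read a paired-measurements table (columns id, mri, rx [, replicates])."""
    df = pd.read_csv(path)
    missing = {"id", "mri", "rx"} - set(df.columns)
    if missing:
        raise IOFormatError(f"{path}: missing required columns {sorted(missing)}")
    for col in df.columns:
        if col == "id":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
        if bad.size:
            # +2: 1-based rows plus the header line
            raise IOFormatError(
                f"{path}: non-numeric or missing value in column {col!r} at row {bad[0] + 2}"
            )
        df[col] = vals
    return PairedMeasurements(df)


def write_pairs_csv(pairs: PairedMeasurements, path: str | Path) -> None:
    pairs.df.to_csv(path, index=False)


def write_report_json(report, path: str | Path) -> None:
    d = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    validate_report(d)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)


def read_report_json(path: str | Path) -> dict:
    with open(path) as fh:
        d = json.load(fh)
    validate_report(d)
    return d


def validate_report(d: dict) -> None:
    """Structural validation of a method-comparison report dictionary."""
    if d.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise IOFormatError(
            f"report schema_version {d.get('schema_version')!r} != {REPORT_SCHEMA_VERSION!r}"
        )
    for block in _REQUIRED_BLOCKS:
        if block not in d:
            raise IOFormatError(f"report missing block {block!r}")
    for key in ("bias", "sd_diff", "loa_low", "loa_high"):
        if key not in d["bland_altman"]:
            raise IOFormatError(f"bland_altman block missing {key!r}")
    for key in ("slope", "intercept", "cusum_p"):
        if key not in d["passing_bablok"]:
            raise IOFormatError(f"passing_bablok block missing {key!r}")
    for key in ("icc_single", "icc_average"):
        if key not in d["icc"]:
            raise IOFormatError(f"icc block missing {key!r}")


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: dict, inputs: list[str | Path] = ()) -> Path:
    """Write a reproducibility manifest next to a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "attikit",
        "version": __version__,
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config,
        "input_hashes": {str(p): _hash_file(Path(p)) for p in inputs},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
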