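"""Delimited-text I/O and run manifests.

All interchange is plain CSV (UTF-8, "." decimal): the protein matrix
(first column ``sample_id``, remaining columns numeric), the sample
metadata table, and the censoring-interval table (``sample_id, L_years,
R_years`` with the literal ``inf`` for right censoring).  Times are years
from blood draw; converting visit dates to intervals is the caller's
concern.
"""

from __future__ import annotations

import hashlib
import json
import math
import platform
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import IntervalObservation

__all__ = [
    "read_protein_csv",
    "write_protein_csv",
    "read_meta_csv",
    "write_meta_csv",
    "read_intervals_csv",
    "write_intervals_csv",
    "write_manifest",
]


def read_protein_csv(path) -> pd.DataFrame:
    """Read a samples x proteins abundance matrix.

    Blank cells become NaN (missing); malformed numeric cells and
    duplicated sample or protein ids are rejected with the offending
    identifier named.
    """
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate sample id {dup.iloc[0]!r}")
    cols = pd.Index(df.columns[1:])
    if cols.duplicated().any():
        raise ValueError(f"{path}: duplicate protein id {cols[cols.duplicated()][0]!r}")
    out = df.set_index("sample_id")
    for c in out.columns:
        parsed = np.empty(len(out), dtype=float)
        for i, v in enumerate(out[c].to_numpy(dtype=object)):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                parsed[i] = math.nan  # blank cell -> missing
                continue
            try:
                parsed[i] = float(v)  # exact round-trip parse
            except (TypeError, ValueError) as err:
                raise ValueError(
                    f"{path}: malformed value {v!r} at sample "
                    f"{out.index[i]!r}, protein {c!r}"
                ) from err
        out[c] = parsed
    return out


def write_protein_csv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=True, index_label="sample_id")


def read_meta_csv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype=str)
    required = {"sample_id", "group", "outcome"}
    if not required.issubset(meta.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(required)}")
    bad = set(meta["group"]) - {"case", "control"}
    if bad:
        raise ValueError(f"{path}: unknown group value {sorted(bad)[0]!r}")
    bad = set(meta["outcome"]) - {"progressor", "non_progressor", "not_applicable"}
    if bad:
        raise ValueError(f"{path}: unknown outcome value {sorted(bad)[0]!r}")
    ctrl_bad = meta[(meta["group"] == "control") != (meta["outcome"] == "not_applicable")]
    if not ctrl_bad.empty:
        raise ValueError(
            f"{path}: outcome must be 'not_applicable' iff group is 'control' "
            f"(sample {ctrl_bad['sample_id'].iloc[0]!r})"
        )
    return meta


def write_meta_csv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def read_intervals_csv(path) -> list[IntervalObservation]:
    df = pd.read_csv(path)
    required = {"sample_id", "L_years", "R_years"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: intervals file needs columns {sorted(required)}")
    out = []
    for i, row in df.iterrows():
        L = float(row["L_years"])
        R = float(row["R_years"])  # 'inf' parses to math.inf
        try:
            out.append(IntervalObservation(str(row["sample_id"]), L, R))
        except ValueError as err:
            raise ValueError(f"{path}: row {i + 2}: {err}") from err
    return out


def write_intervals_csv(obs: Sequence[IntervalObservation], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [o.sample_id for o in obs],
            "L_years": [o.L for o in obs],
            "R_years": ["inf" if math.isinf(o.R) else o.R for o in obs],
        }
    ).to_csv(path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seed: int, inputs: dict[str, str] | None = None) -> Path:
    """Record everything needed to reproduce a run: config echo, seed,
    package/library versions and input-file digests."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "pressc": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {name: _sha256(p) for name, p in (inputs or {}).items()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path
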