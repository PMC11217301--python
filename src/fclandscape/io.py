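"""File I/O for parcellated timeseries, metadata, covariates and results.

All exchange formats are plain text: tab-separated matrices (regions as
rows, timepoints as columns; stability matrices are time x time), TSV
metadata/covariate tables, and JSON summaries.  Matrices round-trip
through ``write_matrix`` / ``read_matrix`` at full double precision.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParcellatedTimeseries",
    "CovariateTable",
    "read_timeseries",
    "read_covariates",
    "read_matrix",
    "write_matrix",
    "write_results",
]

# full double precision so write -> read reproduces values exactly
_MATRIX_FMT = "%.17g"


@dataclass
class ParcellatedTimeseries:
    """A per-subject regions x timepoints signal matrix with region labels.

    Parameters
    ----------
    subject_id:
        Identifier used to derive deterministic output filenames.
    data:
        ``(n_regions, n_timepoints)`` float array of signal values
        (arbitrary units, e.g. mean BOLD per parcel).
    region_names:
        Unique name per region (row).
    network_labels:
        Resting-state-network assignment per region; treated as opaque
        strings.
    tr_seconds:
        Sampling interval (repetition time) in seconds.
    """

    subject_id: str
    data: np.ndarray
    region_names: list[str]
    network_labels: list[str]
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("timeseries data must be a 2-D matrix")
        n, t = self.data.shape
        if n < 2:
            raise ValueError(f"need at least 2 regions, got {n}")
        if t < 4:
            raise ValueError(f"need at least 4 timepoints, got {t}")
        if not np.isfinite(self.data).all():
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite value at region row {bad[0]}, timepoint {bad[1]}"
            )
        self.region_names = [str(r) for r in self.region_names]
        self.network_labels = [str(l) for l in self.network_labels]
        if len(self.region_names) != n:
            raise ValueError(
                f"{len(self.region_names)} region names for {n} regions"
            )
        if len(self.network_labels) != n:
            raise ValueError(
                f"{len(self.network_labels)} network labels for {n} regions"
            )
        seen: set[str] = set()
        for name in self.region_names:
            if name in seen:
                raise ValueError(f"duplicate region name: {name!r}")
            seen.add(name)
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def network_members(self, network: str) -> np.ndarray:
        """Row indices of the regions assigned to ``network``."""
        idx = np.array(
            [i for i, l in enumerate(self.network_labels) if l == network],
            dtype=int,
        )
        if idx.size == 0:
            raise KeyError(f"unknown network label: {network!r}")
        return idx


@dataclass
class CovariateTable:
    """Per-subject covariates: group membership, age (years) and sex."""

    table: pd.DataFrame
    group_levels: tuple[str, ...] = ()

    REQUIRED = ("subject_id", "group", "age", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")
        if self.table["subject_id"].duplicated().any():
            dup = self.table["subject_id"][self.table["subject_id"].duplicated()]
            raise ValueError(f"duplicate subject rows: {sorted(set(dup))}")
        if not self.group_levels:
            self.group_levels = tuple(sorted(self.table["group"].unique()))
        unknown = set(self.table["group"]) - set(self.group_levels)
        if unknown:
            raise ValueError(f"group labels outside declared set: {unknown}")
        if not np.isfinite(self.table["age"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite age values")

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, group: str) -> pd.DataFrame:
        return self.table[self.table["group"] == group]


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a TSV numeric matrix, reporting the location of any bad cell."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(values))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric or missing cell at row {r}, column {c}: "
            f"{df.iat[r, c]!r}"
        )
    return values


def write_matrix(matrix: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt=_MATRIX_FMT, delimiter="\t")
    return path


def read_timeseries(
    path: str | Path,
    metadata_path: str | Path,
    tr_seconds: float = 2.0,
    subject_id: str | None = None,
) -> ParcellatedTimeseries:
    """Load a regions x timepoints TSV matrix plus its region-metadata sidecar.

    The metadata table must have columns ``region_name`` and
    ``network_label`` with one row per matrix row, in the same order.
    """
    data = read_matrix(path)
    meta = pd.read_csv(metadata_path, sep="\t")
    for col in ("region_name", "network_label"):
        if col not in meta.columns:
            raise ValueError(f"{metadata_path}: metadata missing column {col!r}")
    if len(meta) != data.shape[0]:
        raise ValueError(
            f"dimension mismatch: matrix has {data.shape[0]} region rows but "
            f"metadata has {len(meta)} rows"
        )
    if subject_id is None:
        subject_id = Path(path).stem
    return ParcellatedTimeseries(
        subject_id=subject_id,
        data=data,
        region_names=list(meta["region_name"].astype(str)),
        network_labels=list(meta["network_label"].astype(str)),
        tr_seconds=tr_seconds,
    )


def read_covariates(path: str | Path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path, sep="\t"))


def _json_default(x: Any) -> Any:
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating, float)):
        return _round_sig(float(x))
    if isinstance(x, np.ndarray):
        return x.tolist()
    if hasattr(x, "__dict__"):
        return vars(x)
    raise TypeError(f"unserializable: {type(x)}")


def _round_sig(x: float, sig: int = 10):
    """10 significant digits; infinities become the string sentinel 'inf'."""
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    if math.isnan(x):
        return "nan"
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return _round_sig(float(obj))
    if isinstance(obj, (np.integer, int, str, bool)) or obj is None:
        return obj
    if hasattr(obj, "to_summary_dict"):
        return _jsonable(obj.to_summary_dict())
    if hasattr(obj, "__dict__"):
        return _jsonable(vars(obj))
    return repr(obj)


def write_json(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
    return path


_SAFE = re.compile(r"[^A-Za-z0-9._-]+")


def _slug(s: str) -> str:
    return _SAFE.sub("_", s)


def write_results(
    results: Mapping[str, Any], out_dir: str | Path, subject_id: str = "subject"
) -> list[Path]:
    """Write pipeline outputs under ``out_dir``.

    ``results`` maps a stage name (e.g. ``"stability_matrix"``) to either a
    2-D array (written as TSV) or any summary object (written as JSON).
    Filenames are deterministic: ``<subject>_<stage>.tsv`` / ``.json``.
    An empty mapping writes nothing and succeeds.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise NotADirectoryError(str(out_dir))
    written: list[Path] = []
    for stage, obj in results.items():
        base = f"{_slug(subject_id)}_{_slug(stage)}"
        arr = getattr(obj, "phi", getattr(obj, "z_matrix", obj))
        if isinstance(arr, np.ndarray) and arr.ndim == 2:
            written.append(write_matrix(arr, out_dir / f"{base}.tsv"))
        else:
            written.append(write_json(obj, out_dir / f"{base}.json"))
    return written
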