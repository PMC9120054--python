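"""Cohort data model and plain-text I/O.

Matrices are stored one file per subject as square numeric TSV without
headers; region order is defined solely by the region table.  Metadata is
a CSV with one row per subject.  Missing scores/volumes are empty cells,
never silently imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from connstat.regions import RegionTable

logger = logging.getLogger(__name__)

#: max|W - W.T| <= ASYMMETRY_RTOL * max(W) is silently symmetrized by averaging.
ASYMMETRY_RTOL = 1e-8

GROUPS = ("MDD", "HC")
SEXES = ("male", "female")

METADATA_REQUIRED = ["subject_id", "group", "age", "sex"]

RESULT_COLUMN_ORDER = [
    "region",
    "metric",
    "statistic",
    "effect_size",
    "p",
    "q",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative weighted adjacency over parcellation regions."""

    weights: np.ndarray
    region_table: RegionTable = field(repr=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"matrix must be square, got shape {W.shape}")
        if W.shape[0] != len(self.region_table):
            raise ValueError(
                f"dimension mismatch: matrix is {W.shape[0]}x{W.shape[0]} "
                f"but region table has {len(self.region_table)} regions"
            )
        if not np.all(np.isfinite(W)):
            raise ValueError("non-finite weight")
        if (W < 0).any():
            raise ValueError("negative weight")
        asym = np.abs(W - W.T).max()
        scale = W.max() if W.size else 0.0
        if asym > 0:
            if scale > 0 and asym > ASYMMETRY_RTOL * scale:
                raise ValueError(
                    f"matrix asymmetry {asym:.3g} exceeds tolerance "
                    f"{ASYMMETRY_RTOL * scale:.3g}"
                )
            W = (W + W.T) / 2.0
        if np.any(np.diag(W) != 0):
            logger.warning("nonzero diagonal forced to zero")
            W = W.copy()
            np.fill_diagonal(W, 0.0)
        self.weights = W

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.weights, delimiter="\t", fmt="%.12g")

    @classmethod
    def from_tsv(cls, path, region_table: RegionTable) -> "ConnectivityMatrix":
        W = np.loadtxt(path, delimiter="\t", ndmin=2)
        return cls(W, region_table)


@dataclass
class SubjectRecord:
    """One subject's metadata; missing scores are None, missing volumes NaN."""

    subject_id: str
    group: str
    age: float
    sex: str
    medication_history: int | None = None
    madrs: float | None = None
    qids: float | None = None
    episode_duration: float | None = None
    region_volumes: np.ndarray | None = None  # NaN where unavailable

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not np.isfinite(self.age):
            raise ValueError("age must be present and finite")


@dataclass
class Cohort:
    """Subjects paired with their connectivity matrices over one parcellation."""

    region_table: RegionTable
    subjects: list[SubjectRecord]
    matrices: list[ConnectivityMatrix]

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.matrices):
            raise ValueError("one matrix per subject required")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")
        for m in self.matrices:
            if m.n_regions != len(self.region_table):
                raise ValueError("matrix region count does not match region table")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def group_labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def indices_of_group(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.group_labels == group)

    def stacked_weights(self) -> np.ndarray:
        """(n_subjects, N, N) array of all weight matrices."""
        return np.stack([m.weights for m in self.matrices])

    def volumes_matrix(self) -> np.ndarray:
        """(n_subjects, N) region volumes, NaN where missing."""
        N = len(self.region_table)
        out = np.full((len(self.subjects), N), np.nan)
        for i, s in enumerate(self.subjects):
            if s.region_volumes is not None:
                out[i] = s.region_volumes
        return out


def _parse_subject_row(row: pd.Series, region_table: RegionTable) -> SubjectRecord:
    vol_cols = [f"vol_{name}" for name in region_table.names]
    volumes = None
    if any(c in row.index for c in vol_cols):
        volumes = np.array([float(row[c]) if c in row.index and pd.notna(row[c]) else np.nan for c in vol_cols])

    def opt(key, cast=float):
        if key in row.index and pd.notna(row[key]):
            return cast(row[key])
        return None

    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        group=str(row["group"]),
        age=float(row["age"]),
        sex=str(row["sex"]),
        medication_history=opt("medication_history", int),
        madrs=opt("madrs"),
        qids=opt("qids"),
        episode_duration=opt("episode_duration"),
        region_volumes=volumes,
    )


def read_metadata(path, region_table: RegionTable) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    missing = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    return [_parse_subject_row(row, region_table) for _, row in df.iterrows()]


def write_metadata(subjects: list[SubjectRecord], region_table: RegionTable, path) -> None:
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "sex": s.sex,
            "medication_history": s.medication_history,
            "madrs": s.madrs,
            "qids": s.qids,
            "episode_duration": s.episode_duration,
        }
        if s.region_volumes is not None:
            for name, v in zip(region_table.names, s.region_volumes):
                row[f"vol_{name}"] = v if np.isfinite(v) else None
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(matrix_paths: list, metadata_path, region_path) -> Cohort:
    """Load and validate a cohort from plain-text files.

    Matrix file order must match the metadata row order.
    """
    region_table = RegionTable.from_csv(region_path)
    subjects = read_metadata(metadata_path, region_table)
    if len(matrix_paths) != len(subjects):
        raise ValueError(
            f"{len(matrix_paths)} matrix files but {len(subjects)} metadata rows"
        )
    matrices = [ConnectivityMatrix.from_tsv(p, region_table) for p in matrix_paths]
    return Cohort(region_table, subjects, matrices)


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write the standard cohort layout; returns the paths written."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    region_path = out / "regions.csv"
    cohort.region_table.to_csv(region_path)
    metadata_path = out / "metadata.csv"
    write_metadata(cohort.subjects, cohort.region_table, metadata_path)
    matrix_paths = []
    for s, m in zip(cohort.subjects, cohort.matrices):
        p = out / f"{s.subject_id}.tsv"
        m.to_tsv(p)
        matrix_paths.append(p)
    return {"regions": region_path, "metadata": metadata_path, "matrices": matrix_paths}


def write_results(results: pd.DataFrame, path) -> None:
    """Serialize a results table as CSV with fixed column and row order.

    Requires ``region_index`` and ``metric`` columns for deterministic
    ordering; the ``q`` column is optional (uncorrected output mode).
    Values round-trip at 12 significant digits.
    """
    if results is None or len(results) == 0:
        raise ValueError("results table is empty")
    df = results.copy()
    sort_cols = [c for c in ("region_index", "metric", "score") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    ordered = [c for c in RESULT_COLUMN_ORDER if c in df.columns]
    rest = [c for c in df.columns if c not in ordered]
    df = df[ordered + rest]
    df.to_csv(path, index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
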