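"""TSV readers and writers for matrices, covariate tables, and cohorts.

Matrix dialect: tab-separated, a header row and a header column of region
abbreviations in atlas order, full (not triangular) matrix — the simplest
layout to diff and validate by eye. Weights are written with 17 significant
digits so a write/read round trip reproduces them bit-identically.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GROUP_LABELS,
    SYMMETRY_TOL,
    CohortDataset,
    ConnectivityMatrix,
    RegionAtlas,
    SubjectRecord,
    validate_matrix,
)

log = logging.getLogger(__name__)


def read_connectivity_matrix(path, atlas: RegionAtlas) -> ConnectivityMatrix:
    """Read one subject's weighted matrix from TSV and validate it.

    The file must carry the atlas abbreviations as both header row and
    header column; rows may appear in any order and are realigned to atlas
    order. Asymmetry up to ``SYMMETRY_TOL`` is averaged away; anything
    larger is an error (it usually signals a transposition bug upstream).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    unknown = [a for a in df.index if a not in atlas._abbr_index]
    unknown += [a for a in df.columns if a not in atlas._abbr_index]
    if unknown:
        raise ValueError(f"unknown abbreviation(s) in {path}: {sorted(set(unknown))[:5]}")
    if len(df.index) != atlas.n or len(df.columns) != atlas.n:
        raise ValueError(
            f"dimension mismatch in {path}: {df.shape} vs atlas n={atlas.n}"
        )
    df = df.loc[atlas.abbreviations, atlas.abbreviations]
    try:
        w = df.to_numpy(dtype=float)
    except ValueError as e:
        raise ValueError(f"non-numeric cell in {path}: {e}") from None
    if np.any(w < 0):
        i, j = np.argwhere(w < 0)[0]
        raise ValueError(f"negative weight at ({i},{j}) in {path}")
    asym = np.max(np.abs(w - w.T)) if w.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ValueError(f"asymmetry {asym:g} exceeds tolerance {SYMMETRY_TOL:g} in {path}")
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    m = ConnectivityMatrix(w, atlas)
    violations = validate_matrix(m)
    if violations:
        raise ValueError(f"invalid matrix in {path}: {violations}")
    return m


def write_connectivity_matrix(m: ConnectivityMatrix, path) -> None:
    abbrs = m.atlas.abbreviations
    df = pd.DataFrame(m.weights, index=abbrs, columns=abbrs)
    df.to_csv(path, sep="\t", float_format="%.17g")


def _parse_score(cell) -> int | None:
    if pd.isna(cell) or cell == "":
        return None
    return int(cell)


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str}, comment="#")
    required = ["subject_id", "group", "age", "gender", "mmse", "nihss"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"covariate table missing columns: {missing}")
    bad = set(df["group"]) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}; expected {GROUP_LABELS}")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate subject_id(s): {dupes}")
    return df


def read_cohort(matrix_dir, covariate_table, atlas: RegionAtlas) -> CohortDataset:
    """Assemble a cohort from a matrix directory plus a covariate TSV.

    One file ``<subject_id>.tsv`` per row of the covariate table; subjects
    keep the table's order.
    """
    matrix_dir = Path(matrix_dir)
    cov = read_covariates(covariate_table)
    subjects = []
    for row in cov.itertuples(index=False):
        mpath = matrix_dir / f"{row.subject_id}.tsv"
        if not mpath.exists():
            raise FileNotFoundError(f"no matrix file for subject {row.subject_id!r}: {mpath}")
        subjects.append(
            SubjectRecord(
                subject_id=row.subject_id,
                group=row.group,
                age=float(row.age),
                gender=row.gender,
                mmse=_parse_score(row.mmse),
                nihss=_parse_score(row.nihss),
                matrix=read_connectivity_matrix(mpath, atlas),
            )
        )
    log.info("read %d subjects from %s", len(subjects), matrix_dir)
    return CohortDataset(subjects=subjects, atlas=atlas)


def write_cohort(cohort: CohortDataset, out_dir) -> None:
    """Write matrices (one TSV per subject) plus covariates.tsv."""
    out_dir = Path(out_dir)
    mdir = out_dir / "matrices"
    mdir.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        write_connectivity_matrix(s.matrix, mdir / f"{s.subject_id}.tsv")
    cov = cohort.covariates.copy()
    for col in ("mmse", "nihss"):
        cov[col] = cov[col].map(lambda v: "" if v is None else v)
    cov.to_csv(out_dir / "covariates.tsv", sep="\t", index=False)
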