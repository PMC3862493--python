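"""Domain types for weighted structural connectomes.

The node universe is a :class:`RegionAtlas` — an ordered table of brain
regions (id, name, abbreviation, hemisphere, volume). Every connectivity
matrix in a run shares one atlas, and region identity is keyed by
abbreviation so that reordered files remain interpretable.

A :class:`ConnectivityMatrix` is one subject's undirected weighted network:
symmetric, nonnegative, zero diagonal. Entry (i, j) > 0 means regions i and
j are connected (at least one reconstructed fiber between them); the weight
is a fiber connection density in 1/(mm^3 * mm).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

GROUP_LABELS = ("NC", "patient")

#: Maximum tolerated asymmetry before a matrix is rejected outright.
SYMMETRY_TOL = 1e-9


class RegionAtlas:
    """Ordered table of brain regions serving as the shared node universe.

    Parameters
    ----------
    table
        DataFrame with columns ``region_id``, ``name``, ``abbreviation``,
        ``hemisphere`` (L/R) and ``volume_mm3`` (positive). Row order is the
        node order of every matrix built against this atlas.
    """

    REQUIRED_COLUMNS = ("region_id", "name", "abbreviation", "hemisphere", "volume_mm3")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        table = table.reset_index(drop=True)
        abbrs = table["abbreviation"].tolist()
        if len(set(abbrs)) != len(abbrs):
            dupes = sorted({a for a in abbrs if abbrs.count(a) > 1})
            raise ValueError(f"duplicate region abbreviations: {dupes}")
        if not set(table["hemisphere"]) <= {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")
        if (table["volume_mm3"] <= 0).any():
            raise ValueError("region volumes must be positive")
        self.table = table
        self._abbr_index = {a: i for i, a in enumerate(abbrs)}
        self._id_index = {int(r): i for i, r in enumerate(table["region_id"])}

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def abbreviations(self) -> list[str]:
        return self.table["abbreviation"].tolist()

    @property
    def volumes(self) -> np.ndarray:
        """Region volumes in mm^3, atlas order."""
        return self.table["volume_mm3"].to_numpy(dtype=float)

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy(dtype=int)

    def index_of(self, abbreviation: str) -> int:
        return self._abbr_index[abbreviation]

    def index_of_id(self, region_id: int) -> int:
        return self._id_index[int(region_id)]

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionAtlas) and self.table.equals(other.table)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "RegionAtlas":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def default(cls) -> "RegionAtlas":
        """The bundled 90-region AAL atlas (45 regions per hemisphere).

        Region volumes in the bundled table are nominal synthetic values on
        a realistic scale; studies with real parcellations supply their own
        region table with measured volumes.
        """
        ref = importlib.resources.files("strokenet").joinpath("data/aal90.tsv")
        with importlib.resources.as_file(ref) as p:
            return cls.from_tsv(p)


class ConnectivityMatrix:
    """One subject's weighted undirected network over atlas regions."""

    def __init__(self, weights: np.ndarray, atlas: RegionAtlas):
        weights = np.asarray(weights, dtype=float)
        if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
            raise ValueError(f"weights must be square, got shape {weights.shape}")
        if weights.shape[0] != atlas.n:
            raise ValueError(
                f"matrix has {weights.shape[0]} nodes but atlas has {atlas.n} regions"
            )
        self.weights = weights
        self.atlas = atlas

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def copy(self) -> "ConnectivityMatrix":
        return ConnectivityMatrix(self.weights.copy(), self.atlas)


def validate_matrix(m: ConnectivityMatrix) -> list[str]:
    """Check connectivity-matrix invariants; return a list of violations.

    An empty list means the matrix is valid. Each violation names the rule
    broken and the offending indices. Violations are returned rather than
    raised so callers can report all of them at once.
    """
    w = m.weights
    violations: list[str] = []
    if not np.all(np.isfinite(w)):
        ii, jj = np.where(~np.isfinite(w))
        violations.append(f"non-finite entry at ({ii[0]},{jj[0]})")
    diag = np.flatnonzero(np.diag(w) != 0)
    for i in diag[:5]:
        violations.append(f"nonzero diagonal at ({i},{i})")
    neg = np.argwhere(w < 0)
    for i, j in neg[:5]:
        violations.append(f"negative weight at ({i},{j})")
    asym = np.argwhere(np.abs(w - w.T) > SYMMETRY_TOL)
    for i, j in asym[:5]:
        if i < j:
            violations.append(f"asymmetric at ({i},{j})")
    return violations


@dataclass
class SubjectRecord:
    """One subject: identity, group, covariates, and the connectome.

    MMSE (global cognition, 0-30) and NIHSS (stroke severity, >= 0) may be
    missing (None); subjects with a missing score are dropped per-analysis,
    never at load time.
    """

    subject_id: str
    group: str
    age: float
    gender: str
    mmse: Optional[int]
    nihss: Optional[int]
    matrix: ConnectivityMatrix

    def __post_init__(self):
        if self.group not in GROUP_LABELS:
            raise ValueError(
                f"unknown group label {self.group!r}; expected one of {GROUP_LABELS}"
            )
        if self.gender not in ("M", "F"):
            raise ValueError(f"gender must be 'M' or 'F', got {self.gender!r}")
        if not np.isfinite(self.age):
            raise ValueError("age must be finite")
        if self.mmse is not None and not (0 <= self.mmse <= 30):
            raise ValueError(f"MMSE out of range 0-30: {self.mmse}")
        if self.nihss is not None and self.nihss < 0:
            raise ValueError(f"NIHSS must be >= 0: {self.nihss}")


@dataclass
class CohortDataset:
    """Connectomes plus covariates for a two-group study."""

    subjects: list[SubjectRecord]
    atlas: RegionAtlas

    def __post_init__(self):
        for s in self.subjects:
            if s.matrix.atlas is not self.atlas and s.matrix.atlas != self.atlas:
                raise ValueError(f"subject {s.subject_id} uses a different atlas")

    def group(self, label: str) -> list[SubjectRecord]:
        if label not in GROUP_LABELS:
            raise ValueError(f"unknown group label {label!r}")
        return [s for s in self.subjects if s.group == label]

    @property
    def covariates(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "gender": [s.gender for s in self.subjects],
                "mmse": [s.mmse for s in self.subjects],
                "nihss": [s.nihss for s in self.subjects],
            }
        )
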