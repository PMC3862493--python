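"""Build a weighted connectivity matrix from labeled streamlines.

The edge weight between regions i and j is the fiber connection density:
the number of fibers connecting the two regions, each penalized by its
trajectory length, normalized by the regions' combined volume:

    w_ij = (2 / (V_i + V_j)) * sum_{f in F_e} 1 / l_f

where F_e is the set of fibers whose two endpoints fall in regions i and j,
l_f is fiber f's length along its trajectory (mm), and V_i, V_j are region
volumes (mm^3). Density has units 1/(mm^3 * mm). Two regions count as
connected when at least one fiber runs between them.

Fibers are assigned to a region pair by their endpoint labels only; fibers
with an unassigned endpoint or with both endpoints in the same region are
dropped (with a logged count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConnectivityMatrix, RegionAtlas

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Streamline:
    """One tracked fiber: an ordered polyline plus endpoint region labels."""

    points: np.ndarray  # (k, 3) coordinates in mm
    endpoint_regions: tuple | None = None  # (region_id|'unassigned', region_id|'unassigned')

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("a streamline needs >= 2 three-dimensional points")
        object.__setattr__(self, "points", pts)


@dataclass
class StreamlineSet:
    streamlines: list[Streamline]
    atlas: RegionAtlas

    def __post_init__(self):
        known = set(int(r) for r in self.atlas.region_ids)
        for s in self.streamlines:
            if s.endpoint_regions is None:
                continue
            for r in s.endpoint_regions:
                if r != UNASSIGNED and int(r) not in known:
                    raise ValueError(f"endpoint region {r} not in atlas")


@dataclass
class LabelGrid:
    """Voxelized region-label volume: one region id (or 0 = background) per voxel."""

    labels: np.ndarray  # (nx, ny, nz) integer labels, 0 = background
    voxel_size: tuple[float, float, float]  # mm per axis
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm coordinate of voxel (0,0,0)'s lower corner


def fiber_length(s: Streamline) -> float:
    """Length of the fiber along its trajectory: summed segment lengths (mm)."""
    seg = np.diff(s.points, axis=0)
    total = float(np.sqrt((seg**2).sum(axis=1)).sum())
    if total <= 0:
        raise ValueError("degenerate streamline: zero trajectory length")
    return total


def assign_endpoints(s: Streamline, grid: LabelGrid) -> Streamline:
    """Label both endpoints with the region of the voxel containing them.

    Voxels are half-open boxes [lower, upper) on each axis, so boundary
    points belong to the voxel on their upper side. Background (label 0)
    maps to 'unassigned'.
    """
    labels = []
    shape = np.array(grid.labels.shape)
    vox = np.asarray(grid.voxel_size, dtype=float)
    origin = np.asarray(grid.origin, dtype=float)
    for point in (s.points[0], s.points[-1]):
        idx = np.floor((np.asarray(point) - origin) / vox).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            raise ValueError(f"endpoint {point} outside grid bounds")
        lab = int(grid.labels[tuple(idx)])
        labels.append(UNASSIGNED if lab == 0 else lab)
    return replace(s, endpoint_regions=tuple(labels))


def fiber_density(fibers: list[Streamline], v_i: float, v_j: float) -> float:
    """Fiber connection density of one bundle between two regions.

    Expects every fiber in the bundle to connect the same (distinct) region
    pair; returns 0 for an empty bundle (the regions are not connected).
    """
    if v_i <= 0 or v_j <= 0:
        raise ValueError("region volumes must be positive")
    if not fibers:
        return 0.0
    pairs = {frozenset(f.endpoint_regions) for f in fibers if f.endpoint_regions}
    if len(pairs) > 1:
        raise ValueError(f"bundle mixes endpoint pairs: {pairs}")
    if pairs and len(next(iter(pairs))) != 2:
        raise ValueError("bundle connects a region to itself")
    inv_lengths = sum(1.0 / fiber_length(f) for f in fibers)
    return (2.0 / (v_i + v_j)) * inv_lengths


def build_matrix(ss: StreamlineSet, atlas: RegionAtlas) -> ConnectivityMatrix:
    """Aggregate a streamline set into the weighted connectivity matrix.

    Streamlines with an unassigned endpoint or with both endpoints in one
    region are skipped (counts logged). Symmetric by construction.
    """
    if ss.atlas is not atlas and ss.atlas != atlas:
        raise ValueError("streamline set was labeled against a different atlas")
    volumes = atlas.volumes
    inv_length_sums = np.zeros((atlas.n, atlas.n))
    n_unassigned = n_self = 0
    for s in ss.streamlines:
        if s.endpoint_regions is None or UNASSIGNED in s.endpoint_regions:
            n_unassigned += 1
            continue
        ra, rb = s.endpoint_regions
        if ra == rb:
            n_self += 1
            continue
        i, j = atlas.index_of_id(ra), atlas.index_of_id(rb)
        contrib = 1.0 / fiber_length(s)
        inv_length_sums[i, j] += contrib
        inv_length_sums[j, i] += contrib
    if n_unassigned or n_self:
        log.info(
            "dropped %d streamlines with unassigned endpoints, %d self-connections",
            n_unassigned,
            n_self,
        )
    norm = 2.0 / np.add.outer(volumes, volumes)
    w = norm * inv_length_sums
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, atlas)


# ---------------------------------------------------------------------------
# plain-text streamline IO (imaging-framework-free)


def write_streamlines(ss: StreamlineSet, path) -> None:
    """TSV: streamline_id, x, y, z per point; endpoint labels repeated per row."""
    rows = []
    for sid, s in enumerate(ss.streamlines):
        ra, rb = s.endpoint_regions if s.endpoint_regions else (UNASSIGNED, UNASSIGNED)
        for x, y, z in s.points:
            rows.append((sid, x, y, z, ra, rb))
    pd.DataFrame(
        rows, columns=["streamline_id", "x", "y", "z", "region_a", "region_b"]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_streamlines(path, atlas: RegionAtlas) -> StreamlineSet:
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    streamlines = []
    for _, grp in df.groupby("streamline_id", sort=True):
        ra, rb = grp["region_a"].iloc[0], grp["region_b"].iloc[0]

        def parse(r):
            return UNASSIGNED if str(r) == UNASSIGNED else int(r)

        streamlines.append(
            Streamline(
                points=grp[["x", "y", "z"]].to_numpy(dtype=float),
                endpoint_regions=(parse(ra), parse(rb)),
            )
        )
    return StreamlineSet(streamlines=streamlines, atlas=atlas)
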