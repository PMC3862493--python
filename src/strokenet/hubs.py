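"""Rank-based hub identification over group-mean nodal metrics.

A node earns one point per criterion it lands in: the top 20% by mean
strength, the *bottom* 20% by mean clustering, and the top 20% by mean
betweenness, regional efficiency, and vulnerability. The hub score is the
number of criteria met (0-5); a score of 2 or more makes the node a hub.

Metrics are computed per subject, then averaged across the group's subjects
per node, then ranked (average-then-rank, not rank-then-average).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RegionAtlas
from .metrics import NodalMetrics

log = logging.getLogger(__name__)

HUB_SCORE_THRESHOLD = 2
TOP_FRACTION = 0.2

#: criterion column -> (NodalMetrics field, ranking direction)
CRITERIA = {
    "high_strength": ("strength", "highest"),
    "low_clustering": ("clustering", "lowest"),
    "high_betweenness": ("betweenness", "highest"),
    "high_regional_efficiency": ("regional_efficiency", "highest"),
    "high_vulnerability": ("vulnerability", "highest"),
}


def top_fraction_mask(
    values: np.ndarray, fraction: float = TOP_FRACTION, direction: str = "highest"
) -> np.ndarray:
    """Flag exactly round(fraction * n) nodes by rank.

    Ties at the cutoff are broken deterministically by atlas (input) order,
    with a logged warning — reproducibility beats silent ambiguity.
    """
    values = np.asarray(values, dtype=float)
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if direction not in ("highest", "lowest"):
        raise ValueError(f"direction must be 'highest' or 'lowest', got {direction!r}")
    n = len(values)
    k = int(np.floor(fraction * n + 0.5))
    key = -values if direction == "highest" else values
    order = np.argsort(key, kind="stable")  # stable: ties keep atlas order
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    if 0 < k < n and key[order[k - 1]] == key[order[k]]:
        log.warning("tie at the top-%d cutoff broken by atlas order", k)
    return mask


def hub_scores(group_mean_metrics: NodalMetrics, atlas: RegionAtlas) -> pd.DataFrame:
    """Score every node against the five top-20% criteria.

    Returns the hub table: one row per region with the five criterion
    flags, the hub score, and the hub flag (score >= 2).
    """
    table = pd.DataFrame({"abbreviation": atlas.abbreviations})
    for col, (metric, direction) in CRITERIA.items():
        table[col] = top_fraction_mask(
            getattr(group_mean_metrics, metric), TOP_FRACTION, direction
        )
    table["hub_score"] = table[list(CRITERIA)].sum(axis=1).astype(int)
    table["is_hub"] = table["hub_score"] >= HUB_SCORE_THRESHOLD
    return table


@dataclass
class HubComparison:
    """Hub-set differences between two groups (by region abbreviation)."""

    shared: list[str]
    only_a: list[str]
    only_b: list[str]
    #: (abbreviation, score_a, score_b) for every node whose score differs
    score_changes: list[tuple[str, int, int]]


def compare_hub_sets(a: pd.DataFrame, b: pd.DataFrame) -> HubComparison:
    """Compare two hub tables built on the same atlas."""
    if list(a["abbreviation"]) != list(b["abbreviation"]):
        raise ValueError("hub tables use different atlases (region lists differ)")
    hubs_a = set(a.loc[a["is_hub"], "abbreviation"])
    hubs_b = set(b.loc[b["is_hub"], "abbreviation"])
    order = list(a["abbreviation"])
    changes = [
        (abbr, int(sa), int(sb))
        for abbr, sa, sb in zip(order, a["hub_score"], b["hub_score"])
        if sa != sb
    ]
    return HubComparison(
        shared=[r for r in order if r in hubs_a & hubs_b],
        only_a=[r for r in order if r in hubs_a - hubs_b],
        only_b=[r for r in order if r in hubs_b - hubs_a],
        score_changes=changes,
    )


def group_mean_nodal_metrics(per_subject: list[NodalMetrics]) -> NodalMetrics:
    """Average nodal metrics across a group's subjects, per node."""
    if not per_subject:
        raise ValueError("need at least one subject")
    return NodalMetrics(
        strength=np.mean([nm.strength for nm in per_subject], axis=0),
        clustering=np.mean([nm.clustering for nm in per_subject], axis=0),
        betweenness=np.mean([nm.betweenness for nm in per_subject], axis=0),
        regional_efficiency=np.mean(
            [nm.regional_efficiency for nm in per_subject], axis=0
        ),
        vulnerability=np.mean([nm.vulnerability for nm in per_subject], axis=0),
        degree=np.mean([nm.degree for nm in per_subject], axis=0),
    )
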