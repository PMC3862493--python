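"""Permutation group comparison, FDR correction, and clinical correlation.

The group test is a label-reshuffling permutation test: pool both groups,
reassign subjects to two groups of the original sizes, and recompute the
mean difference; the one-tailed p is the proportion of sampled assignments
whose difference is at least as extreme as the observed one, with ties
counting as exceedances. The identity labeling is always among the sampled
assignments (it ties the observed difference by construction), so p is
never 0 and the test is exact — under an exchangeable null,
P(p <= alpha) <= alpha at any n_perm. There is no further add-one
correction; the smallest reportable p is 1/n_perm.

Nodal comparisons are corrected with Benjamini-Hochberg FDR at level q;
clinical scores are related to metrics by Pearson partial correlation
controlling for age and gender (0/1 indicator), p from the t distribution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import CohortDataset
from .metrics import NodalMetrics, global_metrics, nodal_metrics
from .nulls import small_worldness

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# permutation machinery


@dataclass
class PermutationResult:
    metric_name: str
    observed_diff: float  # group A mean - group B mean
    p_one_tailed: float
    side: str
    n_perm: int
    seed: int
    null_diffs: np.ndarray = field(repr=False, default=None)


def _null_mean_diffs(
    pooled: np.ndarray, n_a: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean differences (first n_a vs rest) under label reshuffling.

    The first assignment is always the identity labeling, whose difference
    equals the observed one; the remaining n_perm - 1 are uniform random
    relabelings. ``pooled`` may be 1-D (one variable) or 2-D
    (n_subjects, n_vars); the result has shape (n_perm,) or
    (n_perm, n_vars).
    """
    n = pooled.shape[0]
    idx = np.tile(np.arange(n), (n_perm, 1))
    if n_perm > 1:
        idx[1:] = rng.permuted(idx[1:], axis=1)
    perm = pooled[idx]  # (n_perm, n) or (n_perm, n, n_vars)
    return perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)


def permutation_test(
    values_a,
    values_b,
    n_perm: int = 5000,
    side: str = "greater",
    seed: int = 0,
    metric_name: str = "",
    exact: bool = False,
) -> PermutationResult:
    """One-tailed permutation test on the difference of group means.

    With ``exact=True`` every distinct equal-size label assignment is
    enumerated instead of sampling, yielding the exact permutation p
    (feasible only for small total samples); ``n_perm`` is then ignored
    and reported as the number of assignments.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if side not in ("greater", "less"):
        raise ValueError(f"side must be 'greater' or 'less', got {side!r}")
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    if exact:
        null = np.array(
            [
                pooled[list(comb)].mean()
                - np.delete(pooled, list(comb)).mean()
                for comb in itertools.combinations(range(pooled.size), a.size)
            ]
        )
        n_perm = len(null)
    else:
        null = _null_mean_diffs(pooled, a.size, n_perm, rng)
    if side == "greater":
        p = float(np.count_nonzero(null >= observed)) / n_perm
    else:
        p = float(np.count_nonzero(null <= observed)) / n_perm
    return PermutationResult(
        metric_name=metric_name,
        observed_diff=float(observed),
        p_one_tailed=p,
        side=side,
        n_perm=n_perm,
        seed=seed,
        null_diffs=null,
    )


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at level q.

    Returns (rejected mask, critical p) where the critical p is the largest
    p value still rejected — 0 when nothing is rejected, mirroring the
    convention of reporting "FDR critical p-value = 0" for a null result.
    """
    p = np.asarray(p_values, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    rejected = multipletests(p, alpha=q, method="fdr_bh")[0]
    critical_p = float(p[rejected].max()) if rejected.any() else 0.0
    return rejected, critical_p


# ---------------------------------------------------------------------------
# partial correlation


@dataclass
class PartialCorrelationResult:
    r: float
    p: float
    n_effective: int
    covariates: list[str]


def partial_correlation(x, y, covariates=None, covariate_names=None) -> PartialCorrelationResult:
    """Pearson partial correlation of x and y given covariates.

    Both variables are residualized on the covariates plus an intercept by
    least squares; r is the Pearson correlation of the residuals and p comes
    from the t statistic with n - 2 - n_covariates degrees of freedom
    (two-sided).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    k = z.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete observations, got {n}")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    coef, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ coef
    rx, ry = resid[:, 0], resid[:, 1]
    scale = max(x.var(), y.var(), 1.0)
    if rx.var() <= 1e-15 * scale or ry.var() <= 1e-15 * scale:
        raise ValueError("zero residual variance after removing covariates")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clamped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clamped * np.sqrt(df / (1.0 - r_clamped**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrelationResult(
        r=r,
        p=p,
        n_effective=n,
        covariates=list(covariate_names) if covariate_names else [f"z{i}" for i in range(k)],
    )


# ---------------------------------------------------------------------------
# cohort-level metric tables


def cohort_nodal_metrics(cohort: CohortDataset) -> list[NodalMetrics]:
    """Nodal metrics for every subject, in cohort order."""
    return [nodal_metrics(s.matrix) for s in cohort.subjects]


def global_metric_table(
    cohort: CohortDataset,
    n_random: int = 0,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> pd.DataFrame:
    """Per-subject global metrics; with n_random > 0, adds the normalized
    small-world quantities gamma, lambda, sigma (one surrogate ensemble per
    subject, seeds spawned deterministically from ``seed``)."""
    rows = []
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(len(cohort.subjects)) if n_random > 0 else [None] * len(cohort.subjects)
    for s, child in zip(cohort.subjects, children):
        gm = global_metrics(s.matrix)
        row = {"subject_id": s.subject_id, "group": s.group, **gm.as_dict()}
        if n_random > 0:
            sw = small_worldness(
                s.matrix, n_random=n_random, rng_seed=child, swaps_per_edge=swaps_per_edge
            )
            row.update({"gamma": sw.gamma, "lambda": sw.lam, "sigma": sw.sigma})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparison


@dataclass
class NodalComparisonTable:
    """Per-node group comparison for one metric, FDR-corrected."""

    metric_name: str
    table: pd.DataFrame  # abbreviation, observed_diff, p_one_tailed, side, fdr_significant
    fdr_critical_p: float
    q: float
    n_perm: int
    seed: int


def _choose_side(observed: float) -> str:
    # post-hoc: test in the direction of the observed difference
    return "greater" if observed >= 0 else "less"


def compare_groups_global(
    global_table: pd.DataFrame,
    metric_names=None,
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    sides: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Permutation tests on per-subject global metrics (patient vs NC).

    The observed difference is patient mean minus NC mean. Unless an
    explicit side is configured per metric, the test direction follows the
    observed difference (flagged as post-hoc in the report). Significance
    at p < alpha, uncorrected.
    """
    if metric_names is None:
        metric_names = [
            c for c in global_table.columns if c not in ("subject_id", "group")
        ]
    is_patient = (global_table["group"] == "patient").to_numpy()
    rows = []
    seq = np.random.SeedSequence(seed)
    for metric, child in zip(metric_names, seq.spawn(len(metric_names))):
        vals = global_table[metric].to_numpy(dtype=float)
        a, b = vals[is_patient], vals[~is_patient]
        side = (sides or {}).get(metric) or _choose_side(a.mean() - b.mean())
        res = permutation_test(
            a, b, n_perm=n_perm, side=side,
            seed=int(child.generate_state(1)[0] % 2**31), metric_name=metric,
        )
        rows.append(
            {
                "metric": metric,
                "patient_mean": a.mean(),
                "nc_mean": b.mean(),
                "observed_diff": res.observed_diff,
                "side": res.side,
                "p_one_tailed": res.p_one_tailed,
                "significant": res.p_one_tailed < alpha,
            }
        )
    return pd.DataFrame(rows)


def compare_groups_nodal(
    cohort: CohortDataset,
    per_subject: list[NodalMetrics] | None = None,
    metric_names=None,
    n_perm: int = 5000,
    seed: int = 0,
    q: float = 0.05,
    sides: dict[str, str] | None = None,
) -> dict[str, NodalComparisonTable]:
    """Node-wise permutation tests per metric, BH-FDR corrected at q.

    All nodes of one metric share a single set of label permutations
    (vectorized), then the per-node one-tailed p values enter the BH
    step-up together.
    """
    if per_subject is None:
        per_subject = cohort_nodal_metrics(cohort)
    if metric_names is None:
        metric_names = list(NodalMetrics.METRIC_NAMES)
    groups = np.array([s.group for s in cohort.subjects])
    is_patient = groups == "patient"
    order = np.argsort(~is_patient, kind="stable")  # patients first
    n_a = int(is_patient.sum())
    if n_a == 0 or n_a == len(groups):
        raise ValueError("both groups must be present")
    abbrs = cohort.atlas.abbreviations
    out: dict[str, NodalComparisonTable] = {}
    seq = np.random.SeedSequence(seed)
    for metric, child in zip(metric_names, seq.spawn(len(metric_names))):
        vals = np.stack([getattr(nm, metric) for nm in per_subject])  # (n_subj, n_nodes)
        pooled = vals[order]
        observed = pooled[:n_a].mean(axis=0) - pooled[n_a:].mean(axis=0)
        mseed = int(child.generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(mseed)
        null = _null_mean_diffs(pooled, n_a, n_perm, rng)  # (n_perm, n_nodes)
        side = np.where(observed >= 0, "greater", "less")
        if sides and metric in sides:
            side = np.full(len(abbrs), sides[metric])
        p = np.where(
            side == "greater",
            np.count_nonzero(null >= observed, axis=0) / n_perm,
            np.count_nonzero(null <= observed, axis=0) / n_perm,
        )
        rejected, critical_p = fdr_bh(p, q=q)
        out[metric] = NodalComparisonTable(
            metric_name=metric,
            table=pd.DataFrame(
                {
                    "abbreviation": abbrs,
                    "observed_diff": observed,
                    "side": side,
                    "p_one_tailed": p,
                    "fdr_significant": rejected,
                }
            ),
            fdr_critical_p=critical_p,
            q=q,
            n_perm=n_perm,
            seed=mseed,
        )
    return out


# ---------------------------------------------------------------------------
# clinical correlation


def correlate_clinical(
    cohort: CohortDataset,
    score: str,
    level: str = "nodal",
    alpha: float = 0.001,
    per_subject: list[NodalMetrics] | None = None,
    global_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Partial correlation of a clinical score with network metrics.

    Computed in the patient group only, controlling for age and gender;
    subjects missing the score are dropped listwise (with a logged count).
    Nodal level yields one row per (metric, region); global level one row
    per metric. Significance is flagged at p < alpha, uncorrected.
    """
    if score not in ("mmse", "nihss"):
        raise ValueError("score must be 'mmse' or 'nihss'")
    patients = cohort.group("patient")
    have = [s for s in patients if getattr(s, score) is not None]
    dropped = len(patients) - len(have)
    if dropped:
        log.info("dropped %d patients missing %s", dropped, score)
    if len(have) < 5:
        raise ValueError(f"need >= 5 patients with {score}, got {len(have)}")
    y = np.array([float(getattr(s, score)) for s in have])
    if np.var(y) == 0:
        raise ValueError(f"zero residual variance: {score} is constant across patients")
    cov = np.column_stack(
        [
            [s.age for s in have],
            [1.0 if s.gender == "M" else 0.0 for s in have],
        ]
    )
    rows = []
    if level == "nodal":
        if per_subject is None:
            per_subject = cohort_nodal_metrics(cohort)
        by_id = {s.subject_id: nm for s, nm in zip(cohort.subjects, per_subject)}
        for metric in NodalMetrics.METRIC_NAMES:
            vals = np.stack([getattr(by_id[s.subject_id], metric) for s in have])
            for j, abbr in enumerate(cohort.atlas.abbreviations):
                try:
                    res = partial_correlation(
                        vals[:, j], y, cov, covariate_names=["age", "gender"]
                    )
                except ValueError:
                    continue  # constant metric at this node
                rows.append(
                    {
                        "metric": metric,
                        "region": abbr,
                        "r": res.r,
                        "p": res.p,
                        "n": res.n_effective,
                        "significant": res.p < alpha,
                    }
                )
    elif level == "global":
        if global_table is None:
            raise ValueError("global level requires a per-subject global metric table")
        sub = global_table.set_index("subject_id").loc[[s.subject_id for s in have]]
        for metric in [c for c in sub.columns if c != "group"]:
            res = partial_correlation(
                sub[metric].to_numpy(dtype=float), y, cov, covariate_names=["age", "gender"]
            )
            rows.append(
                {
                    "metric": metric,
                    "region": "",
                    "r": res.r,
                    "p": res.p,
                    "n": res.n_effective,
                    "significant": res.p < alpha,
                }
            )
    else:
        raise ValueError("level must be 'nodal' or 'global'")
    return pd.DataFrame(rows)
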