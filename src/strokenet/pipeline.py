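"""End-to-end orchestration: simulate or load, analyze, report.

Stage outputs are plain TSV files, so each stage is testable in isolation
and the stages compose: running them one by one with the same master seed
produces byte-identical tables to a single ``run_pipeline`` call. A
run-manifest (YAML) captures every parameter and derived seed, and alone
suffices to reproduce every number in the report bundle.

Per-stage seeds are derived deterministically from the master seed and the
stage name, so adding a stage never shifts another stage's stream.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as snio
from .core import CohortDataset, RegionAtlas
from .hubs import compare_hub_sets, group_mean_nodal_metrics, hub_scores
from .metrics import NodalMetrics
from .simulate import NihssLink, SyntheticCohortSpec, generate_cohort
from .stats import (
    cohort_nodal_metrics,
    compare_groups_global,
    compare_groups_nodal,
    correlate_clinical,
    global_metric_table,
)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Parameters of one full analysis run.

    Defaults are the study constants this pipeline targets: 100 matched
    random networks per subject, 5,000 permutations, FDR q = 0.05, and a
    clinical-correlation threshold of p < 0.001 (uncorrected).
    """

    out_dir: str = "strokenet_run"
    # either simulate ...
    simulate: SyntheticCohortSpec | None = None
    # ... or load from disk
    matrix_dir: str | None = None
    covariate_table: str | None = None
    atlas_table: str | None = None
    n_random: int = 100
    swaps_per_edge: int = 10
    n_perm: int = 5000
    q: float = 0.05
    alpha_global: float = 0.05
    alpha_corr: float = 0.001
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            link = sim.pop("nihss_link", None)
            spec = SyntheticCohortSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()})
            if link is not None:
                spec.nihss_link = NihssLink(**link)
            cfg.simulate = spec
        return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: master seed mixed with a hash of the name."""
    return int((master_seed * 2654435761 + zlib.crc32(stage.encode())) % 2**31)


def load_or_simulate(config: RunConfig) -> CohortDataset:
    if config.simulate is not None:
        cohort, _ = generate_cohort(config.simulate)
        return cohort
    if not (config.matrix_dir and config.covariate_table):
        raise ValueError("config needs either a simulation spec or matrix_dir + covariate_table")
    atlas = (
        RegionAtlas.from_tsv(config.atlas_table)
        if config.atlas_table
        else RegionAtlas.default()
    )
    return snio.read_cohort(config.matrix_dir, config.covariate_table, atlas)


# ---------------------------------------------------------------------------
# stages (each writes TSVs under out_dir and returns its products)


def stage_metrics(cohort: CohortDataset, out_dir: Path) -> list[NodalMetrics]:
    per_subject = cohort_nodal_metrics(cohort)
    ids = [s.subject_id for s in cohort.subjects]
    abbrs = cohort.atlas.abbreviations
    for name in NodalMetrics.METRIC_NAMES:
        pd.DataFrame(
            np.stack([getattr(nm, name) for nm in per_subject]),
            index=pd.Index(ids, name="subject_id"),
            columns=abbrs,
        ).to_csv(out_dir / f"nodal_{name}.tsv", sep="\t", float_format=FLOAT_FMT)
    return per_subject


def stage_nulls(cohort: CohortDataset, config: RunConfig, out_dir: Path) -> pd.DataFrame:
    table = global_metric_table(
        cohort,
        n_random=config.n_random,
        seed=stage_seed(config.master_seed, "nulls"),
        swaps_per_edge=config.swaps_per_edge,
    )
    table.to_csv(out_dir / "global_metrics.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    return table


def stage_hubs(
    cohort: CohortDataset, per_subject: list[NodalMetrics], out_dir: Path
) -> dict:
    tables = {}
    for label in ("NC", "patient"):
        members = [nm for s, nm in zip(cohort.subjects, per_subject) if s.group == label]
        tables[label] = hub_scores(group_mean_nodal_metrics(members), cohort.atlas)
        tables[label].to_csv(out_dir / f"hubs_{label}.tsv", sep="\t", index=False)
    comp = compare_hub_sets(tables["patient"], tables["NC"])
    side_by_side = tables["patient"][["abbreviation", "hub_score", "is_hub"]].rename(
        columns={"hub_score": "hub_score_patient", "is_hub": "is_hub_patient"}
    )
    side_by_side["hub_score_NC"] = tables["NC"]["hub_score"]
    side_by_side["is_hub_NC"] = tables["NC"]["is_hub"]
    side_by_side.to_csv(out_dir / "hubs_comparison.tsv", sep="\t", index=False)
    return {"tables": tables, "comparison": comp}


def stage_compare(
    cohort: CohortDataset,
    per_subject: list[NodalMetrics],
    global_table: pd.DataFrame,
    config: RunConfig,
    out_dir: Path,
):
    glob = compare_groups_global(
        global_table,
        n_perm=config.n_perm,
        seed=stage_seed(config.master_seed, "compare_global"),
        alpha=config.alpha_global,
    )
    _write_with_provenance(
        glob, out_dir / "compare_global.tsv", config,
        extra={"level": "global", "alpha": config.alpha_global},
    )
    nodal = compare_groups_nodal(
        cohort,
        per_subject=per_subject,
        n_perm=config.n_perm,
        seed=stage_seed(config.master_seed, "compare_nodal"),
        q=config.q,
    )
    for metric, res in nodal.items():
        _write_with_provenance(
            res.table, out_dir / f"compare_nodal_{metric}.tsv", config,
            extra={"level": "nodal", "metric": metric, "q": config.q,
                   "fdr_critical_p": res.fdr_critical_p},
        )
    return glob, nodal


def stage_correlate(
    cohort: CohortDataset,
    per_subject: list[NodalMetrics],
    global_table: pd.DataFrame,
    config: RunConfig,
    out_dir: Path,
) -> dict[str, pd.DataFrame]:
    out = {}
    for score in ("mmse", "nihss"):
        for level in ("global", "nodal"):
            try:
                table = correlate_clinical(
                    cohort,
                    score,
                    level=level,
                    alpha=config.alpha_corr,
                    per_subject=per_subject,
                    global_table=global_table.drop(columns=["group"], errors="ignore")
                    if level == "global"
                    else None,
                )
            except ValueError as e:
                log.warning("correlation %s/%s skipped: %s", score, level, e)
                continue
            _write_with_provenance(
                table, out_dir / f"correlate_{score}_{level}.tsv", config,
                extra={"score": score, "level": level, "alpha": config.alpha_corr},
            )
            out[f"{score}_{level}"] = table
    return out


def _write_with_provenance(df: pd.DataFrame, path: Path, config: RunConfig, extra=None):
    header = {
        "master_seed": config.master_seed,
        "n_perm": config.n_perm,
        "n_random": config.n_random,
        **(extra or {}),
    }
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the full report bundle under out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = load_or_simulate(config)
    if config.simulate is not None:
        snio.write_cohort(cohort, out_dir / "cohort")
    log.info("stage metrics: %d subjects, %d regions", len(cohort.subjects), cohort.atlas.n)
    per_subject = stage_metrics(cohort, out_dir)
    log.info("stage nulls: n_random=%d", config.n_random)
    global_table = stage_nulls(cohort, config, out_dir)
    log.info("stage hubs")
    hubs = stage_hubs(cohort, per_subject, out_dir)
    log.info("stage compare: n_perm=%d", config.n_perm)
    glob, nodal = stage_compare(cohort, per_subject, global_table, config, out_dir)
    log.info("stage correlate")
    corr = stage_correlate(cohort, per_subject, global_table, config, out_dir)
    manifest = {
        "master_seed": config.master_seed,
        "stage_seeds": {
            s: stage_seed(config.master_seed, s)
            for s in ("nulls", "compare_global", "compare_nodal")
        },
        "n_random": config.n_random,
        "swaps_per_edge": config.swaps_per_edge,
        "n_perm": config.n_perm,
        "q": config.q,
        "alpha_global": config.alpha_global,
        "alpha_corr": config.alpha_corr,
        "n_subjects": len(cohort.subjects),
        "n_nodes": cohort.atlas.n,
        "simulated": config.simulate is not None,
    }
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return {
        "cohort": cohort,
        "per_subject": per_subject,
        "global_table": global_table,
        "hubs": hubs,
        "compare_global": glob,
        "compare_nodal": nodal,
        "correlations": corr,
    }
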