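"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-group structural-connectome study:

* a weighted small-world template — a Watts-Strogatz ring lattice (n nodes,
  each linked to ``ring_neighbors`` nearest neighbors, edges rewired with
  probability ``rewire_prob``) with positive edge weights drawn from a
  lognormal or uniform law;
* a patient template derived from it by a localized "lesion": every edge
  incident to a chosen node set is attenuated by a fixed factor, mimicking
  infarct-related connectivity loss;
* per-subject variability as multiplicative lognormal noise on each edge
  (mean 1, coefficient of variation ``subject_noise_cv``), applied to the
  upper triangle and mirrored so matrices stay symmetric and nonnegative;
* covariates: age and gender per group, MMSE in group-appropriate ranges,
  and an NIHSS score linked to one node's metric — computed on each
  patient's own (lesioned, noisy) matrix so the planted correlation
  survives the full pipeline — via
  ``NIHSS = round(baseline + coefficient * z(metric) + noise)``, clipped
  at 0.

Default group sizes are 44 controls / 47 patients over 90 nodes, the shape
of the study design this package targets. Everything is a pure function of
the spec (including ``master_seed``): the same spec reproduces the same
cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import metrics
from .core import CohortDataset, ConnectivityMatrix, RegionAtlas, SubjectRecord
from .mapping import Streamline, StreamlineSet


@dataclass
class NihssLink:
    """Planted link between NIHSS and one node's metric (patients only)."""

    target_node: int = 75  # PAL.R in the bundled 90-region atlas
    target_metric: str = "betweenness"
    coefficient: float = 0.6
    noise_sd: float = 0.65
    baseline: float = 5.0


@dataclass
class SyntheticCohortSpec:
    """All knobs of the cohort generator, with study-shaped defaults."""

    n_nc: int = 44
    n_patient: int = 47
    n_nodes: int = 90
    ring_neighbors: int = 6
    rewire_prob: float = 0.1
    #: ("lognormal", mu, sigma) or ("uniform", lo, hi) for edge weights
    weight_law: tuple = ("lognormal", 0.0, 0.5)
    subject_noise_cv: float = 0.15
    #: SOG, MOG, IPG bilaterally in the bundled atlas — a parietal-occipital lesion
    lesion_nodes: tuple = (48, 49, 50, 51, 60, 61)
    lesion_attenuation: float = 0.7
    age_mean: float = 68.0
    age_sd: float = 8.0
    male_fraction: float = 0.6
    mmse_range_nc: tuple = (26, 30)
    mmse_range_patient: tuple = (18, 30)
    nihss_link: NihssLink = field(default_factory=NihssLink)
    master_seed: int = 0

    def validate(self) -> None:
        if self.n_nc < 2 or self.n_patient < 2:
            raise ValueError("need >= 2 subjects per group")
        if self.ring_neighbors >= self.n_nodes:
            raise ValueError("ring_neighbors must be < n_nodes")
        if not 0 <= self.rewire_prob <= 1:
            raise ValueError("rewire_prob must be in [0, 1]")
        if not 0 < self.lesion_attenuation <= 1:
            raise ValueError("lesion_attenuation must be in (0, 1]")
        if self.subject_noise_cv < 0:
            raise ValueError("subject_noise_cv must be >= 0")
        if any(not 0 <= v < self.n_nodes for v in self.lesion_nodes):
            raise ValueError("lesion node index out of range")
        if not 0 <= self.nihss_link.target_node < self.n_nodes:
            raise ValueError("NIHSS target node out of range")


@dataclass
class GroundTruth:
    """Everything needed to recompute the cohort deterministically."""

    template_nc: ConnectivityMatrix
    template_patient: ConnectivityMatrix
    lesion_nodes: tuple
    lesion_attenuation: float
    nihss_link: NihssLink
    subject_seeds: dict[str, int]
    spec: SyntheticCohortSpec


def _atlas_for(n_nodes: int) -> RegionAtlas:
    if n_nodes == 90:
        return RegionAtlas.default()
    half = n_nodes // 2
    return RegionAtlas(
        pd.DataFrame(
            {
                "region_id": np.arange(1, n_nodes + 1),
                "name": [f"Synthetic region {i + 1}" for i in range(n_nodes)],
                "abbreviation": [f"R{i + 1:03d}" for i in range(n_nodes)],
                "hemisphere": ["L" if i < half else "R" for i in range(n_nodes)],
                "volume_mm3": np.full(n_nodes, 10000.0),
            }
        )
    )


def _draw_weights(law: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind, a, b = law
    if kind == "lognormal":
        return rng.lognormal(a, b, size=size)
    if kind == "uniform":
        return rng.uniform(a, b, size=size)
    raise ValueError(f"unknown weight law {kind!r}")


def generate_template(
    spec: SyntheticCohortSpec, rng: np.random.Generator, atlas: RegionAtlas | None = None
) -> ConnectivityMatrix:
    """Weighted Watts-Strogatz template network."""
    spec.validate()
    if atlas is None:
        atlas = _atlas_for(spec.n_nodes)
    g = nx.watts_strogatz_graph(
        spec.n_nodes,
        spec.ring_neighbors,
        spec.rewire_prob,
        seed=int(rng.integers(2**31)),
    )
    w = np.zeros((spec.n_nodes, spec.n_nodes))
    edges = np.array(g.edges())
    vals = _draw_weights(spec.weight_law, len(edges), rng)
    w[edges[:, 0], edges[:, 1]] = vals
    w = w + w.T
    return ConnectivityMatrix(w, atlas)


def apply_lesion(
    m: ConnectivityMatrix, nodes, attenuation: float
) -> ConnectivityMatrix:
    """Attenuate every edge incident to the listed nodes by a fixed factor."""
    if not 0 < attenuation <= 1:
        raise ValueError("attenuation must be in (0, 1]")
    nodes = list(nodes)
    for v in nodes:
        if not 0 <= v < m.n:
            raise ValueError(f"unknown node {v}")
    w = m.weights.copy()
    mask = np.zeros(m.n, dtype=bool)
    mask[nodes] = True
    # an edge touching two lesion nodes is attenuated once, not twice
    touched = mask[:, None] | mask[None, :]
    w[touched] *= attenuation
    return ConnectivityMatrix(w, m.atlas)


def _noisy_copy(
    template: ConnectivityMatrix, cv: float, rng: np.random.Generator
) -> ConnectivityMatrix:
    if cv == 0:
        return template.copy()
    sigma = np.sqrt(np.log1p(cv**2))
    mu = -(sigma**2) / 2.0  # mean-1 multiplicative noise
    n = template.n
    noise = np.ones((n, n))
    iu = np.triu_indices(n, k=1)
    noise[iu] = rng.lognormal(mu, sigma, size=len(iu[0]))
    noise = np.triu(noise, k=1)
    noise = noise + noise.T
    return ConnectivityMatrix(template.weights * noise, template.atlas)


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[CohortDataset, GroundTruth]:
    """Generate the full two-group cohort with covariates and ground truth."""
    spec.validate()
    atlas = _atlas_for(spec.n_nodes)
    seq = np.random.SeedSequence(spec.master_seed)
    template_seq, cov_seq, subject_seq = seq.spawn(3)
    template_rng = np.random.default_rng(template_seq)
    template_nc = generate_template(spec, template_rng, atlas)
    template_patient = apply_lesion(
        template_nc, spec.lesion_nodes, spec.lesion_attenuation
    )

    n_total = spec.n_nc + spec.n_patient
    subject_children = subject_seq.spawn(n_total)
    subject_seeds: dict[str, int] = {}
    cov_rng = np.random.default_rng(cov_seq)

    subjects: list[SubjectRecord] = []
    patient_matrices: list[ConnectivityMatrix] = []
    meta: list[dict] = []
    for k in range(n_total):
        is_patient = k >= spec.n_nc
        sid = f"{'pat' if is_patient else 'nc'}{(k - spec.n_nc if is_patient else k) + 1:03d}"
        child = subject_children[k]
        subject_seeds[sid] = int(child.generate_state(1)[0])
        srng = np.random.default_rng(child)
        template = template_patient if is_patient else template_nc
        matrix = _noisy_copy(template, spec.subject_noise_cv, srng)
        lo, hi = spec.mmse_range_patient if is_patient else spec.mmse_range_nc
        meta.append(
            {
                "subject_id": sid,
                "group": "patient" if is_patient else "NC",
                "age": float(cov_rng.normal(spec.age_mean, spec.age_sd)),
                "gender": "M" if cov_rng.random() < spec.male_fraction else "F",
                "mmse": int(cov_rng.integers(lo, hi + 1)),
                "matrix": matrix,
            }
        )
        if is_patient:
            patient_matrices.append(matrix)

    # NIHSS: linked to the target nodal metric on each patient's own matrix
    link = spec.nihss_link
    metric_fn = getattr(metrics, link.target_metric)
    vals = np.array([metric_fn(m)[link.target_node] for m in patient_matrices])
    sd = vals.std()
    z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
    nihss_rng = np.random.default_rng(cov_seq.spawn(1)[0])
    latent = link.baseline + link.coefficient * z + nihss_rng.normal(
        0.0, link.noise_sd, size=len(z)
    )
    nihss_vals = np.maximum(0, np.rint(latent)).astype(int)

    ipat = 0
    for row in meta:
        if row["group"] == "patient":
            nihss = int(nihss_vals[ipat])
            ipat += 1
        else:
            nihss = None
        subjects.append(
            SubjectRecord(
                subject_id=row["subject_id"],
                group=row["group"],
                age=row["age"],
                gender=row["gender"],
                mmse=row["mmse"],
                nihss=nihss,
                matrix=row["matrix"],
            )
        )
    truth = GroundTruth(
        template_nc=template_nc,
        template_patient=template_patient,
        lesion_nodes=tuple(spec.lesion_nodes),
        lesion_attenuation=spec.lesion_attenuation,
        nihss_link=link,
        subject_seeds=subject_seeds,
        spec=spec,
    )
    return CohortDataset(subjects=subjects, atlas=atlas), truth


def generate_streamlines(
    target: ConnectivityMatrix, atlas: RegionAtlas, rng: np.random.Generator
) -> StreamlineSet:
    """Emit a streamline set whose fiber-density matrix equals ``target``.

    For each connected pair the bundle's fiber count is drawn in 1..3 and
    the inverse lengths are split randomly so that the bundle's density
    reproduces the target entry (to floating-point accuracy). Geometry is
    straight segments at arbitrary positions: only endpoint labels and
    trajectory lengths matter to the density.
    """
    volumes = atlas.volumes
    ids = atlas.region_ids
    streamlines: list[Streamline] = []
    n = target.n
    for i in range(n):
        for j in range(i + 1, n):
            w = target.weights[i, j]
            if w == 0:
                continue
            total_inv = w * (volumes[i] + volumes[j]) / 2.0  # sum of 1/l_f
            m = int(rng.integers(1, 4))
            shares = rng.dirichlet(np.ones(m)) if m > 1 else np.array([1.0])
            for share in shares:
                length = 1.0 / (share * total_inv)
                origin = rng.uniform(0.0, 100.0, size=3)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                streamlines.append(
                    Streamline(
                        points=np.stack([origin, origin + direction * length]),
                        endpoint_regions=(int(ids[i]), int(ids[j])),
                    )
                )
    return StreamlineSet(streamlines=streamlines, atlas=atlas)
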