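# strokenet

Weighted structural brain connectome analysis for two-group (patient vs
control) studies: fiber-density connectivity mapping, weighted small-world
graph metrics, degree-preserving null models, rank-based hub
identification, and permutation group statistics with clinical-score
correlation.

The package targets the classic DTI-connectome study design: each subject
is a 90-region (AAL) weighted undirected network; patients differ from
controls through localized connectivity loss; clinical scores (MMSE,
NIHSS) may track individual network metrics. Since such studies rarely
deposit patient matrices, a first-class synthetic-cohort generator
reproduces the statistical structure the analysis assumes, making every
stage testable end to end.

## The model

**Edge weights.** Two regions *i*, *j* are connected when at least one
tractography streamline runs between them. The weight is the fiber
connection density

```
w_ij = (2 / (V_i + V_j)) * Σ_{f ∈ F_e} 1 / l_f
```

where `F_e` is the set of fibers whose endpoints fall in *i* and *j*,
`l_f` is fiber length along its trajectory (mm), and `V_i`, `V_j` are
region volumes (mm³) — fibers per unit volume, penalized by length.

**Nodal metrics** (per subject): strength `S_i = Σ_j w_ij`; Onnela
weighted clustering `C_i` (cube-root triangle intensity, weights rescaled
by the network max; 0 when degree < 2); betweenness `B_i` (sum over pairs
of the fraction of shortest weighted paths through *i*, length = 1/w,
unnormalized); regional efficiency `E_i = (1/(n−1)) Σ_j 1/d_ij`;
vulnerability `Vul_i = E_glob − E_glob(G∖i)`.

**Global metrics:** means of `S`, `C`, `B`; characteristic path length
`L = 1/E_glob`; global vulnerability `max_i Vul_i`; and the small-world
quantities `γ = C/⟨C_rand⟩`, `λ = L/⟨L_rand⟩`, `σ = γ/λ` against 100
degree-preserving rewired surrogates. σ > 1 indicates small-world
organization.

**Hubs:** a node scores one point per criterion — top 20% by group-mean
strength, bottom 20% by clustering, top 20% by betweenness, regional
efficiency, and vulnerability; a score ≥ 2 makes it a hub.

**Statistics:** group differences by label-reshuffling permutation tests
(5,000 resamples, one-tailed exceedance p, the identity labeling always
included so p ≥ 1/n_perm); nodal tests corrected by Benjamini–Hochberg
FDR at q = 0.05; clinical scores related to metrics by Pearson partial
correlation controlling for age and gender, flagged at p < 0.001.

## Worked example

```python
import numpy as np
import strokenet as sn

spec = sn.SyntheticCohortSpec(master_seed=0)       # 44 NC / 47 patients, 90 nodes
m = sn.generate_template(spec, np.random.default_rng(0))

sw = sn.small_worldness(m, n_random=100, rng_seed=42)
print(f"gamma={sw.gamma:.3f} lambda={sw.lam:.3f} sigma={sw.sigma:.3f}")
```

prints

```
gamma=10.217 lambda=1.264 sigma=8.083
```

— clustering ten times the matched-random level at a near-random path
length: a strongly small-world network. The `examples/` directory has one
short script per capability (fiber-density mapping, metrics, null models,
hubs, group comparison, clinical correlation, full pipeline); for
instance `examples/06_clinical_correlation.py` recovers a planted
NIHSS–betweenness link at the right pallidum with `r = 0.643, p = 2e-06`
across 47 synthetic patients.

A thin CLI wraps the pipeline for shell use:

```bash
strokenet run --config config.yaml --seed 7 --out report/
```

with stage subcommands (`simulate`, `metrics`, `nulls`, `hubs`,
`compare`, `correlate`) that write the same TSV contracts and compose to
identical results.

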