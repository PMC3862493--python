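"""Permutation group comparison with FDR-corrected nodal tests.

Patients carry a 6-node parietal-occipital 'lesion' (30% edge
attenuation). Group labels are reshuffled 2,000 times; nodal p values are
corrected with Benjamini-Hochberg FDR at q = 0.05.
"""

import strokenet as sn

spec = sn.SyntheticCohortSpec(n_nc=20, n_patient=20, master_seed=2)
cohort, truth = sn.generate_cohort(spec)

res = sn.compare_groups_nodal(
    cohort, metric_names=["strength"], n_perm=2000, seed=0, q=0.05
)["strength"]

sig = res.table[res.table["fdr_significant"]]
lesioned = {cohort.atlas.abbreviations[i] for i in truth.lesion_nodes}
print(f"FDR-significant strength differences ({len(sig)} regions, "
      f"critical p = {res.fdr_critical_p:.4g}):")
print(sig[["abbreviation", "observed_diff", "p_one_tailed"]].to_string(index=False))
print(f"planted lesion regions: {sorted(lesioned)}")
# Negative observed_diff = patient mean below control mean. The detected set
# recovers the attenuated regions; ring neighbors share attenuated edges, so
# their strength drops too and they may be flagged as well — real signal,
# not false positives.
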