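"""Weighted nodal and global graph metrics on one connectome.

Strength, Onnela clustering, betweenness on shortest weighted paths
(length = 1/weight), regional/global efficiency, and node vulnerability
(efficiency drop after node removal).
"""

import numpy as np

import strokenet as sn

spec = sn.SyntheticCohortSpec(master_seed=0)
m = sn.generate_template(spec, np.random.default_rng(0))

nm = sn.nodal_metrics(m)
gm = sn.global_summary(nm, m)

top = np.argsort(-nm.strength)[:3]
abbrs = m.atlas.abbreviations
print("three strongest regions:",
      ", ".join(f"{abbrs[i]} (S={nm.strength[i]:.2f})" for i in top))
print(f"global efficiency      : {gm.global_efficiency:.4f}")
print(f"characteristic path len: {gm.char_path_length:.4f}  (= 1/E_glob)")
print(f"mean clustering        : {gm.global_clustering:.4f}")
print(f"max vulnerability      : {gm.global_vulnerability:.4f} "
      f"at {abbrs[int(np.argmax(nm.vulnerability))]}")
# Vulnerability is the network's efficiency loss if that single region (and
# its connections) were removed — the most indispensable node has the max.
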