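"""Build a weighted connectivity matrix from labeled streamlines.

Each edge weight is the fiber connection density: fibers between two
regions, each penalized by its trajectory length, normalized by the
regions' combined volume. Two regions are connected when at least one
fiber runs between them.
"""

import numpy as np

import strokenet as sn

atlas = sn.RegionAtlas.default()  # the 90-region AAL parcellation

# three fibers between PreCG.L (2001) and PreCG.R (2002), one to SFGdor.L (2101)
fibers = [
    sn.Streamline(points=[(0, 0, 0), (60, 0, 0)], endpoint_regions=(2001, 2002)),
    sn.Streamline(points=[(0, 5, 0), (30, 5, 0), (62, 3, 0)], endpoint_regions=(2001, 2002)),
    sn.Streamline(points=[(0, 0, 0), (40, 30, 10)], endpoint_regions=(2001, 2101)),
]
ss = sn.StreamlineSet(fibers, atlas)
m = sn.build_matrix(ss, atlas)

i, j = atlas.index_of("PreCG.L"), atlas.index_of("PreCG.R")
k = atlas.index_of("SFGdor.L")
print(f"density PreCG.L - PreCG.R : {m.weights[i, j]:.3e}  (two fibers, 1/(mm^3*mm))")
print(f"density PreCG.L - SFGdor.L: {m.weights[i, k]:.3e}  (one longer fiber)")
print(f"validation violations: {sn.validate_matrix(m)}")
# The two-fiber bundle carries more density; weights scale with fiber count,
# shrink with fiber length and with the regions' combined volume.
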