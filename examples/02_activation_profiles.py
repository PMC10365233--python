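"""Weighted pathway activation as a function of stimulation amplitude.

Generates one synthetic hemisphere (hyperdirect pathway converging on the
dorsolateral STN, corticospinal tract descending posterolateral to it),
places a directional lead, and prints the activation fraction of both
pathways over the monopolar-review amplitude grid for a few
configurations.  The activation fraction is the sum of the weights of the
streamlines intersected by the VTA divided by the bundle's total weight.
"""

import numpy as np

from tractstim import SyntheticParams, activation_profile
from tractstim.synthetic_cohort import (make_cst_bundle, make_hdp_bundle,
                                        place_lead, stn_for_hemisphere)

params = SyntheticParams(seed=1, n_streamlines_hdp=200, n_streamlines_cst=600)
rng = np.random.default_rng(1)
stn = stn_for_hemisphere(params, "right")
hdp = make_hdp_bundle(params, "S01", "right", rng)
cst = make_cst_bundle(params, "S01", "right", rng)
lead = place_lead(params, stn, rng)

grid = [0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0]
print("activation fraction by amplitude (mA)")
print("config  pathway " + "".join(f"{a:>7.1f}" for a in grid))
for cfg in ("L1", "L2", "L3", "L4", "C2", "C5"):
    for name, bundle in (("HDP", hdp), ("CST", cst)):
        prof = activation_profile(bundle, lead, cfg, grid, params.vta_params)
        row = "".join(f"{prof[a]:7.3f}" for a in grid)
        print(f"{cfg:6s}  {name:6s}{row}")

print(
    "\nProfiles are non-decreasing in amplitude (VTAs are nested), the HDP\n"
    "activates earliest at the levels nearest the dorsolateral border, and\n"
    "the CST stays near zero until the volume reaches the capsule tube —\n"
    "the geometry behind effect vs side-effect thresholds."
)
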