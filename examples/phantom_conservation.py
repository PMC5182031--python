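"""Conservation of FDC across a warped fibre bundle's cross-section.

Builds the straight 2-D fibre-bundle phantom (FD = 1 everywhere, oriented
along x), applies three pull-back warps -- a pure length scaling, a shear
and a smoothed piecewise-cosine displacement -- and integrates FD and FDC
across the bundle's width at every position along its length.

The printout shows that the summed FDC stays at the untransformed bundle's
summed FD (the bundle's total intra-axonal cross-sectional content) under
every warp, while the summed FD alone is distorted whenever the warp
changes the cross-section: FD is a within-voxel density and needs the FC
modulation to be comparable across differently-sized bundles.
"""

import numpy as np

from fixel.phantom import (TSCALE, TSHEAR, PhantomSpec, cosine_warp,
                           cross_section_sums, linear_warp, make_phantom,
                           transform_phantom)

spec = PhantomSpec()
phantom = make_phantom(spec)
baseline = cross_section_sums(phantom, spec)
ref = baseline.sum_fd.mean()
print(f"phantom: {phantom.n_fixels} fixels, bundle width {spec.width_vox:g} "
      f"voxels\nuntransformed sum of FD across width: {ref:.3f}\n")

warps = {"scale": linear_warp(TSCALE, spec),
         "shear": linear_warp(TSHEAR, spec),
         "cosine": cosine_warp(spec)}
print(f"{'warp':>8} {'FC range':>18} {'max |dev| sum FD':>17} "
      f"{'max |dev| sum FDC':>18}")
for name, warp in warps.items():
    warped = transform_phantom(phantom, warp)
    prof = cross_section_sums(warped, spec)
    v = prof.valid
    dev_fd = np.abs(prof.sum_fd[v] - ref).max() / ref
    dev_fdc = np.abs(prof.sum_fdc[v] - ref).max() / ref
    fc = warped.values["fc"]
    print(f"{name:>8} [{fc.min():6.4f}, {fc.max():6.4f}] "
          f"{dev_fd:16.1%} {dev_fdc:17.1%}")

print("\nsum FDC is conserved (< 2%) under all three warps; sum FD alone "
      "is conserved\nonly under the pure length scaling, which leaves the "
      "cross-section untouched.")
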