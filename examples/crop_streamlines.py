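"""Cropping a tractogram to its significant segments.

For visualising fixel statistics, streamlines of a template tractogram are
assigned point-by-point to the fixel whose direction best matches the
local streamline tangent, and then cropped so only runs of points lying on
significant fixels survive.  Here a synthetic tractogram of straight lines
runs along the phantom bundle, and significance is faked on the middle
half of the bundle's length to show the cropping behaviour.
"""

import numpy as np

from fixel.phantom import PhantomSpec, make_phantom
from fixel.tracks import (Tractogram, assign_streamline_points,
                          crop_tractogram)

spec = PhantomSpec()
bundle = make_phantom(spec)

lines = []
for y in (-2.5, 0.5, 2.5):
    pts = np.zeros((40, 3))
    pts[:, 0] = np.linspace(-22.0, 22.0, 40)
    pts[:, 1] = y
    lines.append(pts)
tracks = Tractogram(lines)

assignment = assign_streamline_points(tracks, bundle, max_angle=30.0)

# pretend only fixels in the middle half of the bundle length are significant
voxels = bundle.fixel_voxels()
mask = np.abs(voxels[:, 0] - spec.length_vox / 2) < spec.length_vox / 4

cropped = crop_tractogram(tracks, assignment, mask)
n_in = sum(len(s) for s in tracks.streamlines)
n_out = sum(len(s) for s in cropped.streamlines)
print(f"input : {tracks.count} streamlines, {n_in} points")
print(f"cropped: {cropped.count} streamlines, {n_out} points")
for s in cropped.streamlines:
    print(f"  kept run x in [{s[:, 0].min():+.1f}, {s[:, 0].max():+.1f}] mm "
          f"at y = {s[0, 1]:+.1f}")
print("only the segments overlying in-mask fixels survive; runs shorter "
      "than two points\nare dropped because they cannot be rendered as a "
      "segment.")
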