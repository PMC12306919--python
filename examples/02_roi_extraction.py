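"""Build the shipped 16-sphere stress ROI set on a 2-mm MNI-like grid and
extract an ROI time series from a synthetic 4D volume.

A 6-mm-diameter sphere (radius 3 mm) centered on a voxel center of a
2-mm isotropic grid contains exactly 19 voxels: the center, the 6 face
neighbors at 2.0 mm, and the 12 edge neighbors at 2.83 mm.
"""

import numpy as np

from iscpipe import GridSpec, build_sphere_mask, default_roi_table, extract_timeseries

grid = GridSpec.isotropic((91, 109, 91), 2.0, origin_mm=(-90, -126, -72))

rois = default_roi_table()
print(f"{len(rois)} stress-processing ROIs; first three:")
for roi in rois[:3]:
    mask = build_sphere_mask(roi.mni_xyz, roi.radius, grid, label=roi.key)
    print(f"  {roi.key:42s} diameter {roi.diameter} mm -> {len(mask)} voxels")

# a toy 4D volume whose every voxel carries the same ramp
T = 5
vol = np.broadcast_to(np.arange(T, dtype=float), (*grid.dims, T)).copy()
mask = build_sphere_mask(rois[0].mni_xyz, rois[0].radius, grid)
series = extract_timeseries(vol, mask)
print(f"\nROI mean series of a spatially constant ramp: {series}")
print("(the unweighted mean over mask voxels reproduces the ramp exactly)")
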