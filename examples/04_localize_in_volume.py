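"""Detect and classify the device markers in a synthetic CT-like volume.

Renders bright 4 mm spheres at the device's marker positions into a
0.5 mm-voxel volume, localizes them by connected-component analysis with
intensity-weighted centroids, and recovers which sphere is which: the
three collinear column markers versus the four wheel fiducials (identified
by their arm radius).
"""

import numpy as np

from fidkit import (
    DeviceGeometry,
    PhantomSpec,
    classify_markers,
    localize_markers,
    make_phantom_points,
    make_volume,
)

# compact device so the rendered volume stays small
geometry = DeviceGeometry(
    arm_radii_mm=(20.0, 26.0, 32.0, 38.0),
    collector_offsets_mm=(0.0, 6.0, 12.0),
)
spec = PhantomSpec(
    geometry=geometry,
    wheel_axial_offsets_mm=(-6.0, -12.0, -18.0, -24.0),
    targets_mm=np.array([[15.0, -10.0, -25.0]]),
    target_labels=("screw",),
    volume_size=(192, 192, 128),
    spacing_mm=(0.5, 0.5, 0.5),
)

truth, _ = make_phantom_points(spec)
volume = make_volume(spec, include_targets=False)
print(f"volume: {volume.shape} voxels at {volume.spacing} mm")

detected = localize_markers(volume, expected_diameter=spec.sphere_diameter_mm)
print(f"detected {len(detected)} spherical markers")

classified = classify_markers(
    np.vstack([m.position for m in detected]), geometry
)
print(f"collector column residual: {classified.collinearity_residual_mm:.4f} mm")
for wheel in geometry.wheel_ids:
    err = np.linalg.norm(classified.wheels[wheel] - truth.wheels[wheel])
    print(f"{wheel:>6} wheel marker localized within {err:.3f} mm of ground truth")

# Sub-voxel accuracy comes from the intensity-weighted centroid: the
# partial-volume shading at the sphere boundary encodes the centre position
# at a fraction of the 0.5 mm voxel size.
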