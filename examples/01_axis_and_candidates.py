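"""Fit the wheel rotation axis and generate each wheel's candidate stops.

Builds the noiseless ground-truth marker set of the default device, fits
the rotation axis through the three collinear column markers, and rotates
each wheel fiducial through its ten discrete stops (36 degrees apart).
"""

import numpy as np

from fidkit import (
    DeviceGeometry,
    PhantomSpec,
    enumerate_configurations,
    fit_axis,
    generate_candidates,
    make_phantom_points,
)

geometry = DeviceGeometry.default()
print(f"device: {len(geometry.wheel_ids)} wheels x "
      f"{geometry.positions_per_wheel} stops of {geometry.angular_step_deg} deg")
print(f"configuration space: {len(enumerate_configurations(geometry))} settings")

spec = PhantomSpec(geometry=geometry)
obs, homes = make_phantom_points(spec)
axis = fit_axis(obs.collectors)
print(f"fitted axis direction: {np.round(axis.direction, 6)}, "
      f"pivot {np.round(axis.pivot, 3)} mm, residual {axis.fit_residual:.2e} mm")

for wheel in geometry.wheel_ids:
    cs = generate_candidates(homes[wheel], axis, geometry, wheel_id=wheel)
    radius = axis.distance_to(cs.home)
    print(f"{wheel:>6}: {cs.n_positions} candidates on a circle of radius "
          f"{radius:.1f} mm (arm length)")

# The candidate circle is where the tracking sensor can physically be
# placed; the radius equals the wheel's arm length, so each wheel sweeps a
# different ring around the head.
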