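"""Synthetic phantom: device-consistent point sets, volumes and tracking data.

Everything the toolkit consumes can be generated here with known ground
truth: the seven spherical markers of the device (three collinear column
markers plus four wheel fiducials in home position), screw-head targets, a
CT-like volume containing bright antialiased spheres, and noisy
tracker-space measurement sessions.

The noise model is deliberately the one under which the error estimators
are exact: isotropic zero-mean Gaussian fiducial localization error,
independent across fiducials and repeats. Every random draw is determined
by a seed.

The device's arm radii, column-marker offsets, wheel stack heights and home
azimuths are synthetic choices (the mechanical drawings are not public);
they are sized for an adult head and kept pairwise distinct so that wheel
identity is recoverable from geometry alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .axis import LineAxis, fit_axis, generate_candidates, rotate_about_axis
from .errors import FidkitError
from .geometry import DeviceGeometry, WheelConfiguration
from .localize import MarkerObservationSet
from .registration import (
    RegistrationErrorReport,
    RigidTransform,
    _register_batch,
    estimate_fle,
    predict_tre,
)
from .volume import VolumeGrid

#: per-axis sigma for a given total (3D RMS) fiducial localization error
_SIGMA_PER_AXIS = 1.0 / np.sqrt(3.0)


@dataclass
class PhantomSpec:
    """Full description of a synthetic scene.

    Geometric defaults emulate a CT head scan of the device: the printed
    scan spacing (0.488 x 0.488 x 0.6 mm), 4 mm marker spheres, 2 mm
    screw-head targets, and an electromagnetic-tracker-like fiducial
    localization noise of 0.4 mm RMS.
    """

    geometry: DeviceGeometry = field(default_factory=DeviceGeometry)
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    axis_pivot: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: axial offset of each wheel fiducial along the axis (mm); the wheels
    #: are stacked below the collector column
    wheel_axial_offsets_mm: tuple[float, ...] = (-10.0, -18.0, -26.0, -34.0)
    #: home-position azimuth of each wheel arm (deg, right-handed about the
    #: axis); chosen with no two arms opposite each other
    wheel_home_azimuth_deg: tuple[float, ...] = (20.0, 110.0, 225.0, 315.0)
    targets_mm: np.ndarray = field(
        default_factory=lambda: np.array([[30.0, -20.0, -50.0], [-40.0, 25.0, -45.0]])
    )
    target_labels: tuple[str, ...] = ()
    volume_size: tuple[int, int, int] = (480, 480, 224)  # (nx, ny, nz) voxels
    spacing_mm: tuple[float, float, float] = (0.488, 0.488, 0.6)
    origin_mm: tuple[float, float, float] | None = None  # None: centred on pivot
    sphere_diameter_mm: float = 4.0
    target_diameter_mm: float = 2.0
    background_intensity: float = 0.0
    marker_intensity: float = 1000.0
    intensity_noise_sigma: float = 0.0
    tracker_fle_rms_mm: float = 0.4
    probe_noise_rms_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.targets_mm = np.asarray(self.targets_mm, dtype=float).reshape(-1, 3)
        n_w = self.geometry.n_wheels
        if len(self.wheel_axial_offsets_mm) != n_w:
            raise ValueError("one axial offset per wheel required")
        if len(self.wheel_home_azimuth_deg) != n_w:
            raise ValueError("one home azimuth per wheel required")
        if self.target_labels and len(self.target_labels) != self.targets_mm.shape[0]:
            raise ValueError("one label per target required")
        if not self.target_labels:
            self.target_labels = tuple(
                f"target_{i + 1}" for i in range(self.targets_mm.shape[0])
            )

    @property
    def axis(self) -> LineAxis:
        return LineAxis(
            direction=np.asarray(self.axis_direction, dtype=float),
            pivot=np.asarray(self.axis_pivot, dtype=float),
        )

    def volume_origin(self) -> np.ndarray:
        if self.origin_mm is not None:
            return np.asarray(self.origin_mm, dtype=float)
        size = np.asarray(self.volume_size, dtype=float)
        spacing = np.asarray(self.spacing_mm, dtype=float)
        return np.asarray(self.axis_pivot) - (size - 1) * spacing / 2.0


def _axis_frame(axis: LineAxis) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis (u, v) with u x v = direction
    rotated into v by a positive (right-handed) axis rotation."""
    d = axis.direction
    a = np.array([1.0, 0.0, 0.0])
    if abs(d @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = a - (a @ d) * d
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def make_phantom_points(
    spec: PhantomSpec,
) -> tuple[MarkerObservationSet, dict[str, np.ndarray]]:
    """Exact ground-truth marker/target positions for a phantom scene.

    Collector markers sit at the configured offsets along the axis; wheel
    fiducials at their arm radius, home azimuth and stack height. Returns
    the labelled observation set and the per-wheel home positions (equal to
    the wheel entries; returned separately as the input contract of
    :func:`fidkit.axis.generate_candidates`).
    """
    axis = spec.axis
    u, v = _axis_frame(axis)
    d, pivot = axis.direction, axis.pivot
    collectors = np.array(
        [pivot + off * d for off in spec.geometry.collector_offsets_mm]
    )
    homes: dict[str, np.ndarray] = {}
    for wid, radius, h, az in zip(
        spec.geometry.wheel_ids,
        spec.geometry.arm_radii_mm,
        spec.wheel_axial_offsets_mm,
        spec.wheel_home_azimuth_deg,
    ):
        phi = np.radians(az)
        homes[wid] = pivot + h * d + radius * (np.cos(phi) * u + np.sin(phi) * v)
    obs = MarkerObservationSet(
        collectors=collectors,
        wheels={k: p.copy() for k, p in homes.items()},
        targets=spec.targets_mm.copy(),
        collinearity_residual_mm=0.0,
    )
    return obs, homes


def configured_fiducials(
    spec: PhantomSpec, configuration: WheelConfiguration
) -> np.ndarray:
    """True fiducial positions (wheel order) for a given configuration."""
    configuration.validate(spec.geometry)
    _, homes = make_phantom_points(spec)
    axis = spec.axis
    out = []
    for wid in spec.geometry.wheel_ids:
        theta = configuration.angle_deg(spec.geometry, wid)
        out.append(
            homes[wid] if theta == 0 else rotate_about_axis(homes[wid], axis, theta)
        )
    return np.vstack(out)


def _paint_sphere(
    data: np.ndarray, spec: PhantomSpec, origin: np.ndarray, centre: np.ndarray,
    radius: float, intensity: float,
) -> None:
    """Rasterize one antialiased sphere into ``data`` (in place)."""
    spacing = np.asarray(spec.spacing_mm)
    size = np.asarray(spec.volume_size)  # (nx, ny, nz)
    centre_idx = (centre - origin) / spacing  # (x, y, z) order
    pad = radius / spacing + 1.5
    lo = np.floor(centre_idx - pad).astype(int)
    hi = np.ceil(centre_idx + pad).astype(int) + 1
    if np.any(lo < 0) or np.any(hi > size):
        raise FidkitError(
            f"sphere at {centre} (r = {radius} mm) extends outside the volume"
        )
    ix = np.arange(lo[0], hi[0])
    iy = np.arange(lo[1], hi[1])
    iz = np.arange(lo[2], hi[2])
    px = origin[0] + ix * spacing[0]
    py = origin[1] + iy * spacing[1]
    pz = origin[2] + iz * spacing[2]
    dist = np.sqrt(
        (px[None, None, :] - centre[0]) ** 2
        + (py[None, :, None] - centre[1]) ** 2
        + (pz[:, None, None] - centre[2]) ** 2
    )  # (z, y, x) block
    h = float(spacing.mean())  # partial-volume shading width ~ one voxel
    frac = np.clip(0.5 + (radius - dist) / h, 0.0, 1.0)
    block = data[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]]
    shade = spec.background_intensity + (intensity - spec.background_intensity) * frac
    np.maximum(block, shade, out=block)


def make_volume(
    spec: PhantomSpec, include_targets: bool = True, include_markers: bool = True
) -> VolumeGrid:
    """Render the phantom as a CT-like volume of bright antialiased spheres.

    Sphere boundaries get partial-volume shading (linear intensity ramp one
    voxel wide) so that intensity-weighted centroids are meaningful at
    sub-voxel scale. Optional Gaussian intensity noise is seeded by
    ``spec.seed``.

    Raises :class:`FidkitError` if any sphere extends outside the volume;
    warns if the marker diameter spans fewer than two voxels (centroid
    accuracy degraded).
    """
    if spec.sphere_diameter_mm < 2 * max(spec.spacing_mm):
        warnings.warn(
            "marker diameter below two voxels; centroid accuracy not guaranteed",
            stacklevel=2,
        )
    nz, ny, nx = spec.volume_size[2], spec.volume_size[1], spec.volume_size[0]
    data = np.full((nz, ny, nx), spec.background_intensity, dtype=np.float32)
    origin = spec.volume_origin()
    obs, _ = make_phantom_points(spec)
    all_markers = (
        [*obs.collectors, *(obs.wheels[w] for w in spec.geometry.wheel_ids)]
        if include_markers
        else []
    )
    for centre in all_markers:
        _paint_sphere(
            data, spec, origin, np.asarray(centre), spec.sphere_diameter_mm / 2,
            spec.marker_intensity,
        )
    if include_targets:
        for centre in obs.targets:
            _paint_sphere(
                data, spec, origin, np.asarray(centre), spec.target_diameter_mm / 2,
                spec.marker_intensity,
            )
    if spec.intensity_noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data += rng.normal(0.0, spec.intensity_noise_sigma, data.shape).astype(
            np.float32
        )
    return VolumeGrid(
        data=data,
        spacing=tuple(float(s) for s in spec.spacing_mm),
        origin=tuple(float(o) for o in origin),
    )


@dataclass
class TrackingSession:
    """A simulated intraoperative measurement series.

    ``fiducials_tracker`` is ``(repeats, N, 3)``: the configured fiducials
    under the (unknown to the user) patient pose, with fresh localization
    noise per repeat. ``targets_tracker`` are the probe-touched targets
    under the same pose.
    """

    fiducials_tracker: np.ndarray  # (R, N, 3)
    targets_tracker: np.ndarray  # (T, 3)
    fiducials_image: np.ndarray  # (N, 3) ground truth
    targets_image: np.ndarray  # (T, 3) ground truth
    pose: RigidTransform  # image -> tracker, ground truth
    configuration: WheelConfiguration
    fle_rms: float

    @property
    def n_repeats(self) -> int:
        return self.fiducials_tracker.shape[0]

    @property
    def n_fiducials(self) -> int:
        return self.fiducials_tracker.shape[1]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (unit-quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def simulate_tracking_session(
    spec: PhantomSpec,
    configuration: WheelConfiguration,
    n_repeats: int = 10,
    rng: np.random.Generator | int | None = None,
) -> TrackingSession:
    """Simulate tracker-space measurements of a configured device.

    A random rigid "patient pose" maps image space into tracker space; each
    repeat then perturbs every fiducial independently with isotropic
    Gaussian noise of total RMS ``spec.tracker_fle_rms_mm``. Targets are
    perturbed once with the probe-noise term (default 0).

    All randomness comes from ``rng`` (seeded by ``spec.seed`` when not
    given), so identical inputs give bitwise identical sessions.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif isinstance(rng, int):
        rng = np.random.default_rng(rng)
    fid_image = configured_fiducials(spec, configuration)
    tgt_image = spec.targets_mm
    pose = RigidTransform(_random_rotation(rng), rng.uniform(-100.0, 100.0, 3))
    fid_posed = pose.apply(fid_image)
    tgt_posed = pose.apply(tgt_image)
    sigma = spec.tracker_fle_rms_mm * _SIGMA_PER_AXIS
    noise = rng.normal(0.0, sigma, size=(n_repeats, *fid_image.shape)) if sigma > 0 \
        else np.zeros((n_repeats, *fid_image.shape))
    fid_tracker = fid_posed[None, :, :] + noise
    tgt_tracker = tgt_posed.copy()
    if spec.probe_noise_rms_mm > 0:
        tgt_tracker = tgt_tracker + rng.normal(
            0.0, spec.probe_noise_rms_mm * _SIGMA_PER_AXIS, size=tgt_tracker.shape
        )
    return TrackingSession(
        fiducials_tracker=fid_tracker,
        targets_tracker=tgt_tracker,
        fiducials_image=fid_image,
        targets_image=tgt_image,
        pose=pose,
        configuration=configuration,
        fle_rms=spec.tracker_fle_rms_mm,
    )


def evaluate_session(
    session: TrackingSession,
    target_labels: tuple[str, ...] | None = None,
    fle_for_prediction: float | None = None,
) -> RegistrationErrorReport:
    """Register every repeat and assemble the full error report.

    Per repeat: rigid fit tracker -> image, RMS FRE, and the measured TRE
    of every target (mapped probe position vs. image target). The report's
    FLE is estimated from the FRE repeats; the predicted TRE uses the
    analytic model with ``fle_for_prediction`` (default: the session's true
    FLE, so prediction and measurement share the noise scale).
    """
    r_rep = session.n_repeats
    src = session.fiducials_tracker
    tgt = np.broadcast_to(session.fiducials_image, src.shape)
    r, t, fre = _register_batch(src, tgt)
    mapped = (
        np.einsum("bij,tj->bti", r, session.targets_tracker) + t[:, None, :]
    )  # (R, T, 3)
    disp = mapped - session.targets_image[None, :, :]
    tre_measured = np.sqrt(
        np.einsum("bti,bti->bt", disp, disp).mean(axis=0)
    )  # RMS over repeats, per target
    fle_pred = session.fle_rms if fle_for_prediction is None else fle_for_prediction
    tre_predicted = [
        predict_tre(session.fiducials_image, tg, fle_pred)
        for tg in session.targets_image
    ]
    com = session.fiducials_image.mean(axis=0)
    d_com = np.linalg.norm(session.targets_image - com, axis=1)
    labels = list(
        target_labels
        if target_labels is not None
        else (f"target_{i + 1}" for i in range(session.targets_image.shape[0]))
    )
    return RegistrationErrorReport(
        n_fiducials=session.n_fiducials,
        fre_repeats=fre.tolist(),
        target_labels=labels,
        tre_predicted=[float(x) for x in tre_predicted],
        d_com_to_target=d_com.tolist(),
        tre_measured=tre_measured.tolist(),
        configuration=session.configuration.label(),
    )


def twelve_target_preset(spec: PhantomSpec | None = None) -> PhantomSpec:
    """A demonstration scene with twelve anatomy-like targets.

    Target depths and lateral offsets span near-axis deep structures
    through peripheral cortical sites, emulating the spread of clinically
    interesting cranial targets (cochlea through frontal lobe). The
    positions — and any error numbers computed from them — are synthetic;
    they demonstrate the workflow, not any measured accuracy.
    """
    base = spec or PhantomSpec()
    targets = np.array(
        [
            [62.0, 18.0, -48.0],   # lateral deep, cochlea-like
            [8.0, 55.0, -52.0],    # anterior fossa-like
            [0.0, 8.0, -56.0],     # midline deep, sella-like
            [-6.0, 30.0, -58.0],   # sphenoid-like
            [2.0, -8.0, -62.0],    # central skull base-like
            [12.0, 28.0, -50.0],   # optic-canal-like
            [-55.0, 5.0, -46.0],   # middle fossa-like
            [-15.0, -60.0, -55.0], # posterior fossa-like
            [48.0, -48.0, -58.0],  # lateral posterior, deep
            [25.0, -30.0, -30.0],  # superficial posterior cortex
            [-30.0, 20.0, -26.0],  # superficial parietal-like
            [10.0, 62.0, -28.0],   # superficial frontal-like
        ]
    )
    labels = tuple(f"t{i + 1:02d}" for i in range(targets.shape[0]))
    return replace(base, targets_mm=targets, target_labels=labels)
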