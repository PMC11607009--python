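"""Spherical fiducial detection and role classification.

Detection finds connected bright components of sphere-like shape and size
and returns their intensity-weighted centroids in physical mm, which gives
sub-voxel accuracy for symmetric markers. Classification then splits an
unlabelled point cloud into the three collinear column (collector) markers,
the four wheel fiducials — identified by the wheel-specific arm radius,
i.e. perpendicular distance to the provisional axis — and leftover target
candidates.

Shape filtering uses two geometric scores, both unitless:

* component volume within ``[0.5, 2.0] x`` the expected sphere volume;
* sphericity = component volume / volume of the bounding sphere whose
  diameter is the component's maximum Feret diameter (1.0 for a perfect
  ball, small for elongated blobs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu

from .axis import LineAxis, fit_axis
from .errors import (
    AmbiguousAssignmentError,
    ClassificationError,
    NoMarkersFoundError,
    ThresholdSaturationError,
)
from .geometry import DeviceGeometry
from .volume import VolumeGrid

SPHERICITY_FLOOR = 0.35
COLLINEARITY_TOL_MM = 0.3  # RMS residual ceiling for the collector triple
RADIUS_MATCH_TOL_MM = 5.0  # |distance-to-axis - arm radius| ceiling per wheel
AMBIGUITY_MARGIN_MM = 0.5  # min cost gap between best and swapped assignment


@dataclass(frozen=True)
class DetectedMarker:
    """One detected sphere: centroid (mm, LPS), shape score and size."""

    position: np.ndarray  # (3,)
    sphericity: float
    volume_mm3: float
    n_voxels: int


@dataclass
class MarkerObservationSet:
    """The classified device observation: 3 collector + labelled wheel markers.

    ``collectors`` are sorted by their coordinate along the provisional
    axis; ``wheels`` maps wheel id to its fiducial position; ``targets``
    holds any leftover points (e.g. screw heads).
    """

    collectors: np.ndarray  # (3, 3)
    wheels: dict[str, np.ndarray]
    targets: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    collinearity_residual_mm: float = 0.0

    def __post_init__(self) -> None:
        self.collectors = np.asarray(self.collectors, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float).reshape(-1, 3)
        if self.collectors.shape != (3, 3):
            raise ValueError("exactly three collector markers required")
        if len(set(self.wheels)) != len(self.wheels):
            raise ValueError("wheel labels must be unique")

    def wheel_array(self, wheel_ids) -> np.ndarray:
        """Wheel fiducials stacked in the given wheel order."""
        return np.vstack([self.wheels[w] for w in wheel_ids])


def _max_feret_diameter(coords_mm: np.ndarray) -> float:
    """Largest pairwise distance between component voxel centres (mm)."""
    if coords_mm.shape[0] <= 1:
        return 0.0
    pts = coords_mm
    if pts.shape[0] > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # flat/degenerate component: brute-force below
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).max())


def localize_markers(
    volume: VolumeGrid,
    intensity_threshold: float | str = "auto",
    expected_diameter: float = 4.0,
    sphericity_floor: float = SPHERICITY_FLOOR,
) -> list[DetectedMarker]:
    """Detect spherical markers and return sub-voxel centroids in mm.

    Parameters
    ----------
    volume:
        The image, any orientation; results are physical LPS mm.
    intensity_threshold:
        Foreground threshold; ``"auto"`` selects Otsu's threshold on the
        intensity histogram.
    expected_diameter:
        Nominal marker diameter in mm (default 4). Components whose volume
        falls outside ``[0.5, 2.0]`` times the corresponding sphere volume
        are rejected, as are components below the sphericity floor.

    Returns
    -------
    list of :class:`DetectedMarker`, sorted by position (x, then y, then z).

    Raises
    ------
    NoMarkersFoundError
        No component survives thresholding and shape filtering.
    ThresholdSaturationError
        The threshold selects essentially the whole volume.
    """
    if expected_diameter <= 0:
        raise ValueError("expected_diameter must be positive")
    data = np.asarray(volume.data, dtype=float)
    if intensity_threshold == "auto":
        if data.max() == data.min():
            raise NoMarkersFoundError("volume is constant; no markers detectable")
        thr = float(threshold_otsu(data))
    else:
        thr = float(intensity_threshold)
    mask = data > thr
    n_fg = int(mask.sum())
    if n_fg == 0:
        raise NoMarkersFoundError(f"no voxels above threshold {thr}")
    if n_fg > 0.5 * mask.size:
        raise ThresholdSaturationError(
            f"threshold {thr} selects {n_fg}/{mask.size} voxels; not a marker image"
        )

    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    vvol = volume.voxel_volume_mm3
    sphere_vol = np.pi / 6.0 * expected_diameter**3
    markers: list[DetectedMarker] = []
    for comp in range(1, n_comp + 1):
        kji = np.argwhere(labels == comp)
        comp_vol = kji.shape[0] * vvol
        if not 0.5 * sphere_vol <= comp_vol <= 2.0 * sphere_vol:
            continue
        # voxel indices (k,j,i) -> sitk index order (i,j,k) -> physical mm
        coords_mm = volume.index_to_physical(kji[:, ::-1])
        feret = _max_feret_diameter(coords_mm)
        # pad by one voxel diagonal: voxel centres under-estimate extents
        feret = max(feret, max(volume.spacing))
        bounding_sphere_vol = np.pi / 6.0 * feret**3
        sphericity = comp_vol / bounding_sphere_vol if bounding_sphere_vol > 0 else 0.0
        if sphericity < sphericity_floor:
            continue
        weights = data[kji[:, 0], kji[:, 1], kji[:, 2]] - thr
        centroid = (coords_mm * weights[:, None]).sum(axis=0) / weights.sum()
        markers.append(
            DetectedMarker(
                position=centroid,
                sphericity=float(min(sphericity, 1.0)),
                volume_mm3=float(comp_vol),
                n_voxels=int(kji.shape[0]),
            )
        )
    if not markers:
        raise NoMarkersFoundError(
            "thresholding succeeded but no component passed the size/shape filters"
        )
    markers.sort(key=lambda m: tuple(m.position))
    return markers


def _best_collinear_triple(pts: np.ndarray) -> tuple[tuple[int, int, int], LineAxis]:
    """The 3-subset with minimal RMS perpendicular residual to its own line."""
    best: tuple[float, tuple[int, int, int], LineAxis] | None = None
    for triple in itertools.combinations(range(pts.shape[0]), 3):
        sub = pts[list(triple)]
        if np.allclose(sub.std(axis=0), 0):
            continue
        ax = fit_axis(sub)
        key = (ax.fit_residual, triple)
        if best is None or key < (best[0], best[1]):
            best = (ax.fit_residual, triple, ax)
    if best is None:
        raise ClassificationError("no non-degenerate 3-point subset found")
    return best[1], best[2]


def classify_markers(
    points: np.ndarray,
    geometry: DeviceGeometry,
    collinearity_tol: float = COLLINEARITY_TOL_MM,
    radius_tol: float = RADIUS_MATCH_TOL_MM,
    ambiguity_margin: float = AMBIGUITY_MARGIN_MM,
) -> MarkerObservationSet:
    """Split an unlabelled point cloud into collector/wheel/target roles.

    The collector triple is the 3-subset with the smallest collinearity
    residual (RMS perpendicular distance to its best-fit line), required to
    be below ``collinearity_tol``. A provisional axis is fitted through it;
    each remaining point's perpendicular distance to that axis is compared
    against the arm radii and wheels are assigned by minimum-cost bipartite
    matching on ``|distance - radius|`` (order-independent). Points not
    matched to a wheel become target candidates.

    Raises
    ------
    ClassificationError
        No collinear triple within tolerance, or a matched wheel's radius
        mismatch exceeds ``radius_tol``.
    AmbiguousAssignmentError
        Swapping two wheel assignments changes the total matching cost by
        less than ``ambiguity_margin`` (e.g. two wheels with equal radii).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 3 + geometry.n_wheels:
        raise ClassificationError(
            f"need >= {3 + geometry.n_wheels} points, got {pts.shape[0]}"
        )
    # canonical input order -> permutation invariance
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    pts = pts[order]

    triple, axis = _best_collinear_triple(pts)
    if axis.fit_residual > collinearity_tol:
        raise ClassificationError(
            f"best 3-point collinearity residual {axis.fit_residual:.3f} mm exceeds"
            f" tolerance {collinearity_tol} mm; no collector column found"
        )
    collector = pts[list(triple)]
    collector = collector[np.argsort(axis.axial_coordinate(collector))]

    rest_idx = [i for i in range(pts.shape[0]) if i not in triple]
    rest = pts[rest_idx]
    dists = axis.distance_to(rest)
    radii = np.asarray(geometry.arm_radii_mm)
    cost = np.abs(dists[None, :] - radii[:, None])  # (wheels, points)
    rows, cols = linear_sum_assignment(cost)
    base_cost = float(cost[rows, cols].sum())
    matched = dict(zip(rows.tolist(), cols.tolist()))

    worst = float(cost[rows, cols].max())
    if worst > radius_tol:
        raise ClassificationError(
            f"wheel-radius match failed: worst |distance - radius| = {worst:.2f} mm"
            f" exceeds tolerance {radius_tol} mm"
        )
    # ambiguity: any pairwise swap that costs (almost) nothing means the
    # radii do not discriminate the wheels
    for a, b in itertools.combinations(range(len(radii)), 2):
        swapped = base_cost - cost[a, matched[a]] - cost[b, matched[b]] \
            + cost[a, matched[b]] + cost[b, matched[a]]
        if swapped - base_cost < ambiguity_margin:
            raise AmbiguousAssignmentError(
                f"wheels '{geometry.wheel_ids[a]}' and '{geometry.wheel_ids[b]}'"
                f" match the observed radii ambiguously (swap cost gap"
                f" {swapped - base_cost:.3g} mm < margin {ambiguity_margin} mm)"
            )

    wheels = {geometry.wheel_ids[w]: rest[p] for w, p in matched.items()}
    target_rows = [i for i in range(rest.shape[0]) if i not in matched.values()]
    targets = rest[target_rows] if target_rows else np.empty((0, 3))
    return MarkerObservationSet(
        collectors=collector,
        wheels=wheels,
        targets=targets,
        collinearity_residual_mm=axis.fit_residual,
    )
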