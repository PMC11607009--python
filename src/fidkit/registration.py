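"""Rigid point-based registration and its error model.

The chain of quantities used throughout image-guided navigation:

* **FLE** (fiducial localization error): RMS error in localizing a single
  fiducial, the underlying noise source. Assumed isotropic, zero-mean,
  independent across fiducials.
* **FRE** (fiducial registration error): RMS residual distance between
  corresponding fiducials after the rigid fit. For isotropic FLE,
  ``<FRE^2> = (1 - 2/N) FLE^2``, which inverts to the estimator
  ``FLE_est^2 = N/(N-2) * mu`` with ``mu`` the average squared measured
  FRE over repeated registrations.
* **TRE** (target registration error): distance between a target's mapped
  and true positions — the clinically meaningful accuracy. Its RMS
  expectation for a target at position ``r`` is::

      TRE^2(r) = FLE^2 / N * (1 + (1/3) * sum_k d_k^2 / f_k^2)

  where ``d_k`` is the target's distance to principal axis ``k`` of the
  fiducial configuration and ``f_k`` the RMS fiducial distance to that
  axis. A Monte-Carlo estimator (perturb, register, measure) is provided
  as a first-class alternative and as the cross-check of the analytic form.

The rigid fit is the SVD (Kabsch/Arun) solution with the determinant
correction that forbids reflections. All quantities are RMS in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np

from .errors import DegenerateFiducialsError, UndefinedEstimatorError

#: ratio of smallest to largest principal RMS spread below which a fiducial
#: configuration counts as collinear for the TRE model
_DEGENERACY_RATIO = 1e-6


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R x + t`` (no scaling, no reflection)."""

    rotation: np.ndarray  # (3,3), orthonormal, det +1
    translation: np.ndarray  # (3,), mm

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise ValueError("rotation must have determinant +1 (no reflection)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    # --- serialization ----------------------------------------------------

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "rotation_row_major": self.rotation.reshape(-1).tolist(),
                    "translation_mm": self.translation.tolist(),
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["rotation_row_major"], dtype=float).reshape(3, 3),
            np.asarray(d["translation_mm"], dtype=float),
        )

    def to_matrix_file(self, path: str | Path) -> None:
        np.savetxt(path, self.as_matrix(), fmt="%.17g")

    @classmethod
    def from_matrix_file(cls, path: str | Path) -> "RigidTransform":
        return cls.from_matrix(np.loadtxt(path))


def _register_batch(source: np.ndarray, target: np.ndarray):
    """Vectorized Kabsch fit for a batch of corresponding point sets.

    Parameters are ``(B, N, 3)`` stacks; returns rotations ``(B, 3, 3)``,
    translations ``(B, 3)`` and per-set RMS FRE ``(B,)``. Reflections are
    prevented by flipping the sign of the smallest singular direction.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    sc = src.mean(axis=1, keepdims=True)
    tc = tgt.mean(axis=1, keepdims=True)
    s0 = src - sc
    t0 = tgt - tc
    h = np.einsum("bni,bnj->bij", s0, t0)
    u, _, vt = np.linalg.svd(h)
    # det(V U^T) = det(V) det(U); flip the smallest singular direction when
    # the unconstrained optimum would be a reflection
    det = np.linalg.det(u) * np.linalg.det(vt)
    d = np.ones((src.shape[0], 3))
    d[:, 2] = np.sign(det)
    # R[b] = V diag(d) U^T
    r = np.einsum("bki,bk,bjk->bij", vt, d, u)
    t = tc[:, 0, :] - np.einsum("bij,bj->bi", r, sc[:, 0, :])
    resid = np.einsum("bij,bnj->bni", r, src) + t[:, None, :] - tgt
    fre = np.sqrt(np.einsum("bni,bni->b", resid, resid) / src.shape[1])
    return r, t, fre


def register_rigid(
    source_points: np.ndarray, target_points: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit mapping ``source`` onto ``target``.

    Point correspondence is by index; both lists must have equal length
    >= 3 and must not be collinear. Returns the transform and the RMS
    fiducial registration error (mm) after alignment.

    Raises
    ------
    DegenerateFiducialsError
        Fewer than 3 points, or a collinear/coincident configuration for
        which the rotation is not uniquely determined (reflection guard).
    """
    src = np.asarray(source_points, dtype=float)
    tgt = np.asarray(target_points, dtype=float)
    if src.ndim != 2 or src.shape[1] != 3 or src.shape != tgt.shape:
        raise ValueError("source and target must be (N, 3) arrays of equal shape")
    n = src.shape[0]
    if n < 3:
        raise DegenerateFiducialsError(f"rigid fit needs >= 3 points, got {n}")
    for name, pts in (("source", src), ("target", tgt)):
        c = pts - pts.mean(axis=0)
        s = np.linalg.svd(c, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise DegenerateFiducialsError(
                f"{name} points are collinear; rotation is not unique"
            )
    r, t, fre = _register_batch(src[None], tgt[None])
    return RigidTransform(r[0], t[0]), float(fre[0])


def fre_rms(transform: RigidTransform, source: np.ndarray, target: np.ndarray) -> float:
    """RMS residual of ``transform`` applied to corresponding points."""
    resid = transform.apply(source) - np.asarray(target, dtype=float)
    return float(np.sqrt((resid**2).sum(axis=1).mean()))


def estimate_fle(fre_repeats: Sequence[float], n_fiducials: int) -> float:
    """Estimate FLE RMS from repeated FRE measurements.

    ``mu`` is the mean of the squared per-repeat RMS FREs; the estimator is
    ``FLE_est = sqrt(N/(N-2) * mu)``, the exact inversion of
    ``<FRE^2> = (1 - 2/N) FLE^2`` for isotropic, independent FLE.

    Raises
    ------
    UndefinedEstimatorError
        If ``n_fiducials <= 2`` (the estimator's denominator vanishes) or
        the repeat list is empty/negative.
    """
    if n_fiducials <= 2:
        raise UndefinedEstimatorError(
            f"FLE estimation undefined for N = {n_fiducials} (needs N >= 3)"
        )
    fres = np.asarray(list(fre_repeats), dtype=float)
    if fres.size == 0:
        raise UndefinedEstimatorError("need at least one FRE measurement")
    if np.any(fres < 0):
        raise UndefinedEstimatorError("FRE values must be non-negative")
    mu = float(np.mean(fres**2))
    return float(np.sqrt(n_fiducials / (n_fiducials - 2) * mu))


def _principal_spread(fiducials: np.ndarray):
    """Centroid, principal axes and per-axis RMS spreads of a fiducial set.

    Returns ``(centroid, axes (3,3) columns, f_sq (3,))`` where ``f_sq[k]``
    is the mean squared fiducial distance to principal axis ``k``.
    """
    fid = np.asarray(fiducials, dtype=float)
    centroid = fid.mean(axis=0)
    centred = fid - centroid
    scatter = centred.T @ centred / fid.shape[0]
    lam, vec = np.linalg.eigh(scatter)  # ascending eigenvalues
    lam = np.maximum(lam, 0.0)
    f_sq = lam.sum() - lam  # distance^2 to axis k = sum of other eigenvalues
    return centroid, vec, f_sq


def predict_tre(fiducials: np.ndarray, target: np.ndarray, fle_rms: float) -> float:
    """Expected RMS target registration error at ``target``.

    Analytic first-order model for N fiducials with isotropic FLE::

        TRE^2 = FLE^2/N * (1 + (1/3) * sum_k d_k^2 / f_k^2)

    ``d_k``: target distance to principal axis ``k`` of the fiducial
    configuration; ``f_k``: RMS fiducial distance to that axis. At the
    fiducial centroid this reduces to ``FLE^2 / N``.

    Raises
    ------
    DegenerateFiducialsError
        Collinear fiducials (smallest ``f_k`` below 1e-6 of the largest) or
        fewer than 3 points.
    """
    fid = np.asarray(fiducials, dtype=float)
    if fid.ndim != 2 or fid.shape[1] != 3 or fid.shape[0] < 3:
        raise DegenerateFiducialsError("TRE prediction needs >= 3 fiducials")
    if fle_rms < 0:
        raise ValueError("fle_rms must be non-negative")
    centroid, vec, f_sq = _principal_spread(fid)
    if np.sqrt(f_sq.min()) <= _DEGENERACY_RATIO * np.sqrt(f_sq.max()):
        raise DegenerateFiducialsError(
            "fiducial configuration is (near-)collinear; TRE model undefined"
        )
    dvec = np.asarray(target, dtype=float) - centroid
    along = dvec @ vec  # coordinates along principal axes
    d_sq = (dvec @ dvec) - along**2  # distance^2 to each axis
    n = fid.shape[0]
    tre_sq = fle_rms**2 / n * (1.0 + (d_sq / f_sq).sum() / 3.0)
    return float(np.sqrt(tre_sq))


def predict_tre_monte_carlo(
    fiducials: np.ndarray,
    target: np.ndarray,
    fle_rms: float,
    n_trials: int = 50_000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Monte-Carlo RMS TRE: perturb fiducials, register, map the target.

    Each trial adds isotropic Gaussian noise of total RMS ``fle_rms``
    (per-axis sigma ``fle_rms/sqrt(3)``) to the fiducials, fits the rigid
    transform back to the true positions and records the displacement of
    the mapped target. Returns the RMS displacement over all trials.
    Independent of :func:`predict_tre`; used to validate it.
    """
    fid = np.asarray(fiducials, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if fid.ndim != 2 or fid.shape[1] != 3 or fid.shape[0] < 3:
        raise DegenerateFiducialsError("TRE simulation needs >= 3 fiducials")
    rng = np.random.default_rng(rng)
    sigma = fle_rms / np.sqrt(3.0)
    noisy = fid[None, :, :] + rng.normal(0.0, sigma, size=(n_trials, *fid.shape))
    r, t, _ = _register_batch(noisy, np.broadcast_to(fid, (n_trials, *fid.shape)))
    mapped = np.einsum("bij,j->bi", r, tgt) + t
    disp = mapped - tgt
    return float(np.sqrt(np.einsum("bi,bi->b", disp, disp).mean()))


def measure_tre(
    transform: RigidTransform, tracker_target: np.ndarray, image_target: np.ndarray
) -> float:
    """Distance between the mapped tracker-space target and the image target."""
    return float(
        np.linalg.norm(transform.apply(np.asarray(tracker_target, dtype=float))
                       - np.asarray(image_target, dtype=float))
    )


@dataclass
class RegistrationErrorReport:
    """Summary of a registration session's error chain, one row per target.

    Mirrors the conventional report layout: fiducial count N, measured FRE
    repeats and their RMS, ``mu`` (mean squared FRE), the FRE-based FLE
    estimate, and per-target predicted/measured TRE plus the distance from
    the fiducial centre of mass to the target.
    """

    n_fiducials: int
    fre_repeats: list[float]
    target_labels: list[str]
    tre_predicted: list[float]
    d_com_to_target: list[float]
    tre_measured: list[float] | None = None
    configuration: str = ""

    def __post_init__(self) -> None:
        if self.n_fiducials < 3:
            raise DegenerateFiducialsError("report requires N >= 3 fiducials")
        t = len(self.target_labels)
        if not (len(self.tre_predicted) == len(self.d_com_to_target) == t):
            raise ValueError("per-target fields must have one entry per target")
        if self.tre_measured is not None and len(self.tre_measured) != t:
            raise ValueError("tre_measured must have one entry per target")

    @property
    def mu(self) -> float:
        """Mean squared measured FRE (mm^2)."""
        return float(np.mean(np.asarray(self.fre_repeats) ** 2))

    @property
    def fre_rms(self) -> float:
        return float(np.sqrt(self.mu))

    @property
    def fle_est_rms(self) -> float:
        return estimate_fle(self.fre_repeats, self.n_fiducials)

    def to_frame(self):
        """One row per target with the standard report columns."""
        import pandas as pd

        return pd.DataFrame(
            {
                "target": self.target_labels,
                "configuration": self.configuration,
                "fre_mm": self.fre_rms,
                "fle_mm": self.fle_est_rms,
                "tre_predicted_mm": self.tre_predicted,
                "tre_measured_mm": (
                    self.tre_measured if self.tre_measured is not None
                    else [np.nan] * len(self.target_labels)
                ),
                "d_com_to_target_mm": self.d_com_to_target,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
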