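"""Brute-force search for the TRE-minimizing wheel configuration.

The configuration space is the Cartesian product of the wheels' discrete
stops (10^4 for the default device). Each configuration places the four
fiducials at known candidate points; the expected TRE at the surgical
target(s) follows from the analytic error model in
:mod:`fidkit.registration`. The search simply evaluates every
configuration — vectorized over the whole product, this takes well under a
second — and returns the minimizer plus the full ranking.

Determinism: the objective is a pure function of the configuration, ties
are broken by (smallest TRE, smallest centroid-to-target distance,
lexicographically smallest index tuple), so the result does not depend on
evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .axis import CandidateSet
from .errors import DegenerateFiducialsError
from .geometry import DeviceGeometry, WheelConfiguration
from .registration import _DEGENERACY_RATIO

log = logging.getLogger(__name__)


@dataclass
class SearchResult:
    """Outcome of the exhaustive configuration search.

    ``ranking`` holds every evaluated (non-degenerate) configuration with
    its aggregated TRE and centroid-to-target distance, sorted best-first.
    """

    best: WheelConfiguration
    tre_min: float
    per_target_tre: np.ndarray  # (T,) at the best configuration
    d_com_to_target: np.ndarray  # (T,) at the best configuration
    ranking: pd.DataFrame
    n_evaluated: int
    n_degenerate: int
    objective: str

    def summary(self) -> str:
        wheels = ", ".join(w[0].upper() for w in self.best.wheel_ids)
        return (
            f"best configuration ({wheels}): {self.best.label()}  "
            f"TRE = {self.tre_min:.3f} mm"
        )


def _configuration_fiducials(
    candidate_sets: Sequence[CandidateSet], positions_per_wheel: int
) -> tuple[np.ndarray, np.ndarray]:
    """All configuration index tuples and their fiducial stacks.

    Returns ``combos`` ``(M, W)`` of 1-based stop indices in lexicographic
    order (first wheel slowest) and ``fiducials`` ``(M, W, 3)``.
    """
    w = len(candidate_sets)
    n = positions_per_wheel
    grids = np.indices((n,) * w).reshape(w, -1).T  # 0-based, first wheel slowest
    combos = grids + 1
    pos = np.stack([cs.candidates for cs in candidate_sets])  # (W, n, 3)
    fiducials = np.stack(
        [pos[k][grids[:, k]] for k in range(w)], axis=1
    )  # (M, W, 3)
    return combos, fiducials


def predict_tre_batch(
    fiducials: np.ndarray, targets: np.ndarray, fle_rms: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized analytic TRE for a batch of fiducial configurations.

    Parameters
    ----------
    fiducials: ``(M, N, 3)`` configurations of N fiducials.
    targets: ``(T, 3)`` target points.
    fle_rms: isotropic fiducial localization error (mm RMS).

    Returns
    -------
    tre: ``(M, T)`` expected RMS TRE; ``inf`` for degenerate (collinear)
        configurations.
    d_com: ``(M, T)`` centroid-to-target distances.
    degenerate: ``(M,)`` boolean mask of rejected configurations.
    """
    fid = np.asarray(fiducials, dtype=float)
    tgt = np.atleast_2d(np.asarray(targets, dtype=float))
    m, n_fid, _ = fid.shape
    centroid = fid.mean(axis=1)  # (M, 3)
    centred = fid - centroid[:, None, :]
    scatter = np.einsum("mni,mnj->mij", centred, centred) / n_fid
    lam, vec = np.linalg.eigh(scatter)  # (M,3) ascending, (M,3,3) columns
    lam = np.maximum(lam, 0.0)
    f_sq = lam.sum(axis=1, keepdims=True) - lam  # (M, 3)
    degenerate = np.sqrt(f_sq.min(axis=1)) <= _DEGENERACY_RATIO * np.sqrt(
        f_sq.max(axis=1)
    )
    f_sq_safe = np.where(f_sq > 0, f_sq, np.inf)

    dvec = tgt[None, :, :] - centroid[:, None, :]  # (M, T, 3)
    d_com = np.linalg.norm(dvec, axis=2)
    along = np.einsum("mti,mik->mtk", dvec, vec)  # coords on principal axes
    d_sq = d_com[:, :, None] ** 2 - along**2  # (M, T, 3) distance^2 to axes
    d_sq = np.maximum(d_sq, 0.0)
    tre_sq = fle_rms**2 / n_fid * (1.0 + (d_sq / f_sq_safe[:, None, :]).sum(axis=2) / 3.0)
    tre = np.sqrt(tre_sq)
    tre[degenerate] = np.inf
    return tre, d_com, degenerate


def search_best_configuration(
    candidate_sets: Sequence[CandidateSet],
    targets: np.ndarray,
    fle_rms: float,
    geometry: DeviceGeometry | None = None,
    objective: Literal["max", "mean"] = "max",
) -> SearchResult:
    """Exhaustively rank all wheel configurations by predicted TRE.

    Parameters
    ----------
    candidate_sets:
        One :class:`CandidateSet` per wheel, in device wheel order.
    targets:
        ``(T, 3)`` or ``(3,)`` surgical target(s), mm.
    fle_rms:
        Fiducial localization error driving the TRE model.
    objective:
        How per-target TREs are reduced for multiple targets: ``"max"``
        (worst case, default) or ``"mean"``.

    Raises
    ------
    ValueError for empty targets or negative FLE;
    DegenerateFiducialsError if every configuration is collinear.
    """
    if fle_rms < 0:
        raise ValueError("fle_rms must be non-negative")
    tgt = np.atleast_2d(np.asarray(targets, dtype=float))
    if tgt.size == 0:
        raise ValueError("at least one target point is required")
    if objective not in ("max", "mean"):
        raise ValueError(f"unknown objective {objective!r}")
    geometry = geometry or DeviceGeometry.default()
    if len(candidate_sets) != geometry.n_wheels:
        raise ValueError("one candidate set per wheel required")

    combos, fiducials = _configuration_fiducials(
        candidate_sets, geometry.positions_per_wheel
    )
    tre, d_com, degenerate = predict_tre_batch(fiducials, tgt, fle_rms)
    reducer = np.max if objective == "max" else np.mean
    tre_agg = reducer(tre, axis=1)
    d_agg = reducer(d_com, axis=1)

    n_degenerate = int(degenerate.sum())
    if n_degenerate == combos.shape[0]:
        raise DegenerateFiducialsError(
            "every configuration is collinear; no valid fiducial arrangement"
        )
    if n_degenerate:
        log.info("skipped %d near-collinear configurations", n_degenerate)

    keep = ~degenerate
    combos_k, tre_k, d_k = combos[keep], tre_agg[keep], d_agg[keep]
    # tie-break: TRE, then centroid distance, then lexicographic indices;
    # np.lexsort sorts by its *last* key first
    keys = tuple(combos_k[:, w] for w in range(combos_k.shape[1] - 1, -1, -1))
    order = np.lexsort(keys + (d_k, tre_k))
    combos_s, tre_s, d_s = combos_k[order], tre_k[order], d_k[order]

    wheel_cols = {f"{w}_position": combos_s[:, i] for i, w in enumerate(geometry.wheel_ids)}
    ranking = pd.DataFrame({**wheel_cols, "tre_mm": tre_s, "d_com_mm": d_s})

    best_idx_global = keep.nonzero()[0][order[0]]
    best = WheelConfiguration(geometry.wheel_ids, tuple(int(i) for i in combos_s[0]))
    return SearchResult(
        best=best,
        tre_min=float(tre_s[0]),
        per_target_tre=tre[best_idx_global],
        d_com_to_target=d_com[best_idx_global],
        ranking=ranking,
        n_evaluated=int(keep.sum()),
        n_degenerate=n_degenerate,
        objective=objective,
    )
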