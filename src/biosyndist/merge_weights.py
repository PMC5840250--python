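"""Fusion of a class-based biosynthetic distance with Bray–Curtis.

When enzyme-level annotations are unavailable, the biosynthesis tree can be
built from coarse compound traits (chemical classes, functional groups).
The resulting distance loses compound identity, so it is merged with
Bray–Curtis dissimilarity as a weighted mean of the two max-standardized
matrices:

    mDist = w · bio′ + (1 − w) · conv′,      d′ = d / max(d),  0 ≤ w ≤ 1.

``scan_weight`` searches a grid of w for the merge that best reproduces an
enzyme-level reference distance, scored by the Mantel (Pearson) correlation
of the off-diagonal entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_matrices import DistanceMatrix, ValidationError

__all__ = ["standardize", "merge_dist", "scan_weight", "WeightScanResult"]


def standardize(d: DistanceMatrix) -> DistanceMatrix:
    """Rescale a distance matrix to [0, 1] by dividing by its maximum."""
    m = d.values.max()
    if m <= 0:
        raise ValidationError("cannot standardize an all-zero distance matrix")
    return DistanceMatrix(d.ids, d.values / m)


def merge_dist(bio: DistanceMatrix, conv: DistanceMatrix, w: float) -> DistanceMatrix:
    """Weighted mean of two standardized distance matrices.

    w = 1 returns the standardized biosynthetic distance, w = 0 the
    standardized conventional one.  Both inputs are standardized here, so
    passing already-standardized matrices is harmless (idempotent).
    """
    if not 0.0 <= w <= 1.0:
        raise ValidationError(f"merge weight w must be in [0, 1], got {w}")
    if bio.ids != conv.ids:
        raise ValidationError(
            "distance matrices to merge must share identical sample ordering"
        )
    bio_s = standardize(bio)
    conv_s = standardize(conv)
    return DistanceMatrix(bio.ids, w * bio_s.values + (1.0 - w) * conv_s.values)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt((xc**2).sum())
    ny = np.sqrt((yc**2).sum())
    if nx == 0 or ny == 0:
        raise ValidationError(
            "correlation undefined: constant off-diagonal distances"
        )
    return float((xc * yc).sum() / (nx * ny))


@dataclass
class WeightScanResult:
    """Mantel-correlation profile of the merge weight w, with its argmax."""

    grid: np.ndarray
    r_values: np.ndarray
    w_star: float
    r_star: float


def scan_weight(
    bio_class: DistanceMatrix,
    conv: DistanceMatrix,
    reference: DistanceMatrix,
    step: float = 0.001,
) -> WeightScanResult:
    """Scan w ∈ {0, step, …, 1} for the merge closest to a reference.

    For every grid value the Mantel correlation (point Pearson r of the
    vectorized upper triangles, no permutations) between
    ``merge_dist(bio_class, conv, w)`` and ``reference`` is computed.  Ties
    are broken toward smaller w.
    """
    if not 0.0 < step <= 0.5:
        raise ValidationError(f"step must be in (0, 0.5], got {step}")
    for other in (conv, reference):
        if other.ids != bio_class.ids:
            raise ValidationError("all matrices must share identical sample ids")
    ref = reference.condensed()
    if np.ptp(ref) == 0:
        raise ValidationError("reference matrix has constant off-diagonal entries")

    bio_u = standardize(bio_class).condensed()
    conv_u = standardize(conv).condensed()
    n_steps = int(np.floor(1.0 / step + 1e-9))
    grid = np.arange(n_steps + 1) * step
    if grid[-1] < 1.0 - 1e-12:  # step does not divide 1: still span the endpoint
        grid = np.append(grid, 1.0)
    grid[-1] = 1.0
    r_values = np.array(
        [_pearson(w * bio_u + (1.0 - w) * conv_u, ref) for w in grid]
    )
    best = int(np.argmax(r_values))  # first max → smallest w on ties
    return WeightScanResult(
        grid=grid,
        r_values=r_values,
        w_star=float(grid[best]),
        r_star=float(r_values[best]),
    )
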