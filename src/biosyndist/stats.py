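"""Mantel tests, NMDS ordination and the factor goodness-of-fit statistic.

These are the comparison tools used around the distance pipeline: a Mantel
permutation test quantifies how strongly two distance matrices agree, NMDS
embeds a distance matrix in few dimensions for inspection, and the factor
fit measures how much of the ordination scatter a grouping (e.g. species)
explains, analogous to fitting a factor onto an ordination.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
from sklearn.manifold import MDS

from .io_matrices import DistanceMatrix, ValidationError

__all__ = [
    "MantelResult",
    "FactorFitResult",
    "NMDSResult",
    "mantel",
    "nmds",
    "factor_fit",
]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt((xc**2).sum())
    ny = np.sqrt((yc**2).sum())
    if nx == 0 or ny == 0:
        raise ValidationError("correlation undefined: constant distances")
    return float((xc * yc).sum() / (nx * ny))


@dataclass
class MantelResult:
    """Pearson Mantel statistic with a one-sided permutation p-value."""

    r: float
    p: float
    n_perm: int
    seed: int | None


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test: Pearson correlation of two distance matrices.

    The statistic is the correlation of the vectorized upper triangles; the
    null distribution is built by simultaneously permuting rows and columns
    of ``d2``.  The one-sided p-value uses the add-one rule
    p = (#{r_perm ≥ r_obs} + 1) / (n_perm + 1) and is therefore never 0.

    With ``n_perm <= 0`` only the point estimate is computed (p = NaN).
    """
    if d1.ids != d2.ids:
        raise ValidationError("Mantel test requires identical ids in same order")
    n = len(d1)
    if n < 4:
        raise ValidationError(
            f"Mantel test needs at least 4 samples, got {n}"
        )
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    r_obs = _pearson(x, d2.values[iu])
    if n_perm <= 0:
        return MantelResult(r=r_obs, p=float("nan"), n_perm=0, seed=seed)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y = d2.values[np.ix_(perm, perm)][iu]
        if _pearson(x, y) >= r_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, seed=seed)


def mantel_exhaustive(d1: DistanceMatrix, d2: DistanceMatrix) -> MantelResult:
    """Mantel test over every permutation (small n only).

    Enumerates all n! simultaneous row/column permutations of ``d2``; the
    p-value is the exact fraction of permutations (identity included) with
    r at least the observed value.
    """
    if d1.ids != d2.ids:
        raise ValidationError("Mantel test requires identical ids in same order")
    n = len(d1)
    if n > 8:
        raise ValidationError("exhaustive enumeration is limited to n ≤ 8")
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    r_obs = _pearson(x, d2.values[iu])
    hits = 0
    total = 0
    for perm in iter_permutations(range(n)):
        idx = np.array(perm)
        y = d2.values[np.ix_(idx, idx)][iu]
        if _pearson(x, y) >= r_obs - 1e-12:
            hits += 1
        total += 1
    return MantelResult(r=r_obs, p=hits / total, n_perm=total, seed=None)


@dataclass
class NMDSResult:
    """Low-dimensional NMDS configuration and its stress-1 value."""

    ids: list[str]
    coords: np.ndarray
    stress: float


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    seed: int | None = None,
    max_iter: int = 300,
) -> NMDSResult:
    """Non-metric multidimensional scaling of a distance matrix.

    Runs ``n_starts`` random initializations of an isotonic-regression NMDS
    and keeps the lowest-stress configuration; deterministic given ``seed``.
    Stress is Kruskal's stress-1 (0 = perfect rank preservation).
    """
    n = len(d)
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the sample count {n}")
    model = MDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_starts,
        max_iter=max_iter,
        random_state=seed,
        normalized_stress=True,
    )
    import warnings

    with warnings.catch_warnings():
        # scikit-learn is migrating the MDS keyword API; the settings above
        # are the version-portable spelling
        warnings.simplefilter("ignore", FutureWarning)
        coords = model.fit_transform(d.values)
    return NMDSResult(ids=list(d.ids), coords=coords, stress=float(model.stress_))


@dataclass
class FactorFitResult:
    """Goodness of fit of a grouping factor on ordination coordinates."""

    r2: float
    p: float
    n_perm: int
    seed: int | None


def _factor_r2(coords: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    grand = coords.mean(axis=0)
    ss_total = float(((coords - grand) ** 2).sum())
    if ss_total == 0:
        raise ValidationError("all coordinates identical; factor fit undefined")
    ss_within = 0.0
    for g in range(n_groups):
        sub = coords[codes == g]
        if len(sub):
            ss_within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return 1.0 - ss_within / ss_total


def factor_fit(
    coords: np.ndarray,
    labels: list[str] | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> FactorFitResult:
    """Fraction of ordination variance explained by a categorical factor.

    r² = 1 − SS_within / SS_total on the coordinates, with SS_within taken
    around group centroids; the p-value permutes the group labels.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    if coords.ndim != 2 or len(labels) != coords.shape[0]:
        raise ValidationError("labels and coordinate rows must align")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValidationError("factor fit needs at least 2 groups")
    r2_obs = _factor_r2(coords, codes, len(uniq))
    if n_perm <= 0:
        return FactorFitResult(r2=r2_obs, p=float("nan"), n_perm=0, seed=seed)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        shuffled = rng.permutation(codes)
        if _factor_r2(coords, shuffled, len(uniq)) >= r2_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return FactorFitResult(r2=r2_obs, p=p, n_perm=n_perm, seed=seed)
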