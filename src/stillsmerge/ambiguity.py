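"""Indexing-ambiguity resolution by modified Brehm-Diederichs clustering.

In point group 23 the lattice symmetry exceeds the intensity symmetry, so the
indexings (h,k,l) and (k,h,-l) are geometrically indistinguishable and every
still must be brought onto one convention before merging.  Each image ``a``
gets a 2D vector ``x_a`` (components initialized uniformly in [0,1]); the
functional

    f(x) = sum over image pairs (a,b) of
           (x_a . x_b - r_ab)^2  +  (x_a . S x_b - r'_ab)^2,

is minimized by L-BFGS with an analytic gradient, where ``r_ab`` is the
through-origin correlation between the images' partiality-corrected
intensities on common reflections, ``r'_ab`` the same with one image
reindexed by (k,h,-l), and ``S`` the component-swap matrix [[0,1],[1,0]].
The swap plays the role of the reindexing operator in vector space: swapping
an image's hand in the data while swapping its vector components leaves the
functional invariant, and the second (inverted-hand) term doubles the number
of pairwise comparisons.  After minimization the vectors fall into two
clusters, one per indexing hand; a deterministic 2-means split labels them.

The through-origin correlation is the regression-based coefficient

    r = sqrt(1 - (SS_res(y|x) + SS_res(x|y)) / (SS_tot(y) + SS_tot(x))),

with both through-origin fits ``y = b x`` (b = sum(xy)/sum(x^2)) and the
symmetric counterpart; SS_tot is about the mean.  Proportional inputs give
exactly 1; a negative radicand ("imaginary" value) is reassigned 0.  Forcing
the fit through the origin makes the coefficient meaningful from as few as
two shared reflections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .geometry import map_to_asu, reindex, resolution
from .image import ImageModel

__all__ = [
    "CorrelationTable",
    "cc_through_origin",
    "build_correlation_table",
    "minimize_functional",
    "assign_hands",
    "apply_reindexing",
]

_SWAP = np.array([[0.0, 1.0], [1.0, 0.0]])


@dataclass
class CorrelationTable:
    r_same: np.ndarray  # (n, n) same-hand correlations, 0 where insufficient
    r_cross: np.ndarray  # (n, n) cross-hand correlations
    n_shared_same: np.ndarray  # (n, n) int
    n_shared_cross: np.ndarray
    mask_same: np.ndarray  # (n, n) bool, pair usable
    mask_cross: np.ndarray

    @property
    def n_images(self) -> int:
        return self.r_same.shape[0]


def cc_through_origin(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric through-origin correlation in [0, 1]; see module docstring."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("insufficient overlap: need >= 2 shared reflections")
    sxx = float(x @ x)
    syy = float(y @ y)
    sxy = float(x @ y)
    if sxx == 0.0 or syy == 0.0:
        return 0.0
    res_y = syy - sxy * sxy / sxx  # residual SS of y = (sxy/sxx) x
    res_x = sxx - sxy * sxy / syy
    tot = float(((y - y.mean()) ** 2).sum() + ((x - x.mean()) ** 2).sum())
    if tot == 0.0:
        # identical constant lists: perfectly proportional iff residuals vanish
        return 1.0 if (res_y + res_x) <= 1e-12 * (sxx + syy) else 0.0
    radicand = 1.0 - (res_y + res_x) / tot
    if radicand < 0.0:
        return 0.0
    return float(min(np.sqrt(radicand), 1.0))


def _intensity_maps(image: ImageModel, d_min: float) -> tuple[dict, dict]:
    """(same-hand, cross-hand) maps from asu key -> corrected intensity."""
    hkl, i_corr, _ = image.accepted_subset()
    if len(hkl) == 0:
        return {}, {}
    d = resolution(hkl, image.cell)
    keep = d >= d_min
    hkl, i_corr = hkl[keep], i_corr[keep]
    same = {tuple(h): v for h, v in zip(map(tuple, map_to_asu(hkl)), i_corr)}
    cross = {tuple(h): v for h, v in zip(map(tuple, map_to_asu(reindex(hkl))), i_corr)}
    return same, cross


def build_correlation_table(
    images: list[ImageModel], d_min: float = 1.8, min_shared: int = 2
) -> CorrelationTable:
    """Pairwise same- and cross-hand correlations over common reflections.

    Intensities must already be partiality-corrected (cutoff applied);
    reflections beyond ``d_min`` are excluded.  Pairs sharing fewer than
    ``min_shared`` reflections are masked out rather than imputed.
    """
    n = len(images)
    maps = [_intensity_maps(img, d_min) for img in images]
    r_same = np.zeros((n, n))
    r_cross = np.zeros((n, n))
    ns = np.zeros((n, n), dtype=int)
    nc = np.zeros((n, n), dtype=int)
    for a in range(n):
        same_a = maps[a][0]
        keys_a = set(same_a)
        for b in range(a, n):
            same_b, cross_b = maps[b]
            shared = keys_a & set(same_b)
            if len(shared) >= min_shared:
                xa = np.fromiter((same_a[k] for k in shared), float, len(shared))
                xb = np.fromiter((same_b[k] for k in shared), float, len(shared))
                r_same[a, b] = r_same[b, a] = cc_through_origin(xa, xb)
                ns[a, b] = ns[b, a] = len(shared)
            if a != b:
                sharedx = keys_a & set(cross_b)
                if len(sharedx) >= min_shared:
                    xa = np.fromiter((same_a[k] for k in sharedx), float, len(sharedx))
                    xb = np.fromiter((cross_b[k] for k in sharedx), float, len(sharedx))
                    r_cross[a, b] = r_cross[b, a] = cc_through_origin(xa, xb)
                    nc[a, b] = nc[b, a] = len(sharedx)
    mask_same = ns >= min_shared
    mask_cross = nc >= min_shared
    np.fill_diagonal(mask_same, False)  # self-pairs carry no information
    np.fill_diagonal(mask_cross, False)
    return CorrelationTable(r_same, r_cross, ns, nc, mask_same, mask_cross)


def functional_and_gradient(
    X: np.ndarray, table: CorrelationTable
) -> tuple[float, np.ndarray]:
    """Objective f(x) and its analytic gradient; pairs counted once each."""
    D = X @ X.T
    Dp = X @ _SWAP @ X.T  # symmetric since S is
    E1 = np.where(table.mask_same, D - table.r_same, 0.0)
    E2 = np.where(table.mask_cross, Dp - table.r_cross, 0.0)
    f = 0.5 * float((E1 * E1).sum() + (E2 * E2).sum())  # each a<b pair once
    grad = 2.0 * (E1 @ X) + 2.0 * (E2 @ X @ _SWAP)
    return f, grad


def minimize_functional(
    table: CorrelationTable, seed: int = 1, max_iter: int = 500
) -> tuple[np.ndarray, dict]:
    """Minimize the pairwise functional by L-BFGS from seeded random vectors.

    Returns the converged (n, 2) vectors and an info dict with the initial and
    final objective values and convergence status.
    """
    n = table.n_images
    rng = np.random.default_rng(seed)
    X0 = rng.uniform(0.0, 1.0, size=(n, 2))
    f0, _ = functional_and_gradient(X0, table)

    def fun(flat: np.ndarray):
        f, g = functional_and_gradient(flat.reshape(n, 2), table)
        return f, g.ravel()

    res = minimize(fun, X0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter})
    X = res.x.reshape(n, 2)
    f1, _ = functional_and_gradient(X, table)
    info = {
        "objective_initial": f0,
        "objective_final": f1,
        "converged": bool(res.success),
        "n_iterations": int(res.nit),
    }
    return X, info


def assign_hands(vectors: np.ndarray) -> tuple[np.ndarray, dict]:
    """Deterministic 2-means split of the (normalized) vectors into hands.

    Initialization uses the farthest pair of normalized vectors as centres;
    the larger cluster is labelled "A".  Reports the silhouette of the split;
    a value below 0.2 flags an ambiguous separation (report-only).
    """
    X = np.asarray(vectors, float)
    norms = np.linalg.norm(X, axis=1)
    V = np.where(norms[:, None] > 1e-12, X / np.maximum(norms, 1e-12)[:, None], 0.0)
    n = len(V)
    if n < 2:
        return np.array(["A"] * n), {"silhouette": np.nan, "ambiguous": False}
    # farthest-pair initialization
    d2 = ((V[:, None, :] - V[None, :, :]) ** 2).sum(-1)
    a, b = np.unravel_index(np.argmax(d2), d2.shape)
    centers = np.stack([V[a], V[b]])
    labels = np.zeros(n, dtype=int)
    for _ in range(100):
        dist = ((V[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        new = np.argmin(dist, axis=1)
        if np.array_equal(new, labels) and _ > 0:
            break
        labels = new
        for k in (0, 1):
            if np.any(labels == k):
                centers[k] = V[labels == k].mean(axis=0)
    # degenerate split: centres closer than any genuine two-hand separation
    if np.linalg.norm(centers[0] - centers[1]) < 0.1:
        return np.array(["A"] * n), {"silhouette": 0.0, "ambiguous": True}
    # larger cluster is hand A
    if (labels == 1).sum() > (labels == 0).sum():
        labels = 1 - labels
    sil = _silhouette(V, labels)
    hands = np.where(labels == 0, "A", "B")
    return hands, {"silhouette": sil, "ambiguous": bool(sil < 0.2)}


def _silhouette(V: np.ndarray, labels: np.ndarray) -> float:
    if len(set(labels.tolist())) < 2:
        return 0.0
    d = np.sqrt(((V[:, None, :] - V[None, :, :]) ** 2).sum(-1))
    s = []
    for i in range(len(V)):
        own = labels == labels[i]
        own[i] = False
        other = labels != labels[i]
        a = d[i][own].mean() if own.any() else 0.0
        b = d[i][other].mean()
        s.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(s))


def apply_reindexing(images: list[ImageModel], hands: np.ndarray) -> None:
    """Bring all images onto the hand-A convention in place.

    Every hand-B image has its observations mapped through (k,h,-l) and its
    orientation post-multiplied by the operator, keeping geometry consistent.
    """
    from .geometry import REINDEX_OP

    for img, hand in zip(images, hands):
        img.hand = str(hand)
        if hand == "B":
            img.apply_reindex()
            img.orientation = img.orientation.__class__(
                img.orientation.U @ REINDEX_OP.astype(float)
            )
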