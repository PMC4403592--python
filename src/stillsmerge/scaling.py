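"""Two-stage per-image scaling, weak-image rejection and symmetry merging.

Stage one equalizes the mean partiality-corrected intensity of low-resolution
reflections (d >= 3.5 A by default) across images, rejecting images whose
mean falls below a weak-image threshold (333 ADU).  A crude merge of the
equalized images forms an interim reference; stage two then refines each
image's scale as the through-origin regression slope of its intensities
against the reference over shared unique reflections, remerges, and iterates
to convergence.  Scales act as divisors: the fully corrected intensity is
``I_raw / (partiality * scale)`` and sigmas follow identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import UnitCell, map_to_asu, resolution
from .image import ImageModel

__all__ = [
    "MergedDataset",
    "initial_scales",
    "merge",
    "refine_scale_to_reference",
    "iterate_scaling",
    "propagate_sigma",
]


@dataclass
class MergedDataset:
    """Unique-reflection table under the merging symmetry (Laue m-3)."""

    hkl: np.ndarray  # (M, 3) asu indices
    intensity: np.ndarray  # (M,)
    sigma: np.ndarray  # (M,)
    multiplicity: np.ndarray  # (M,) int
    cell: UnitCell = field(default_factory=UnitCell)

    def __len__(self) -> int:
        return len(self.hkl)

    def as_dict(self) -> dict:
        return {tuple(h): i for h, i in zip(map(tuple, self.hkl), self.intensity)}

    def resolution_range(self) -> tuple[float, float]:
        d = resolution(self.hkl, self.cell)
        return float(d.max()), float(d.min())


def initial_scales(
    images: list[ImageModel],
    d_limit: float = 3.5,
    weak_threshold: float = 333.0,
) -> dict:
    """Mean-intensity equalization and weak-image rejection.

    The scale of image ``a`` is ``mean_a / T`` (a divisor), where ``mean_a``
    is its mean corrected intensity at d >= ``d_limit`` and ``T`` the grand
    mean over surviving images, so after division every image's low-
    resolution mean equals ``T``.  Images with ``mean_a`` below the weak
    threshold (or no low-resolution reflections) are flagged rejected.
    """
    means: dict[int, float] = {}
    rejected: dict[int, str] = {}
    for idx, img in enumerate(images):
        hkl, i_corr, _ = img.accepted_subset()
        if len(hkl) == 0:
            rejected[idx] = "no accepted reflections"
            continue
        d = resolution(hkl, img.cell)
        low = i_corr[d >= d_limit]
        if low.size == 0:
            rejected[idx] = f"no reflections at d >= {d_limit} A"
            continue
        m = float(low.mean())
        if m < weak_threshold:
            rejected[idx] = f"weak image: mean {m:.1f} < {weak_threshold} ADU"
            continue
        means[idx] = m
    if not means:
        raise ValueError("all images rejected during initial scaling")
    grand = float(np.mean(list(means.values())))
    for idx, m in means.items():
        images[idx].scale = m / grand
        images[idx].rejected_reason = None
    for idx, reason in rejected.items():
        images[idx].rejected_reason = reason
    return {"grand_mean": grand, "rejected": rejected, "n_scaled": len(means)}


def merge(
    images: list[ImageModel],
    weighting: str = "inverse_variance",
    cell: UnitCell | None = None,
) -> MergedDataset:
    """Group observations by asu index and merge.

    ``weighting="inverse_variance"`` gives the sigma-weighted mean with
    ``sigma = sqrt(1 / sum(w))``; ``weighting="unweighted"`` is the plain
    mean used for the crude interim reference.  Scales are applied as
    divisors here; rejected images are skipped.
    """
    cell = cell or (images[0].cell if images else UnitCell())
    keys, ivals, svals = [], [], []
    for img in images:
        if img.rejected_reason is not None:
            continue
        hkl, i_corr, s_corr = img.accepted_subset()
        if len(hkl) == 0:
            continue
        keys.append(map_to_asu(hkl))
        ivals.append(i_corr / img.scale)
        svals.append(s_corr / img.scale)
    if not keys:
        raise ValueError("nothing to merge")
    K = np.concatenate(keys)
    I = np.concatenate(ivals)
    S = np.concatenate(svals)
    uniq, inverse, counts = np.unique(K, axis=0, return_inverse=True, return_counts=True)
    if weighting == "inverse_variance":
        w = 1.0 / (S * S)
        sw = np.bincount(inverse, weights=w)
        swi = np.bincount(inverse, weights=w * I)
        merged_i = swi / sw
        merged_s = np.sqrt(1.0 / sw)
    elif weighting == "unweighted":
        merged_i = np.bincount(inverse, weights=I) / counts
        ssum = np.bincount(inverse, weights=S * S)
        merged_s = np.sqrt(ssum) / counts
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return MergedDataset(uniq, merged_i, merged_s, counts, cell)


def refine_scale_to_reference(
    image: ImageModel, reference: MergedDataset, min_shared: int = 5
) -> float:
    """Through-origin slope of image intensities against the reference.

    Returns the new scale (a divisor): ``sum(I_img I_ref) / sum(I_ref^2)``
    over shared unique reflections, so the rescaled image matches the
    reference in the least-squares sense.  Raises on insufficient overlap.
    """
    hkl, i_corr, _ = image.accepted_subset()
    if len(hkl) == 0:
        raise ValueError("insufficient overlap: image has no accepted reflections")
    ref = reference.as_dict()
    asu = map_to_asu(hkl)
    pairs = [(i, ref[t]) for i, t in zip(i_corr, map(tuple, asu)) if t in ref]
    if len(pairs) < min_shared:
        raise ValueError(
            f"insufficient overlap: {len(pairs)} shared < minimum {min_shared}"
        )
    img_i, ref_i = np.array(pairs).T
    denom = float(ref_i @ ref_i)
    if denom <= 0:
        raise ValueError("reference intensities degenerate")
    return float(img_i @ ref_i) / denom


def iterate_scaling(
    images: list[ImageModel],
    tol: float = 1e-4,
    max_iter: int = 50,
    min_shared: int = 5,
    reference_weighting: str = "unweighted",
) -> tuple[MergedDataset, dict]:
    """Alternate reference-slope scale refinement and remerging to convergence.

    Convergence: maximum relative scale change below ``tol``.  Images that
    ever lack overlap keep their prior scale (flagged in the report).  The
    interim references use the configured (default crude/unweighted) merge;
    the returned final dataset is inverse-variance weighted.
    """
    trace = []
    flagged: set[int] = set()
    converged = False
    for it in range(max_iter):
        reference = merge(images, weighting=reference_weighting)
        max_change = 0.0
        for idx, img in enumerate(images):
            if img.rejected_reason is not None:
                continue
            try:
                new = refine_scale_to_reference(img, reference, min_shared)
            except ValueError:
                flagged.add(idx)
                continue
            if new <= 0:
                flagged.add(idx)
                continue
            max_change = max(max_change, abs(new - img.scale) / img.scale)
            img.scale = new
        trace.append(max_change)
        if max_change < tol:
            converged = True
            break
    final = merge(images, weighting="inverse_variance")
    report = {
        "converged": converged,
        "n_iterations": len(trace),
        "trace": trace,
        "flagged_no_overlap": sorted(flagged),
    }
    return final, report


def propagate_sigma(sigma_raw: np.ndarray, part: np.ndarray, scale: float) -> np.ndarray:
    """Counting sigma divided by both partiality and scale.

    Without a detector-gain model these absolute sigmas are indicative only;
    the relative error ``sigma/I`` is preserved exactly by the division.
    """
    part = np.asarray(part, float)
    if np.any(part <= 0) or scale <= 0:
        raise ValueError("partiality and scale must be positive")
    return np.asarray(sigma_raw, float) / (part * scale)
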