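"""Data-quality statistics: CC1/2, R_split, R_pim, shells and resolution cutoffs.

All statistics operate on partiality- and scale-corrected observations
grouped by asymmetric-unit index, are invariant under a global intensity
scale, and are reported overall and per equal-volume resolution shell
(equal increments of 1/d^3, so a complete lattice populates shells evenly).

R_split uses the standard still-merging definition with the 1/sqrt(2)
prefactor::

    R_split = (1/sqrt(2)) * sum|I1 - I2| / (0.5 * sum(I1 + I2))

between two independently merged half-datasets (here the two indexing
halves).  CC1/2 splits each unique reflection's observations into two random
balanced halves (seeded shuffle, then even/odd alternation), merges each half
and reports the Pearson correlation of the half-set means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import UnitCell, map_to_asu, resolution
from .image import ImageModel
from .scaling import MergedDataset

__all__ = [
    "ShellTable",
    "shell_binning",
    "cc_half",
    "r_split",
    "r_pim",
    "image_resolution_cutoff",
    "overall_resolution",
    "pooled_observations",
    "shell_statistics",
]


@dataclass
class ShellTable:
    d_high: np.ndarray  # inner (high-resolution) edge of each shell, A
    d_low: np.ndarray  # outer edge, A
    n_unique: np.ndarray
    completeness: np.ndarray  # percent, NaN when reference count unknown
    multiplicity: np.ndarray
    cc_half: np.ndarray
    r_split: np.ndarray  # percent
    r_pim: np.ndarray  # percent
    mean_i_over_sigma: np.ndarray

    def to_text(self) -> str:
        hdr = "d_low\td_high\tn_unique\tcompl_%\tmult\tcc_half\tr_split_%\tr_pim_%\ti_over_sig"
        rows = [hdr]
        for i in range(len(self.d_high)):
            rows.append(
                f"{self.d_low[i]:.3f}\t{self.d_high[i]:.3f}\t{int(self.n_unique[i])}"
                f"\t{self.completeness[i]:.1f}\t{self.multiplicity[i]:.2f}"
                f"\t{self.cc_half[i]:.4f}\t{self.r_split[i]:.2f}\t{self.r_pim[i]:.2f}"
                f"\t{self.mean_i_over_sigma[i]:.2f}"
            )
        return "\n".join(rows) + "\n"


def shell_binning(
    d: np.ndarray, n_shells: int, d_max: float | None = None, d_min: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Assign resolutions to equal-volume shells.

    Shell edges are equally spaced in 1/d^3 between ``d_max`` and ``d_min``
    (defaults: data range).  Returns ``(shell_index, edges_d)`` with shell 0
    the lowest-resolution shell; the lower-d (higher-resolution) edge of each
    shell is inclusive.
    """
    d = np.asarray(d, float)
    if d.size == 0:
        raise ValueError("empty reflection set")
    if n_shells < 1:
        raise ValueError("need at least one shell")
    d_max = d_max if d_max is not None else float(d.max())
    d_min = d_min if d_min is not None else float(d.min())
    s_edges = np.linspace(d_max**-3, d_min**-3, n_shells + 1)
    s = d**-3.0
    idx = np.searchsorted(s_edges, s, side="right") - 1
    idx = np.clip(idx, 0, n_shells - 1)
    edges_d = s_edges ** (-1.0 / 3.0)
    return idx, edges_d


def pooled_observations(images: list[ImageModel]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool accepted, fully corrected observations: (asu_hkl, I, sigma)."""
    keys, ivals, svals = [], [], []
    for img in images:
        if img.rejected_reason is not None:
            continue
        hkl, i_corr, s_corr = img.accepted_subset()
        if len(hkl):
            keys.append(map_to_asu(hkl))
            ivals.append(i_corr / img.scale)
            svals.append(s_corr / img.scale)
    if not keys:
        raise ValueError("no observations")
    return np.concatenate(keys), np.concatenate(ivals), np.concatenate(svals)


def _group(asu: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    uniq, inverse, counts = np.unique(asu, axis=0, return_inverse=True, return_counts=True)
    return uniq, inverse, counts


def cc_half(
    asu: np.ndarray, intensity: np.ndarray, seed: int = 1
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """CC1/2 by random balanced half-splitting of each unique's observations.

    Returns ``(cc_overall, uniq_hkl, half1_mean, half2_mean)``; the half-set
    means are NaN for uniques with multiplicity < 2 and are excluded from the
    correlation.  Per-shell values can be computed from the returned means.
    """
    uniq, inverse, counts = _group(asu)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(asu))
    # stable regroup: observations of each unique in shuffled order
    inv_sh = inverse[order]
    int_sh = intensity[order]
    sort = np.argsort(inv_sh, kind="stable")
    inv_sorted = inv_sh[sort]
    int_sorted = int_sh[sort]
    # position of each observation within its group -> even/odd alternation
    starts = np.r_[0, np.cumsum(counts[:-1])]
    pos = np.arange(len(asu)) - starts[inv_sorted]
    half = pos % 2  # 0 -> half1, 1 -> half2
    sum1 = np.bincount(inv_sorted[half == 0], weights=int_sorted[half == 0], minlength=len(uniq))
    n1 = np.bincount(inv_sorted[half == 0], minlength=len(uniq))
    sum2 = np.bincount(inv_sorted[half == 1], weights=int_sorted[half == 1], minlength=len(uniq))
    n2 = np.bincount(inv_sorted[half == 1], minlength=len(uniq))
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.where(n1 > 0, sum1 / np.maximum(n1, 1), np.nan)
        m2 = np.where(n2 > 0, sum2 / np.maximum(n2, 1), np.nan)
    ok = (n1 > 0) & (n2 > 0)
    cc = _pearson(m1[ok], m2[ok]) if ok.sum() >= 3 else np.nan
    m1[~ok] = np.nan
    m2[~ok] = np.nan
    return cc, uniq, m1, m2


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3:
        return np.nan
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    return float(xc @ yc / den) if den > 0 else np.nan


def r_split(half1: MergedDataset, half2: MergedDataset) -> float:
    """R_split (percent) between two merged half-datasets over shared uniques."""
    d1 = half1.as_dict()
    pairs = [(d1[t], i) for t, i in zip(map(tuple, half2.hkl), half2.intensity) if t in d1]
    if not pairs:
        raise ValueError("halves share no unique reflections")
    i1, i2 = np.array(pairs).T
    return _r_split_arrays(i1, i2)


def _r_split_arrays(i1: np.ndarray, i2: np.ndarray) -> float:
    denom = 0.5 * float((i1 + i2).sum())
    if denom <= 0:
        return np.nan
    return float(100.0 / np.sqrt(2.0) * np.abs(i1 - i2).sum() / denom)


def r_pim(asu: np.ndarray, intensity: np.ndarray) -> float:
    """Precision-indicating merging R factor (percent).

    ``sum_h sqrt(1/(n_h - 1)) sum_i |I_i - <I>| / sum_h sum_i I_i`` over
    uniques with multiplicity >= 2; singletons are excluded from both sums.
    """
    uniq, inverse, counts = _group(asu)
    mean = np.bincount(inverse, weights=intensity) / counts
    dev = np.abs(intensity - mean[inverse])
    multi = counts[inverse] >= 2
    if not multi.any():
        return np.nan
    per_unique_dev = np.bincount(inverse[multi], weights=dev[multi], minlength=len(uniq))
    w = np.where(counts >= 2, 1.0 / np.sqrt(np.maximum(counts - 1, 1)), 0.0)
    numer = float((w * per_unique_dev).sum())
    denom = float(np.bincount(inverse[multi], weights=intensity[multi], minlength=len(uniq)).sum())
    return 100.0 * numer / denom if denom > 0 else np.nan


def image_resolution_cutoff(
    image: ImageModel, n_shells: int = 10, threshold: float = 2.0
) -> float:
    """Per-image resolution limit: last contiguous shell with mean I/sigma >= threshold.

    The image's observations are shelled (equal volume in 1/d^3); scanning
    from low resolution, the cutoff is the high-resolution edge of the last
    shell in the initial run of shells whose mean I/sigma meets the
    threshold.  Raises if even the first shell fails (image fully rejected).
    """
    if image.n_obs == 0:
        raise ValueError("image has no observations")
    d = resolution(image.hkl, image.cell)
    isig = image.i_raw / image.sigma_raw
    idx, edges = shell_binning(d, n_shells)
    cutoff = None
    for s in range(n_shells):
        m = idx == s
        if not m.any():
            continue
        if float(isig[m].mean()) >= threshold:
            cutoff = float(edges[s + 1])
        else:
            break
    if cutoff is None:
        raise ValueError("no shell reaches the I/sigma threshold; image rejected")
    return cutoff


def overall_resolution(
    shell_d_high: np.ndarray, shell_cc: np.ndarray, threshold: float = 0.30
) -> float | None:
    """Nominal resolution: d of the first shell (from low res) with CC1/2 < threshold.

    Returns None ("beyond range") when CC1/2 never crosses the threshold.
    Reported only; data are not truncated by default.
    """
    for d, cc in zip(shell_d_high, shell_cc):
        if np.isfinite(cc) and cc < threshold:
            return float(d)
    return None


def shell_statistics(
    asu: np.ndarray,
    intensity: np.ndarray,
    sigma: np.ndarray,
    cell: UnitCell,
    n_shells: int = 20,
    seed: int = 1,
    n_theoretical: np.ndarray | None = None,
    theoretical_d: np.ndarray | None = None,
) -> ShellTable:
    """Per-shell table of all quality metrics for pooled observations."""
    uniq, inverse, counts = _group(asu)
    d_unique = resolution(uniq, cell)
    idx_u, edges = shell_binning(d_unique, n_shells)
    # shell index of each observation = shell of its unique
    idx_obs = idx_u[inverse]

    _, uniq_all, m1, m2 = cc_half(asu, intensity, seed=seed)

    # optional completeness reference: theoretical uniques binned on same edges
    th_counts = None
    if theoretical_d is not None:
        s_edges = np.linspace(edges[0] ** -3, edges[-1] ** -3, n_shells + 1)
        s = np.asarray(theoretical_d, float) ** -3.0
        ti = np.clip(np.searchsorted(s_edges, s, side="right") - 1, 0, n_shells - 1)
        th_counts = np.bincount(ti, minlength=n_shells)

    rows = {k: np.full(n_shells, np.nan) for k in
            ("cc", "rsplit", "rpim", "isig", "mult", "compl")}
    n_unique_shell = np.zeros(n_shells, dtype=int)
    for s in range(n_shells):
        mu_ = idx_u == s
        mo = idx_obs == s
        n_unique_shell[s] = int(mu_.sum())
        if not mo.any():
            continue
        rows["mult"][s] = counts[mu_].mean() if mu_.any() else np.nan
        rows["isig"][s] = float((intensity[mo] / sigma[mo]).mean())
        rows["rpim"][s] = r_pim(asu[mo], intensity[mo])
        ok = mu_ & np.isfinite(m1) & np.isfinite(m2)
        if ok.sum() >= 3:
            rows["cc"][s] = _pearson(m1[ok], m2[ok])
            rows["rsplit"][s] = _r_split_arrays(m1[ok], m2[ok])
        if th_counts is not None and th_counts[s] > 0:
            rows["compl"][s] = 100.0 * n_unique_shell[s] / th_counts[s]
    return ShellTable(
        d_high=edges[1:],
        d_low=edges[:-1],
        n_unique=n_unique_shell,
        completeness=rows["compl"],
        multiplicity=rows["mult"],
        cc_half=rows["cc"],
        r_split=rows["rsplit"],
        r_pim=rows["rpim"],
        mean_i_over_sigma=rows["isig"],
    )
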