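"""Reflection prediction and per-still orientation refinement.

Prediction casts a deliberately wide "net": every lattice-allowed reflection
whose excitation wavelength falls within an inflated bandwidth (default
+-3.5% of the nominal mean) is a candidate, with rlps treated as delta
functions.  Strong candidates ("hits", integrated intensity above an ADU
threshold) drive orientation refinement: each still's orientation matrix is
rotated about the two beam-orthogonal axes to sharpen the histogram of
excitation wavelengths of its hits, on a halving grid from 0.5 degrees down
to 0.001 degrees.  The search target starts as (wavelength spread)/(hit
count) over the whole net window and, after the step has been halved three
times, switches to a target tied to the Gaussian model of the spectrum: the
spread/count of the sample trimmed to the fitted Gaussian peak, which
rewards a sharp, well-populated core rather than the pedestal of marginally
excited reflections.  The per-pulse mean wavelength is re-estimated as the
fitted Gaussian peak position after every halving.

A rotation about the beam axis changes no excitation wavelength (it preserves
both q_z and |q|), which is why only the two orthogonal axes are refined.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .geometry import (
    BeamSpectrum,
    Orientation,
    UnitCell,
    excitation_wavelength,
    is_lattice_allowed,
    rotation_about_axis,
)
from .image import ImageModel

__all__ = [
    "RefinementReport",
    "predict_candidates",
    "select_hits",
    "wavelength_histogram",
    "refine_orientation",
    "derive_beam_sigma",
    "candidate_hkl_sphere",
]


@dataclass
class RefinementReport:
    rotation_applied: tuple[float, float]  # degrees about lab x and y
    combined_angle: float  # degrees
    histogram_sd_before: float
    histogram_sd_after: float
    n_halvings: int
    n_evaluations: int
    success: bool


@lru_cache(maxsize=8)
def _hkl_box(a: float, d_min: float) -> np.ndarray:
    """All lattice-allowed hkl (excluding 000) with d >= d_min, as (N, 3) int."""
    hmax = int(np.floor(a / d_min))
    rng = np.arange(-hmax, hmax + 1)
    H, K, L = np.meshgrid(rng, rng, rng, indexing="ij")
    hkl = np.stack([H.ravel(), K.ravel(), L.ravel()], axis=1)
    n2 = np.einsum("ij,ij->i", hkl, hkl)
    keep = (n2 > 0) & (n2 <= (a / d_min) ** 2) & is_lattice_allowed(hkl)
    return hkl[keep]


def candidate_hkl_sphere(cell: UnitCell, d_min: float) -> np.ndarray:
    """Lattice-allowed index sphere to resolution ``d_min`` (cached)."""
    return _hkl_box(cell.a, d_min)


def predict_candidates(
    orientation: Orientation,
    cell: UnitCell,
    mu: float,
    net_fraction: float = 0.035,
    d_min: float = 2.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate reflections under the inflated-bandwidth net.

    Returns ``(hkl, lambda_exc)`` for every lattice-allowed reflection whose
    excitation wavelength lies in ``[mu (1 - net), mu (1 + net)]`` and whose
    resolution is at least ``d_min``.  Rlps are delta functions here.
    """
    if net_fraction < 0:
        raise ValueError("net_fraction must be non-negative")
    hkl = candidate_hkl_sphere(cell, d_min)
    q = (hkl.astype(float) @ orientation.U.T) / cell.a
    lam = excitation_wavelength(q)
    keep = np.isfinite(lam) & (lam >= mu * (1 - net_fraction)) & (lam <= mu * (1 + net_fraction))
    return hkl[keep], lam[keep]


def select_hits(
    hkl: np.ndarray, intensities: np.ndarray, threshold: float = 150.0
) -> np.ndarray:
    """Boolean mask of strong candidates: intensity strictly above ``threshold`` ADU."""
    return np.asarray(intensities, float) > threshold


def wavelength_histogram(
    lams: np.ndarray,
    mu: float,
    net_fraction: float = 0.035,
    bin_fraction: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Histogram of excitation wavelengths over the net window.

    Fixed bin width ``mu * bin_fraction`` over ``[mu(1-net), mu(1+net)]``;
    returns ``(counts, bin_centers, sample_mean, sample_sd)`` of the in-window
    wavelengths.  Raises on fewer than two in-window values (no s.d.).
    """
    lams = np.asarray(lams, float)
    lo, hi = mu * (1 - net_fraction), mu * (1 + net_fraction)
    inside = lams[(lams >= lo) & (lams <= hi)]
    if inside.size < 2:
        raise ValueError("insufficient hits for a wavelength histogram")
    width = mu * bin_fraction
    n_bins = max(1, int(np.ceil((hi - lo) / width)))
    counts, edges = np.histogram(inside, bins=n_bins, range=(lo, lo + n_bins * width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers, float(inside.mean()), float(inside.std(ddof=1))


def _gaussian_fit_residual(
    counts: np.ndarray, centers: np.ndarray, half_window_bins: int = 8
) -> tuple[float, float]:
    """Least-squares Gaussian fit to the histogram peak.

    The excitation-wavelength histogram is a sharp core (well-excited
    reflections) on a broad pedestal of marginally excited ones, so the fit
    is restricted to ``half_window_bins`` either side of the modal bin.
    Returns ``(normalized residual SSR, fitted mean)``; failures score inf.
    """
    from scipy.optimize import curve_fit

    if counts.sum() < 2:
        return np.inf, np.nan
    j = int(np.argmax(counts))
    sl = slice(max(0, j - half_window_bins), j + half_window_bins + 1)
    c, x = counts[sl].astype(float), centers[sl]
    if c.sum() < 2 or len(c) < 4:
        return np.inf, np.nan
    p0 = [float(c.max()), float(x[np.argmax(c)]), 2.0 * (x[1] - x[0])]

    def gauss(xx, A, m, s):
        return A * np.exp(-0.5 * ((xx - m) / s) ** 2)

    try:
        popt, _ = curve_fit(gauss, x, c, p0=p0, maxfev=2000)
    except (RuntimeError, ValueError):
        return np.inf, np.nan
    r = c - gauss(x, *popt)
    return float((r @ r) / (c @ c)), float(popt[1])


class _Objective:
    """Refinement target for one still, evaluated at trial rotations."""

    def __init__(
        self,
        hkl: np.ndarray,
        U0: np.ndarray,
        cell: UnitCell,
        net_fraction: float,
        bin_fraction: float,
        min_hits: int,
    ) -> None:
        self.hkl = hkl.astype(float)
        self.U0 = U0
        self.a = cell.a
        self.net = net_fraction
        self.bin_fraction = bin_fraction
        self.min_hits = min_hits
        self.stage = 1
        self.mu = np.nan
        self.core_bins = 6  # half-width, in histogram bins, of the peak core

    def lambdas(self, alpha: float, beta: float) -> np.ndarray:
        R = rotation_about_axis(0, alpha) @ rotation_about_axis(1, beta)
        q = (self.hkl @ (R @ self.U0).T) / self.a
        return excitation_wavelength(q)

    def __call__(self, alpha: float, beta: float) -> float:
        lam = self.lambdas(alpha, beta)
        lo, hi = self.mu * (1 - self.net), self.mu * (1 + self.net)
        inside = lam[np.isfinite(lam) & (lam >= lo) & (lam <= hi)]
        if inside.size < max(2, self.min_hits):
            return np.inf
        if self.stage == 1:
            return float(inside.std(ddof=1) / inside.size)
        # stage 2: quality of the Gaussian core of the distribution — the
        # spread/count of the sample trimmed to a fixed window around the
        # fitted peak (robust to the pedestal of marginally excited spots)
        w = self.mu * self.bin_fraction
        core = inside[np.abs(inside - self.mu) <= self.core_bins * w]
        if core.size < 5:
            return np.inf
        return float(core.std(ddof=1) / core.size)

    def refit_mu(self, alpha: float, beta: float) -> None:
        """Update the mean-wavelength estimate from the fitted Gaussian peak."""
        lam = self.lambdas(alpha, beta)
        lo, hi = self.mu * (1 - self.net), self.mu * (1 + self.net)
        inside = lam[np.isfinite(lam) & (lam >= lo) & (lam <= hi)]
        if inside.size < 2:
            return
        counts, centers, mean, _ = wavelength_histogram(
            inside, self.mu, self.net, self.bin_fraction
        )
        _, fitted = _gaussian_fit_residual(counts, centers)
        # accept the fitted peak only if it stays inside the net window
        if np.isfinite(fitted) and lo <= fitted <= hi:
            self.mu = float(fitted)
        else:
            self.mu = float(mean)


def refine_orientation(
    image: ImageModel,
    cell: UnitCell | None = None,
    hit_threshold: float = 150.0,
    net_fraction: float = 0.035,
    bin_fraction: float = 1e-3,
    step_start: float = 0.5,
    step_stop: float = 0.001,
    halvings_before_switch: int = 3,
    min_hits: int = 10,
) -> tuple[Orientation, float, RefinementReport]:
    """Refine one still's orientation and mean wavelength.

    Coordinate-descent on a halving grid over rotations about the lab x and y
    axes.  From the current point the four single-axis neighbours at the
    current step are evaluated; a strict improvement moves the point (ties
    favour the smaller-magnitude rotation), otherwise the point is a local
    minimum and the step is halved.  After ``halvings_before_switch``
    halvings the target switches from whole-window spread/count to the
    Gaussian-core form, and the mean-wavelength estimate is refit (Gaussian
    peak fit) after every halving.  Terminates when the step drops below
    ``step_stop`` degrees.
    """
    cell = cell or image.cell
    hits = select_hits(image.hkl, image.i_raw, hit_threshold)
    if hits.sum() < min_hits:
        raise ValueError(
            f"refinement degenerate: {int(hits.sum())} hits < minimum {min_hits}"
        )
    obj = _Objective(image.hkl[hits], image.orientation.U, cell, net_fraction,
                     bin_fraction, min_hits)
    obj.mu = image.mu_estimate

    lam0 = obj.lambdas(0.0, 0.0)
    lo, hi = obj.mu * (1 - net_fraction), obj.mu * (1 + net_fraction)
    in0 = lam0[np.isfinite(lam0) & (lam0 >= lo) & (lam0 <= hi)]
    sd_before = float(in0.std(ddof=1)) if in0.size >= 2 else np.nan

    alpha = beta = 0.0
    step = step_start
    halvings = 0
    n_eval = 0
    cache: dict[tuple[int, float, float], float] = {}

    def ev(a: float, b: float) -> float:
        nonlocal n_eval
        key = (obj.stage, round(a, 9), round(b, 9))
        if key not in cache:
            cache[key] = obj(a, b)
            n_eval += 1
        return cache[key]

    while step >= step_stop:
        here = ev(alpha, beta)
        trials = [
            (alpha + step, beta), (alpha - step, beta),
            (alpha, beta + step), (alpha, beta - step),
        ]
        vals = [ev(a, b) for a, b in trials]
        best = int(np.argmin(vals))
        # strict improvement moves; ties keep the smaller-magnitude rotation
        improved = vals[best] < here or (
            vals[best] == here
            and np.hypot(*trials[best]) < np.hypot(alpha, beta)
        )
        if improved:
            alpha, beta = trials[best]
        else:
            step /= 2.0
            halvings += 1
            obj.refit_mu(alpha, beta)
            if halvings == halvings_before_switch:
                obj.stage = 2
            cache.clear()

    lam1 = obj.lambdas(alpha, beta)
    lo, hi = obj.mu * (1 - net_fraction), obj.mu * (1 + net_fraction)
    in1 = lam1[np.isfinite(lam1) & (lam1 >= lo) & (lam1 <= hi)]
    sd_after = float(in1.std(ddof=1)) if in1.size >= 2 else np.nan
    success = np.isfinite(sd_after) and (not np.isfinite(sd_before) or sd_after <= sd_before)

    R = rotation_about_axis(0, alpha) @ rotation_about_axis(1, beta)
    combined = float(np.rad2deg(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1))))
    report = RefinementReport(
        rotation_applied=(alpha, beta),
        combined_angle=combined,
        histogram_sd_before=sd_before,
        histogram_sd_after=sd_after,
        n_halvings=halvings,
        n_evaluations=n_eval,
        success=success,
    )
    return image.orientation.rotated(R), obj.mu, report


def derive_beam_sigma(fitted_sd: float, factor: float = 0.27) -> float:
    """Beam-bandwidth s.d. from a fitted histogram s.d.

    The histogram width folds in bandwidth, mosaicity and crystal-size
    broadening; multiplying by the deconvolution factor (default 0.27)
    recovers the bandwidth component alone.
    """
    if fitted_sd <= 0:
        raise ValueError("fitted s.d. must be positive")
    return factor * fitted_sd
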