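"""Reflection partiality for still diffraction with a polychromatic SASE pulse.

A reciprocal-lattice point (rlp) is modelled as a spherical top-hat of radius
``r = r0 + |q| sin(eta)`` (base size from the crystal dimensions plus a
mosaicity term that grows with resolution).  The pulse spectrum is a Gaussian
in wavelength, truncated at +-2 s.d.; each wavelength in ``[l, h]`` defines an
Ewald sphere, and the nest of spheres sweeps a slab through the rlp.

Partiality is the spectral energy the rlp intercepts relative to the maximum
possible — a central cut spanning the whole truncated spectrum.  Each Ewald
sphere cuts the rlp in a disc; with the disc area referenced to the central
section (the cylindrical approximation, cylinder base in the Ewald tangent
plane), the slice at fraction ``x`` along the rlp diameter carries relative
area ``4 x (1 - x)``.  The wavelength exciting fraction ``x`` varies linearly
between the limiting values, so

    P = [ integral over lam in [l, h], 0 <= x(lam) <= 1 of
          4 x(lam) (1 - x(lam)) G(lam; mu, sigma) dlam ]
        / integral over [l, h] of G(lam; mu, sigma) dlam,

with ``x(lam)`` linear through the points ``(l, p)`` and ``(h, q)`` where the
two limiting spheres intersect the diameter.  The quadratic-times-Gaussian
integral has a closed form in ``erf``/``exp``, evaluated here; an independent
fine-quadrature oracle of the same geometric model lives in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .geometry import BeamSpectrum

__all__ = [
    "RlpSphere",
    "PartialityGeometry",
    "limiting_wavelengths",
    "intersection_fractions",
    "partiality",
    "partiality_for_vectors",
    "correct_observation",
]

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class RlpSphere:
    """Finite rlp extent: base radius (1/A) plus resolution-dependent mosaic term."""

    base_radius: float = 1.8e-4
    mosaicity_deg: float = 0.03

    def radius(self, q_norm: np.ndarray) -> np.ndarray:
        """Effective radius r(q) = r0 + |q| sin(eta) in 1/A."""
        return self.base_radius + np.asarray(q_norm) * np.sin(np.deg2rad(self.mosaicity_deg))


@dataclass(frozen=True)
class PartialityGeometry:
    """Fractions along the rlp diameter cut by the limiting Ewald spheres.

    ``p``/``q`` are clipped to [0, 1] and ordered; ``p_raw``/``q_raw`` keep the
    unclipped fractions of the l- and h-sphere respectively, which fix the
    linear wavelength-vs-fraction map used by the partiality integral.
    """

    p: float
    q: float
    p_raw: float
    q_raw: float
    low: float
    high: float


def limiting_wavelengths(beam: BeamSpectrum) -> tuple[float, float]:
    """Wavelengths of the limiting Ewald spheres: (mu - 2 sigma, mu + 2 sigma)."""
    return beam.low, beam.high


def _signed_sphere_distance(centers: np.ndarray, lam: float) -> np.ndarray:
    """Signed distance from rlp centre(s) to the Ewald sphere of wavelength lam.

    Positive outside the sphere.  Sphere centre (0,0,-1/lam), radius 1/lam.
    """
    c = np.atleast_2d(centers).astype(float).copy()
    c[:, 2] += 1.0 / lam
    return np.sqrt(np.einsum("ij,ij->i", c, c)) - 1.0 / lam


def _fractions(centers: np.ndarray, radius: np.ndarray, lam: float) -> np.ndarray:
    """Fraction along the diameter (0 = outer edge ... 1) cut by sphere ``lam``."""
    t = _signed_sphere_distance(centers, lam)
    return (radius - t) / (2.0 * radius)


def intersection_fractions(
    rlp_center: np.ndarray, radius: float, low: float, high: float
) -> PartialityGeometry:
    """Where the two limiting Ewald spheres cut the rlp diameter.

    A fraction of 0.5 means the sphere passes centrally; values are clipped to
    [0, 1] for the reported (p, q) so fully-inside/outside cases degenerate to
    (0, 1), (0, 0) or (1, 1).
    """
    if radius <= 0:
        raise ValueError("rlp radius must be positive")
    c = np.asarray(rlp_center, float).reshape(1, 3)
    r = np.asarray([radius], float)
    f_low = float(_fractions(c, r, low)[0])
    f_high = float(_fractions(c, r, high)[0])
    p, q = sorted((min(max(f_low, 0.0), 1.0), min(max(f_high, 0.0), 1.0)))
    return PartialityGeometry(p=p, q=q, p_raw=f_low, q_raw=f_high, low=low, high=high)


def _gauss_moments(a: np.ndarray, b: np.ndarray, mu: float, sigma: float):
    """(m0, m1, m2): integrals of lam^k * N(lam; mu, sigma) over [a, b]."""
    za = (a - mu) / (_SQRT2 * sigma)
    zb = (b - mu) / (_SQRT2 * sigma)
    phi_a = np.exp(-za * za) / np.sqrt(2.0 * np.pi) / sigma
    phi_b = np.exp(-zb * zb) / np.sqrt(2.0 * np.pi) / sigma
    m0 = 0.5 * (erf(zb) - erf(za))
    m1 = mu * m0 + sigma * sigma * (phi_a - phi_b)
    m2 = (
        (mu * mu + sigma * sigma) * m0
        + sigma * sigma * ((a + mu) * phi_a - (b + mu) * phi_b)
    )
    return m0, m1, m2


def partiality(geom: PartialityGeometry, radius: float, beam: BeamSpectrum) -> float:
    """Partiality of one reflection from its limiting-sphere geometry."""
    p_raw = np.asarray([geom.p_raw])
    q_raw = np.asarray([geom.q_raw])
    return float(_partiality_from_fractions(p_raw, q_raw, beam)[0])


def _partiality_from_fractions(
    f_low: np.ndarray, f_high: np.ndarray, beam: BeamSpectrum
) -> np.ndarray:
    """Vectorized closed-form evaluation of the partiality integral.

    ``f_low``/``f_high`` are the unclipped diameter fractions cut by the l- and
    h-sphere; the fraction excited at wavelength lam is linear through
    (l, f_low) and (h, f_high).
    """
    mu, sigma = beam.mu, beam.sigma
    low, high = beam.low, beam.high
    span = high - low

    slope = (f_high - f_low) / span  # dx/dlam
    out = np.zeros_like(f_low, dtype=float)
    ok = np.abs(slope) > 0
    # wavelengths at which x crosses 0 and 1
    with np.errstate(divide="ignore", invalid="ignore"):
        lam0 = low + (0.0 - f_low) / slope
        lam1 = low + (1.0 - f_low) / slope
    lo = np.maximum(np.minimum(lam0, lam1), low)
    hi = np.minimum(np.maximum(lam0, lam1), high)
    ok &= hi > lo
    if not np.any(ok):
        return out

    a, b = lo[ok], hi[ok]
    s, f0 = slope[ok], f_low[ok]
    m0, m1, m2 = _gauss_moments(a, b, mu, sigma)
    # x(lam) = alpha + s lam;  integrand 4 x (1 - x)
    alpha = f0 - s * low
    # 4 x (1-x) = 4[alpha + s lam] - 4[alpha + s lam]^2
    i0 = 4.0 * alpha - 4.0 * alpha * alpha
    i1 = 4.0 * s - 8.0 * alpha * s
    i2 = -4.0 * s * s
    numer = i0 * m0 + i1 * m1 + i2 * m2
    denom = 0.5 * (erf((high - mu) / (_SQRT2 * sigma)) - erf((low - mu) / (_SQRT2 * sigma)))
    vals = numer / denom
    out[ok] = np.clip(vals, 0.0, 1.0)
    return out


def partiality_for_vectors(
    q_vectors: np.ndarray, rlp: RlpSphere, beam: BeamSpectrum
) -> np.ndarray:
    """Partiality for an (N, 3) array of lab-frame reciprocal vectors."""
    q = np.atleast_2d(np.asarray(q_vectors, float))
    qn = np.sqrt(np.einsum("ij,ij->i", q, q))
    radius = rlp.radius(qn)
    f_low = _fractions(q, radius, beam.low)
    f_high = _fractions(q, radius, beam.high)
    return _partiality_from_fractions(f_low, f_high, beam)


def correct_observation(
    i_raw: float, sigma_raw: float, part: float, cutoff: float = 0.3
) -> tuple[float, float] | None:
    """Divide intensity and sigma by partiality; reject partiality <= cutoff.

    Returns ``(i_corr, sigma_corr)`` or ``None`` for rejected reflections.
    The per-image scale division is applied later, at scaling/merging time.
    """
    if part <= cutoff:
        return None
    return i_raw / part, sigma_raw / part
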