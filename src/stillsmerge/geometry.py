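"""Unit-cell and orientation algebra, Ewald-sphere geometry and I23 symmetry.

Conventions shared by every module:

* the incident beam travels along **+z** in the lab frame;
* the Ewald sphere for wavelength ``lam`` has centre ``(0, 0, -1/lam)`` and
  radius ``1/lam``, so a reciprocal vector ``q`` diffracts exactly when
  ``|q + (0, 0, 1/lam)| = 1/lam``, i.e. ``lam = -2 q_z / |q|^2``;
* Miller indices are stored signed and unreduced per observation; reduction
  to the asymmetric unit happens only when merging or correlating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "Orientation",
    "BeamSpectrum",
    "rlp_vector",
    "excitation_wavelength",
    "resolution",
    "map_to_asu",
    "reindex",
    "is_lattice_allowed",
    "point_group_rotations",
]

#: reindexing operator of the I23 two-fold lattice ambiguity: (h,k,l) -> (k,h,-l)
REINDEX_OP = np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]], dtype=int)


@dataclass(frozen=True)
class UnitCell:
    """Cubic unit cell (space group I23: body centred, point group 23)."""

    a: float = 106.1
    space_group: str = "I 2 3"

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"cell edge must be positive, got {self.a}")

    @property
    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.a, self.a, 90.0, 90.0, 90.0)


@dataclass(frozen=True)
class Orientation:
    """Proper rotation ``U`` mapping crystal reciprocal axes into the lab frame."""

    U: np.ndarray

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        object.__setattr__(self, "U", U)
        if U.shape != (3, 3):
            raise ValueError("orientation must be a 3x3 matrix")
        if not np.allclose(U @ U.T, np.eye(3), atol=1e-10):
            raise ValueError("orientation matrix is not orthonormal")
        if np.linalg.det(U) < 0:
            raise ValueError("orientation matrix must be a proper rotation")

    @staticmethod
    def identity() -> "Orientation":
        return Orientation(np.eye(3))

    def rotated(self, R: np.ndarray) -> "Orientation":
        """Return this orientation pre-rotated by lab-frame rotation ``R``."""
        return Orientation(np.asarray(R, float) @ self.U)


@dataclass(frozen=True)
class BeamSpectrum:
    """Gaussian per-pulse wavelength distribution, truncated at +-2 s.d.

    ``mu`` and ``sigma`` are in Angstrom.  The spectral weight is exactly zero
    outside ``[mu - 2 sigma, mu + 2 sigma]``; those truncation points are the
    limiting Ewald spheres of the partiality model.  ``deconvolution_factor``
    converts the s.d. of a fitted excitation-wavelength histogram (which folds
    in mosaicity and crystal-size broadening) into the beam bandwidth proper.
    """

    mu: float = 1.46
    sigma: float = 0.0015
    deconvolution_factor: float = 0.27

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.sigma <= 0:
            raise ValueError("mu and sigma must be positive")

    @property
    def low(self) -> float:
        """Lower limiting wavelength l = mu - 2 sigma."""
        return self.mu - 2.0 * self.sigma

    @property
    def high(self) -> float:
        """Upper limiting wavelength h = mu + 2 sigma."""
        return self.mu + 2.0 * self.sigma

    def with_mu(self, mu: float) -> "BeamSpectrum":
        return BeamSpectrum(mu, self.sigma, self.deconvolution_factor)


def rlp_vector(hkl: np.ndarray, cell: UnitCell, orientation: Orientation) -> np.ndarray:
    """Lab-frame reciprocal vector(s) q (1/A) for Miller indices ``hkl``.

    Accepts a single triple or an (N, 3) array.  For a cubic cell the setting
    matrix is ``U / a``, so ``|q| = sqrt(h^2+k^2+l^2) / a = 1/d``.
    """
    h = np.asarray(hkl, dtype=float)
    return (h @ orientation.U.T) / cell.a


def excitation_wavelength(q: np.ndarray) -> np.ndarray:
    """Wavelength(s) at which reciprocal vector(s) ``q`` sit on the Ewald sphere.

    Solves ``|q + (0,0,1/lam)| = 1/lam`` for ``lam``, giving
    ``lam = -2 q_z / |q|^2``.  Vectors in the wrong hemisphere (``q_z >= 0``)
    or at the origin are unexcitable and return NaN.
    """
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    q2 = np.atleast_2d(q)
    norm2 = np.einsum("ij,ij->i", q2, q2)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = -2.0 * q2[:, 2] / norm2
    lam = np.where((q2[:, 2] < 0) & (norm2 > 0) & (lam > 0), lam, np.nan)
    return float(lam[0]) if single else lam


def resolution(hkl: np.ndarray, cell: UnitCell) -> np.ndarray:
    """Resolution d (A) of reflections in a cubic cell: ``d = a / |hkl|``."""
    h = np.asarray(hkl, dtype=float)
    single = h.ndim == 1
    h2 = np.atleast_2d(h)
    n = np.sqrt(np.einsum("ij,ij->i", h2, h2))
    if np.any(n == 0):
        raise ValueError("resolution of (0,0,0) is undefined")
    d = cell.a / n
    return float(d[0]) if single else d


def _laue_rotations() -> np.ndarray:
    """The 24 hkl-space ops of Laue group m-3: 12 rotations of 23 x Friedel."""
    sg = gemmi.SpaceGroup("I 2 3")
    mats = []
    seen = set()
    for op in sg.operations():
        R = np.array(op.rot, dtype=int) // op.DEN
        key = R.tobytes()
        if key not in seen:
            seen.add(key)
            mats.append(R)
    rots = np.array(mats)  # (12, 3, 3)
    return np.concatenate([rots, -rots])


_LAUE_OPS = _laue_rotations()


def point_group_rotations() -> np.ndarray:
    """The 12 proper rotations of point group 23 acting on hkl."""
    return _LAUE_OPS[:12].copy()


def map_to_asu(hkl: np.ndarray) -> np.ndarray:
    """Canonical representative of each hkl orbit under the merging symmetry.

    Merging symmetry is point group 23 with Friedel mates merged (Laue m-3).
    The representative is the lexicographically greatest (h, k, l) in the
    24-member orbit; the map is idempotent by construction.
    """
    h = np.asarray(hkl, dtype=int)
    single = h.ndim == 1
    h2 = np.atleast_2d(h)
    # orbit[k] has shape (N, 3): image of every input under op k
    orbit = np.einsum("kij,nj->kni", _LAUE_OPS, h2)
    m = int(np.abs(h2).max(initial=0)) + 1
    base = 2 * m + 1
    keys = ((orbit[..., 0] + m) * base + (orbit[..., 1] + m)) * base + (orbit[..., 2] + m)
    best = np.argmax(keys, axis=0)
    out = orbit[best, np.arange(h2.shape[0])]
    return out[0] if single else out


def reindex(hkl: np.ndarray) -> np.ndarray:
    """Apply the ambiguity operator (h,k,l) -> (k,h,-l).  Involution."""
    h = np.asarray(hkl, dtype=int)
    return h @ REINDEX_OP.T


def is_lattice_allowed(hkl: np.ndarray) -> np.ndarray:
    """I-centring rule: reflection present iff h + k + l is even."""
    h = np.asarray(hkl, dtype=int)
    s = h.sum(axis=-1)
    return s % 2 == 0


def rotation_about_axis(axis: int, angle_deg: float) -> np.ndarray:
    """Rotation matrix about lab axis 0=x, 1=y, 2=z by ``angle_deg`` degrees."""
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    R = np.eye(3)
    i, j = [(1, 2), (2, 0), (0, 1)][axis]
    R[i, i] = c
    R[j, j] = c
    R[i, j] = -s
    R[j, i] = s
    return R
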