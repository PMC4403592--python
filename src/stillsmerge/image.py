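"""Per-still container: orientation, observations and their corrections.

Observations are stored column-wise (one numpy array per field) for speed;
``n_obs`` rows share a common order across all arrays.  ``i_corr``/
``sigma_corr`` are NaN until the partiality correction has been applied, and
``accepted`` marks reflections that survived the partiality cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BeamSpectrum, Orientation, UnitCell, reindex, rlp_vector

__all__ = ["ImageModel"]


@dataclass
class ImageModel:
    image_id: int
    orientation: Orientation
    mu_estimate: float
    hkl: np.ndarray  # (N, 3) int
    i_raw: np.ndarray  # (N,) ADU
    sigma_raw: np.ndarray  # (N,) ADU
    cell: UnitCell = field(default_factory=UnitCell)
    scale: float = 1.0
    hand: str = "unassigned"
    lambda_exc: np.ndarray | None = None
    partiality: np.ndarray | None = None
    i_corr: np.ndarray | None = None
    sigma_corr: np.ndarray | None = None
    accepted: np.ndarray | None = None
    rejected_reason: str | None = None

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.i_raw = np.asarray(self.i_raw, dtype=float)
        self.sigma_raw = np.asarray(self.sigma_raw, dtype=float)
        if len(self.i_raw) != len(self.hkl) or len(self.sigma_raw) != len(self.hkl):
            raise ValueError("observation columns must have equal length")
        if np.any(self.sigma_raw <= 0):
            raise ValueError("counting sigmas must be positive")
        if self.scale <= 0:
            raise ValueError("image scale must be positive")
        # uniqueness of hkl within one image
        if len(self.hkl) and len(np.unique(self.hkl, axis=0)) != len(self.hkl):
            raise ValueError("duplicate hkl on a single image")

    @property
    def n_obs(self) -> int:
        return len(self.hkl)

    def q_vectors(self) -> np.ndarray:
        """Lab-frame reciprocal vectors of all observations (N, 3)."""
        return rlp_vector(self.hkl, self.cell, self.orientation)

    def beam(self, sigma: float, factor: float = 0.27) -> BeamSpectrum:
        """Beam spectrum at this image's refined mean wavelength."""
        return BeamSpectrum(self.mu_estimate, sigma, factor)

    def apply_reindex(self) -> None:
        """Map every observation's hkl through (h,k,l) -> (k,h,-l) in place."""
        self.hkl = reindex(self.hkl)

    def accepted_subset(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(hkl, i_corr, sigma_corr) of partiality-accepted observations."""
        if self.accepted is None or self.i_corr is None:
            raise ValueError("partiality correction has not been applied")
        m = self.accepted
        return self.hkl[m], self.i_corr[m], self.sigma_corr[m]
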