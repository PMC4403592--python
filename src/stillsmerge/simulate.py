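"""Synthetic SFX still-diffraction generator with full ground truth.

The generator emulates the experimental regime the pipeline targets: cubic
I23 crystals (a = 106.1 A), SASE pulses near 1.46 A with a narrow truncated-
Gaussian bandwidth, rlp radius 1.8e-4 1/A plus a 0.03-degree mosaicity term,
thousands of randomly oriented stills, half of them indexed by the alternate
(k, h, -l) convention, and per-image lognormal scale variation.

Forward model per still: draw a uniform random orientation, a jittered mean
wavelength and a lognormal scale; every lattice-allowed reflection whose rlp
partiality (under the same model the pipeline inverts) exceeds a floor and
whose central excitation wavelength lies inside the truncated spectrum is
emitted with

    I_raw = scale_true * partiality_true * I_true + noise,

where I_true are exponential (acentric Wilson) intensities per asymmetric-
unit reflection and the noise is Gaussian with a counting-statistics sigma
``sqrt(I + floor)`` (detector gain 1), optionally inflated to reach a target
mean I/sigma.  Alternate-hand stills are emitted with reindexed Miller
indices and the compensating orientation matrix, so they are geometrically
self-consistent and indistinguishable from the primary hand — exactly the
ambiguity the pipeline must resolve.  Ground truth (intensities, scales,
orientations, hands, injected missets, true partialities) is retained for
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    BeamSpectrum,
    Orientation,
    REINDEX_OP,
    UnitCell,
    excitation_wavelength,
    map_to_asu,
    rotation_about_axis,
)
from .image import ImageModel
from .partiality import RlpSphere, partiality_for_vectors
from .prediction import candidate_hkl_sphere

__all__ = ["GroundTruth", "SimulationConfig", "generate_truth", "generate_image", "generate_dataset"]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic datasets (defaults emulate the target regime)."""

    cell_a: float = 106.1
    d_min: float = 2.5
    mean_wavelength: float = 1.46
    wavelength_jitter_sd: float = 0.001  # per-pulse mean jitter (A)
    beam_sigma: float = 0.0015  # spectral s.d. (A), ~0.1% SASE bandwidth
    rlp_radius: float = 1.8e-4  # 1/A
    mosaicity_deg: float = 0.03
    wilson_mean: float = 2000.0  # ADU; exponential intensity scale
    scale_sigma_log: float = 0.3  # lognormal per-image scale spread
    partiality_floor: float = 0.05  # emission floor for observations
    noise_floor: float = 100.0  # ADU^2 additive term in counting sigma
    noise: bool = False  # add Gaussian noise when True
    target_isigma: float | None = None  # inflate sigmas to this mean I/sigma

    @property
    def cell(self) -> UnitCell:
        return UnitCell(self.cell_a)

    @property
    def rlp(self) -> RlpSphere:
        return RlpSphere(self.rlp_radius, self.mosaicity_deg)


@dataclass
class GroundTruth:
    config: SimulationConfig
    asu_hkl: np.ndarray  # (M, 3) unique asu reflections
    intensity: np.ndarray  # (M,) true intensities
    # per-image records, filled by generate_dataset
    true_orientations: list = field(default_factory=list)  # hand-adjusted, pre-misset
    misset_angles: list = field(default_factory=list)  # (alpha, beta) degrees
    scales: list = field(default_factory=list)
    mus: list = field(default_factory=list)
    hands: list = field(default_factory=list)  # "A" or "B"
    true_partialities: list = field(default_factory=list)  # per-obs arrays
    true_intensities: list = field(default_factory=list)  # per-obs I_true

    _lookup: dict = field(default_factory=dict, repr=False)

    def intensity_of(self, hkl: np.ndarray) -> np.ndarray:
        """True intensities of (possibly non-asu) Miller indices."""
        if not self._lookup:
            self._lookup = {tuple(h): i for h, i in zip(map(tuple, self.asu_hkl), self.intensity)}
        asu = np.atleast_2d(map_to_asu(hkl))
        return np.array([self._lookup[tuple(h)] for h in asu])


def random_orientation(rng: np.random.Generator) -> Orientation:
    """Uniform random rotation via a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    U = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return Orientation(U)


def generate_truth(seed: int, config: SimulationConfig | None = None) -> GroundTruth:
    """Enumerate the asu to d_min and draw exponential (Wilson) intensities."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    sphere = candidate_hkl_sphere(config.cell, config.d_min)
    asu = np.unique(map_to_asu(sphere), axis=0)
    intensity = rng.exponential(config.wilson_mean, size=len(asu))
    return GroundTruth(config=config, asu_hkl=asu, intensity=intensity)


def _sigma_multiplier(i_model: np.ndarray, cfg: SimulationConfig) -> float:
    """Multiplier on counting sigmas that hits the configured mean I/sigma.

    Computed from the image's own model intensities so the realized
    per-image mean of I/sigma equals the target before noise is added.
    """
    if cfg.target_isigma is None:
        return 1.0
    ratio = np.mean(i_model / np.sqrt(np.abs(i_model) + cfg.noise_floor))
    return float(ratio / cfg.target_isigma)


def generate_image(
    truth: GroundTruth,
    image_id: int,
    rng: np.random.Generator,
    misset_sd: float = 0.0,
    hand: str = "A",
) -> ImageModel:
    """One synthetic still; appends its truth record to ``truth``."""
    cfg = truth.config
    cell = cfg.cell
    U = random_orientation(rng)
    mu = cfg.mean_wavelength + rng.normal(0.0, cfg.wavelength_jitter_sd)
    scale = float(rng.lognormal(0.0, cfg.scale_sigma_log))
    beam = BeamSpectrum(mu, cfg.beam_sigma)

    if hand == "B":
        # alternate indexing convention: reported hkl = T hkl_phys with the
        # compensating orientation U T, leaving every q vector unchanged
        U = Orientation(U.U @ REINDEX_OP.astype(float))

    hkl_all = candidate_hkl_sphere(cell, cfg.d_min)
    q = (hkl_all.astype(float) @ U.U.T) / cell.a
    lam = excitation_wavelength(q)
    # a finite rlp can diffract with its centre outside the truncated
    # spectrum; emission is gated on partiality alone
    fin = np.isfinite(lam)
    part = np.zeros(len(hkl_all))
    part[fin] = partiality_for_vectors(q[fin], cfg.rlp, beam)
    keep = fin & (part > cfg.partiality_floor)

    hkl = hkl_all[keep]
    p_true = part[keep]
    if hand == "B":
        i_true = truth.intensity_of(hkl @ REINDEX_OP.T)  # physical indices
    else:
        i_true = truth.intensity_of(hkl)
    i_model = scale * p_true * i_true
    mult = _sigma_multiplier(i_model, cfg)
    sigma = mult * np.sqrt(np.abs(i_model) + cfg.noise_floor)
    noise = rng.normal(0.0, sigma) if cfg.noise else np.zeros_like(sigma)
    i_raw = i_model + noise

    # misset: perturb the stored orientation about the two beam-orthogonal axes
    if misset_sd > 0:
        ang = rng.normal(0.0, misset_sd / np.sqrt(2.0), size=2)
    else:
        ang = np.zeros(2)
    U_stored = U.rotated(rotation_about_axis(0, ang[0]) @ rotation_about_axis(1, ang[1]))

    img = ImageModel(
        image_id=image_id,
        orientation=U_stored,
        mu_estimate=cfg.mean_wavelength,  # nominal, not the jittered truth
        hkl=hkl,
        i_raw=i_raw,
        sigma_raw=sigma,
        cell=cell,
    )
    truth.true_orientations.append(U)
    truth.misset_angles.append((float(ang[0]), float(ang[1])))
    truth.scales.append(scale)
    truth.mus.append(mu)
    truth.hands.append(hand)
    truth.true_partialities.append(p_true)
    truth.true_intensities.append(i_true)
    return img


def generate_dataset(
    n_images: int,
    reindex_fraction: float = 0.5,
    misset_sd: float = 0.0,
    seed: int = 1,
    config: SimulationConfig | None = None,
) -> tuple[list[ImageModel], GroundTruth]:
    """Full synthetic dataset: ``n_images`` stills plus the truth bundle."""
    if n_images < 2:
        raise ValueError("need at least two images")
    config = config or SimulationConfig()
    truth = generate_truth(seed, config)
    rng = np.random.default_rng(seed + 1)
    n_b = int(round(reindex_fraction * n_images))
    hands = np.array(["A"] * (n_images - n_b) + ["B"] * n_b)
    rng.shuffle(hands)
    images = [
        generate_image(truth, i, rng, misset_sd=misset_sd, hand=hands[i])
        for i in range(n_images)
    ]
    return images, truth
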