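"""End-to-end orchestration of the post-integration pipeline.

Stages, in order: per-still orientation/mean-wavelength refinement, beam-
bandwidth derivation from the histogram widths, partiality computation and
correction (with cutoff), indexing-ambiguity resolution, two-stage scaling,
merging, and quality statistics.  Each stage is also callable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ambiguity as amb
from . import prediction, scaling, stats
from .config import RunConfig
from .geometry import BeamSpectrum, excitation_wavelength
from .image import ImageModel
from .partiality import RlpSphere, partiality_for_vectors
from .scaling import MergedDataset

__all__ = ["PipelineResult", "apply_partiality", "refine_all", "resolve_ambiguity",
           "scale_and_merge", "run_pipeline"]


@dataclass
class PipelineResult:
    merged: MergedDataset
    shell_table: stats.ShellTable
    overall_cc_half: float
    overall_r_split: float
    overall_r_pim: float
    nominal_resolution: float | None
    hands: np.ndarray | None
    vectors: np.ndarray | None
    beam_sigma: float
    counts: dict = field(default_factory=dict)


def apply_partiality(
    image: ImageModel,
    beam_sigma: float,
    rlp: RlpSphere,
    cutoff: float = 0.3,
) -> int:
    """Compute lambda/partiality for every observation and apply the correction.

    Returns the number of rejected reflections (partiality <= cutoff or
    unexcitable).  Corrected values are stored on the image; the per-image
    scale division happens later, at merge time.
    """
    beam = BeamSpectrum(image.mu_estimate, beam_sigma)
    q = image.q_vectors()
    lam = excitation_wavelength(np.atleast_2d(q))
    part = partiality_for_vectors(q, rlp, beam)
    accepted = np.isfinite(lam) & (part > cutoff)
    with np.errstate(divide="ignore", invalid="ignore"):
        i_corr = np.where(accepted, image.i_raw / np.maximum(part, 1e-300), np.nan)
        s_corr = np.where(accepted, image.sigma_raw / np.maximum(part, 1e-300), np.nan)
    image.lambda_exc = lam
    image.partiality = part
    image.i_corr = i_corr
    image.sigma_corr = s_corr
    image.accepted = accepted
    return int((~accepted).sum())


def refine_all(images: list[ImageModel], config: RunConfig) -> tuple[float, list]:
    """Refine every still's orientation; derive the beam bandwidth.

    Returns ``(beam_sigma, reports)``.  The bandwidth is the median post-
    refinement histogram s.d. across stills multiplied by the deconvolution
    factor; stills with too few hits keep their input orientation and are
    excluded from the bandwidth estimate.
    """
    reports = []
    sds = []
    for img in images:
        try:
            orient, mu, rep = prediction.refine_orientation(
                img,
                hit_threshold=config.hit_threshold,
                net_fraction=config.net_fraction,
                step_start=config.step_start,
                step_stop=config.step_stop,
                halvings_before_switch=config.halvings_before_switch,
                min_hits=config.min_hits,
            )
        except ValueError:
            reports.append(None)
            continue
        img.orientation = orient
        img.mu_estimate = mu
        reports.append(rep)
        if np.isfinite(rep.histogram_sd_after):
            sds.append(rep.histogram_sd_after)
    if sds and config.use_derived_sigma:
        sigma = prediction.derive_beam_sigma(float(np.median(sds)), config.sigma_factor)
    else:
        sigma = config.beam_sigma
    return sigma, reports


def resolve_ambiguity(
    images: list[ImageModel], config: RunConfig
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Resolve the two-fold indexing ambiguity and reindex in place."""
    table = amb.build_correlation_table(
        images, d_min=config.ambiguity_d_min, min_shared=config.min_shared
    )
    vectors, info = amb.minimize_functional(table, seed=config.seed)
    hands, cluster_info = amb.assign_hands(vectors)
    amb.apply_reindexing(images, hands)
    # reindexing moves asu keys, so corrections stay valid but merges change
    info.update(cluster_info)
    return hands, vectors, info


def scale_and_merge(
    images: list[ImageModel], config: RunConfig
) -> tuple[MergedDataset, dict]:
    """Two-stage scaling then final inverse-variance merge."""
    info = scaling.initial_scales(
        images, d_limit=config.scale_d_limit, weak_threshold=config.weak_image_threshold
    )
    merged, scale_report = scaling.iterate_scaling(
        images, tol=config.scale_tol, max_iter=config.scale_max_iter
    )
    scale_report["initial"] = info
    return merged, scale_report


def partiality_effectiveness(
    images: list[ImageModel], config: RunConfig | None = None
) -> dict[str, float]:
    """Overall CC1/2 under three partiality treatments.

    ``none``: every simulated/predicted reflection merged at raw intensity;
    ``cutoff``: reflections at or below the cutoff discarded but intensities
    not divided; ``divide``: the full correction.  All three share the same
    scaling protocol and half-set split seed, isolating the effect of the
    partiality model on merging quality.
    """
    config = config or RunConfig()
    rlp = RlpSphere(config.rlp_radius, config.mosaicity_deg)
    out: dict[str, float] = {}
    for mode in ("none", "cutoff", "divide"):
        for im in images:
            apply_partiality(im, config.beam_sigma, rlp, config.partiality_cutoff)
            if mode == "none":
                im.accepted = np.isfinite(im.lambda_exc)
                im.i_corr = im.i_raw.copy()
                im.sigma_corr = im.sigma_raw.copy()
            elif mode == "cutoff":
                im.i_corr = np.where(im.accepted, im.i_raw, np.nan)
                im.sigma_corr = np.where(im.accepted, im.sigma_raw, np.nan)
            im.scale = 1.0
            im.rejected_reason = None
        scaling.initial_scales(
            images, d_limit=config.scale_d_limit, weak_threshold=0.0
        )
        scaling.iterate_scaling(images, tol=config.scale_tol, max_iter=20)
        asu, ivals, _ = stats.pooled_observations(images)
        cc, _, _, _ = stats.cc_half(asu, ivals, seed=config.seed)
        out[mode] = cc
    return out


def run_pipeline(
    images: list[ImageModel],
    config: RunConfig | None = None,
    refine: bool = True,
) -> PipelineResult:
    """Run every stage on a list of stills and collect statistics."""
    config = config or RunConfig()
    counts: dict = {"n_images_in": len(images)}

    if refine:
        beam_sigma, reports = refine_all(images, config)
        counts["n_refined"] = sum(r is not None for r in reports)
    else:
        beam_sigma = config.beam_sigma

    rlp = RlpSphere(config.rlp_radius, config.mosaicity_deg)
    n_rejected_refl = 0
    for img in images:
        n_rejected_refl += apply_partiality(img, beam_sigma, rlp, config.partiality_cutoff)
    counts["n_reflections_rejected_partiality"] = n_rejected_refl
    counts["n_reflections_kept"] = int(sum(img.accepted.sum() for img in images))

    hands, vectors, amb_info = resolve_ambiguity(images, config)
    counts["n_hand_b"] = int((hands == "B").sum())
    counts["ambiguity"] = amb_info

    merged, scale_report = scale_and_merge(images, config)
    counts["n_images_rejected"] = len(scale_report["initial"]["rejected"])
    counts["n_images_merged"] = counts["n_images_in"] - counts["n_images_rejected"]
    counts["scaling"] = {k: scale_report[k] for k in ("converged", "n_iterations")}

    asu, ivals, svals = stats.pooled_observations(images)
    table = stats.shell_statistics(
        asu, ivals, svals, images[0].cell, n_shells=config.n_shells, seed=config.seed
    )
    cc_overall, _, m1, m2 = stats.cc_half(asu, ivals, seed=config.seed)
    ok = np.isfinite(m1) & np.isfinite(m2)
    r_split_overall = stats._r_split_arrays(m1[ok], m2[ok])
    r_pim_overall = stats.r_pim(asu, ivals)
    nominal = stats.overall_resolution(table.d_high, table.cc_half, config.cc_half_cut)

    # R_split between the two indexing halves, as an alternative split
    hands_arr = np.asarray(hands)
    if (hands_arr == "B").any() and (hands_arr == "A").any():
        half_a = scaling.merge([im for im, h in zip(images, hands_arr) if h == "A"])
        half_b = scaling.merge([im for im, h in zip(images, hands_arr) if h == "B"])
        try:
            r_split_hands = stats.r_split(half_a, half_b)
        except ValueError:
            r_split_hands = np.nan
        counts["r_split_between_hands"] = r_split_hands

    return PipelineResult(
        merged=merged,
        shell_table=table,
        overall_cc_half=cc_overall,
        overall_r_split=r_split_overall,
        overall_r_pim=r_pim_overall,
        nominal_resolution=nominal,
        hands=hands,
        vectors=vectors,
        beam_sigma=beam_sigma,
        counts=counts,
    )
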