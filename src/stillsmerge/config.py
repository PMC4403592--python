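"""Run configuration: every pipeline constant in one serializable record."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable constants with their experiment-derived defaults.

    Nothing numeric is hard-coded in module code; stages read from here and
    every value is serialized into run logs.
    """

    cell_a: float = 106.1  # A, cubic I23
    nominal_wavelength: float = 1.46  # A
    d_min: float = 2.5  # A, working resolution limit
    net_fraction: float = 0.035  # inflated-bandwidth prediction net
    hit_threshold: float = 150.0  # ADU
    sigma_factor: float = 0.27  # histogram-sd -> beam-sigma deconvolution
    beam_sigma: float = 0.0015  # A, fallback / externally known bandwidth
    use_derived_sigma: bool = True  # deconvolve bandwidth from histograms
    rlp_radius: float = 1.8e-4  # 1/A (treated as a radius)
    mosaicity_deg: float = 0.03
    partiality_cutoff: float = 0.3
    scale_d_limit: float = 3.5  # A
    weak_image_threshold: float = 333.0  # ADU
    cc_half_cut: float = 0.30
    image_isigma_cut: float = 2.0
    step_start: float = 0.5  # degrees
    step_stop: float = 0.001  # degrees
    halvings_before_switch: int = 3
    min_hits: int = 10
    min_shared: int = 2  # ambiguity pairwise overlap floor
    ambiguity_d_min: float = 1.8  # A
    n_shells: int = 20
    scale_tol: float = 1e-4
    scale_max_iter: int = 50
    seed: int = 1

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
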