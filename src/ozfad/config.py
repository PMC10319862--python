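"""Pipeline configuration: every user-set threshold in one serializable block."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the discovery/quantification pipeline.

    Tolerances are ppm unless suffixed otherwise; times are minutes except
    the DDA slot width and include window, which the instrument defines in
    seconds and which are converted at the boundary.
    """

    agent_code: str = "AMPP"

    # m/z matching
    precursor_xic_ppm: float = 20.0
    product_match_ppm: float = 10.0
    noise_proximity_ppm: float = 20.0
    max_precursor_ppm_error: float = 10.0
    isolation_window_da: float = 2.0

    # precursor analysis
    carbons_min: int = 12
    carbons_max: int = 26
    double_bonds_max: int = 6
    abundance_threshold: float = 10.0  # XIC peak area
    min_peak_height: float = 50.0
    min_peak_points: int = 4

    # retention-window prediction (dECL bounds per double-bond count)
    decl_lo_per_db: float = -2.2
    decl_lo_const: float = -0.3
    decl_hi_per_db: float = -0.4
    decl_hi_const: float = 0.3

    # target-list construction
    gradient_min: float = 20.0
    slot_width_s: float = 0.3
    raw_halfwidth_fwhm: float = 1.5  # claim half-width as multiple of peak FWHM
    min_points_per_peak: int = 6
    include_window_mda: float = 150.0
    include_window_s: float = 0.15
    fairness_window_slots: int = 10  # sliding window for slot-allocation fairness

    # double-bond search
    search_mode: str = "de_novo"  # library | de_novo | streamlined
    min_db_position: int = 2
    product_presence_min: float = 1.0  # counts in the combined MS2 spectrum
    co_elution_tol_min: float = 0.05
    duplicate_apex_tol_min: float = 0.02  # same-feature identity for dedupe
    relative_peak_floor: float = 0.02  # minor-peak height vs window maximum

    # S/N scoring and tiers
    snr_tentative: float = 3.0
    snr_confident: float = 10.0

    # annotation
    overox_rate_cis: float = 0.015
    overox_rate_trans: float = 0.03
    overox_guard: float = 1.25
    blank_keep_below: float = 0.01
    blank_exclude_above: float = 0.75
    decl_config_tol: float = 0.15
    decl_branch_offset: float = 0.3
    ecl_log_interpolation: bool = False

    # reproducibility
    rng_seed: int = 0
    replicates: list = field(default_factory=list)

    def __post_init__(self):
        for name in ("precursor_xic_ppm", "product_match_ppm", "noise_proximity_ppm",
                     "slot_width_s", "co_elution_tol_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("overox_rate_cis", "overox_rate_trans",
                     "blank_keep_below", "blank_exclude_above"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh.read())
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    @property
    def n_slots(self) -> int:
        return int(round(self.gradient_min * 60.0 / self.slot_width_s))
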