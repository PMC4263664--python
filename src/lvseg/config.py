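"""Flat key-value pipeline configuration (YAML-serializable).

Every tunable named by a pipeline stage lives here with its default, so a
run is fully described by one small file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # ROI / initialization
    roi_half_size: int = 40
    init_circle_radius: float = 15.0
    mid_slice_index: int | None = None    # None -> middle of the stack

    # LBF evolution
    lbf_lambda1: float = 1.0
    lbf_lambda2: float = 1.0
    lbf_sigma: float = 3.0
    lbf_nu: float | None = None           # None -> 0.01 * intensity range^2
    lbf_mu: float = 1.0
    lbf_timestep: float = 0.1
    lbf_epsilon: float = 1.0
    lbf_max_iter: int = 300
    lbf_tol: float = 1e-3

    # blood pool
    n_thresholds: int = 24
    min_pool_area: int = 20               # px; apical termination guard
    max_pool_fraction: float = 0.6        # of ROI area; degenerate-pool guard

    # endocardium
    lvot_ratio_threshold: float = 1.2
    pool_dilation_px: int = 3
    circle_outlier_px: float = 3.0
    fft_smooth_endo: bool = True
    keep_harmonics: int = 8

    # epicardium / DP
    n_angles: int = 180
    radial_step: float = 1.0
    delta: int = 2
    dp_weight: float = 1.0
    dp_gamma: float = 0.1
    r_max_factor: float = 2.5
    endo_margin_rows: int = 1
    bright_dilation_rows: int = 2
    prev_epi_dilation: int = 3
    edge_smooth_sigma: float = 1.0

    # smoothing
    bezier_segments: int = 16
    bezier_samples: int = 180

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
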