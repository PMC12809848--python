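"""Pipeline configuration: schema, defaults, and validation.

Defaults mirror the analysis parameters of the target study design:
20 components estimated 20 times, mean-FD exclusion at 0.2 mm, 0.01-0.1 Hz
voxel-wise band-pass, 0.15 Hz network time-course low-pass, 6-mm FWHM
smoothing, alpha 0.05 and a 10-voxel minimum cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "validate_config"]


@dataclass
class PipelineConfig:
    # paths
    input_dir: str | None = None  # cohort written by generate_cohort; None -> simulate
    output_dir: str = "dmnflow_out"
    # simulation (kwargs forwarded to CohortSpec when input_dir is None)
    simulate: dict = field(default_factory=dict)
    # preprocessing
    fd_threshold: float = 0.2
    band_hz: tuple[float, float] = (0.01, 0.1)
    high_cutoff_hz: float = 0.15
    fwhm_mm: float = 6.0
    # ICA
    n_components: int = 20
    n_runs: int = 20
    seed: int = 0
    # metrics
    n_bins: int = 32
    mask_z_threshold: float = 1.0
    # statistics
    alpha: float = 0.05
    n_perm: int = 5000
    posthoc: str = "tukey"
    min_cluster: int = 10
    voxelwise: bool = False  # permutation TFCE on NH maps (expensive)

    def __post_init__(self) -> None:
        if self.fd_threshold <= 0:
            raise ValueError("fd_threshold must be > 0")
        low, high = self.band_hz
        if not 0 <= low < high:
            raise ValueError("band_hz must satisfy 0 <= low < high")
        if self.high_cutoff_hz <= 0:
            raise ValueError("high_cutoff_hz must be > 0")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        if self.n_components < 1 or self.n_runs < 1:
            raise ValueError("n_components and n_runs must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.posthoc not in ("tukey", "lsd"):
            raise ValueError("posthoc must be 'tukey' or 'lsd'")
        if self.min_cluster < 1:
            raise ValueError("min_cluster must be >= 1")


def validate_config(raw: str | dict | Path | None) -> PipelineConfig:
    """Parse a YAML/JSON config (text, path, or dict) into a PipelineConfig.

    Missing keys take the documented defaults; unknown keys are rejected.
    """
    if raw is None:
        data: dict = {}
    elif isinstance(raw, dict):
        data = dict(raw)
    else:
        text = Path(raw).read_text() if isinstance(raw, Path) else raw
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "band_hz" in data:
        data["band_hz"] = tuple(data["band_hz"])
    return PipelineConfig(**data)
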