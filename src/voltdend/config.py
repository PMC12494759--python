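"""Pipeline configuration: one validated object carrying every stage's
parameters, with defaults equal to the analysis' canonical values
(2 s running window, 5th-order Butterworth at 4 Hz, 3 sigma threshold,
25 ms spike window, 4 ms CCG bins, 4.8 um segments, 20-200 ms IPSP search
window, 500 shuffles)."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .synth import SceneConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    scene: SceneConfig = Field(default_factory=SceneConfig)

    # trace processing
    dff_window_s: float = Field(2.0, gt=0)
    baseline_cutoff_hz: float = Field(4.0, gt=0)
    baseline_order: int = Field(5, ge=1)
    threshold_sd: float = Field(3.0, gt=0)
    peak_window_ms: float = Field(25.0, gt=0)
    pre_cut_ms: float = Field(10.0, ge=0)
    post_cut_ms: float = Field(25.0, ge=0)

    # segmentation
    mask_sigma_px: float = Field(1.0, ge=0)
    segment_length_um: float = Field(4.8, gt=0)
    cluster_threshold_r: float = Field(0.5, gt=-1, lt=1)

    # synchrony
    ccg_bin_ms: float = Field(4.0, gt=0)
    ccg_span_ms: float = Field(200.0, gt=0)
    ccg_alpha: float = Field(0.01, gt=0, lt=1)

    # triggered responses
    ipsp_window_s: tuple[float, float] = (0.02, 0.2)
    upsample_rate_hz: float = Field(2000.0, gt=0)
    spike_prob_window_s: float = Field(0.15, gt=0)

    # plasticity
    match_threshold: float = Field(0.6, ge=0, le=1)
    n_shuffles: int = Field(500, ge=1)

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        nyquist = self.scene.frame_rate / 2
        if self.baseline_cutoff_hz >= nyquist:
            raise ValueError(
                f"baseline_cutoff_hz: {self.baseline_cutoff_hz} Hz is at or above "
                f"Nyquist ({nyquist} Hz) for a {self.scene.frame_rate} Hz frame rate"
            )
        if self.ipsp_window_s[1] <= self.ipsp_window_s[0]:
            raise ValueError("ipsp_window_s must be increasing")
        return self


def load_config(path: str | Path) -> PipelineConfig:
    """Load a JSON config; missing keys take defaults, unknown keys are
    rejected.  An empty file yields all defaults; ``save_config(load_config(x))``
    round-trips."""
    text = Path(path).read_text().strip()
    data = json.loads(text) if text else {}
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(config.model_dump_json(indent=2))
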