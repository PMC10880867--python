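"""YAML-backed analysis configuration.

One small dataclass gathers the knobs the pipeline exposes — gap filling,
site mapping overrides, cycle segmentation, length normalization, wavelet
comparison — so a whole analysis is reproducible from a single file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["AnalysisConfig", "load_config", "save_config"]


@dataclass
class AnalysisConfig:
    """Pipeline settings with the defaults used throughout the package."""

    # keypoint gap filling
    max_gap: int = 5
    min_confidence: float = 0.3
    # site mapping overrides: site -> [limb_a, vertex, limb_b] joint names
    site_mapping: dict[str, list[str]] | None = None
    # cycle segmentation
    segmentation_site: str = "left_hip"
    smoothing_window: int = 9
    min_prominence: float = 20.0
    # length normalization
    target_length: int = 400
    short_series_policy: str = "error"
    # severity classification
    zero_as_mild: bool = False
    # wavelet comparison
    wavelet: str = "haar"
    aggregation: str = "sum"
    seed: int = 0

    def mapping_tuples(self) -> dict[str, tuple[str, str, str]] | None:
        if self.site_mapping is None:
            return None
        return {site: tuple(names) for site, names in self.site_mapping.items()}


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML; unknown keys are rejected."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a YAML mapping")
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return AnalysisConfig(**raw)


def save_config(config: AnalysisConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(asdict(config), sort_keys=False))
    return path
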