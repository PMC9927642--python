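"""Pipeline configuration and the two published parameter presets.

``points15000``: K_f=64, K1=32, beta1=0.85, alpha1=5 for the stem stage and
K2=32, beta2=0.85, alpha2=9 for the leaf stage, at 15,000 down-sampled points.
``points4096``: the same except K_f=16, K1=8, K2=8 at 4,096 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .downsample import DownsampleConfig
from .errors import ValidationError
from .leaf import LeafConfig
from .quickshiftpp import QspConfig
from .stem import MnvgConfig, StemConfig, StemFeatureConfig

__all__ = ["PipelineConfig", "preset", "PRESETS"]


@dataclass
class PipelineConfig:
    downsample: DownsampleConfig = field(default_factory=DownsampleConfig)
    stem: StemConfig = field(default_factory=StemConfig)
    leaf: LeafConfig = field(default_factory=LeafConfig)
    preset_name: str = "points15000"
    upsample: bool = True      # map labels back onto the raw cloud
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "preset": self.preset_name,
            "seed": self.seed,
            "target_n": self.downsample.target_n,
            "k_f": self.stem.feature.k_f,
            "k1": self.stem.qsp.k,
            "beta1": self.stem.qsp.beta,
            "alpha1": self.stem.alpha1,
            "mu": self.stem.mnvg.mu,
            "k2": self.leaf.k2,
            "beta2": self.leaf.beta2,
            "alpha2": self.leaf.alpha2,
        }


def _preset_15000() -> PipelineConfig:
    return PipelineConfig(
        downsample=DownsampleConfig(target_n=15000),
        stem=StemConfig(
            alpha1=5.0,
            qsp=QspConfig(k=32, beta=0.85),
            feature=StemFeatureConfig(k_f=64),
            mnvg=MnvgConfig(mu=0.30),
        ),
        leaf=LeafConfig(k2=32, beta2=0.85, alpha2=9.0),
        preset_name="points15000",
    )


def _preset_4096() -> PipelineConfig:
    return PipelineConfig(
        downsample=DownsampleConfig(target_n=4096),
        stem=StemConfig(
            alpha1=5.0,
            qsp=QspConfig(k=8, beta=0.85),
            feature=StemFeatureConfig(k_f=16),
            mnvg=MnvgConfig(mu=0.30),
        ),
        leaf=LeafConfig(k2=8, beta2=0.85, alpha2=9.0),
        preset_name="points4096",
    )


PRESETS = {"points15000": _preset_15000, "points4096": _preset_4096}


def preset(name: str) -> PipelineConfig:
    """Return a fresh PipelineConfig for a named preset."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


def load_yaml_config(path: str) -> PipelineConfig:
    """YAML overrides applied on top of the file's ``preset`` (default points15000)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = preset(raw.get("preset", "points15000"))
    return apply_overrides(cfg, raw)


def apply_overrides(cfg: PipelineConfig, over: dict) -> PipelineConfig:
    """Apply flat key overrides (the keys of ``to_dict``) to a config."""
    if "target_n" in over and over["target_n"] is not None:
        cfg.downsample = replace(cfg.downsample, target_n=int(over["target_n"]))
    stem = cfg.stem
    if over.get("k1") is not None or over.get("beta1") is not None:
        stem.qsp = QspConfig(
            k=int(over.get("k1") or stem.qsp.k),
            beta=float(over.get("beta1") or stem.qsp.beta),
            min_core_size=stem.qsp.min_core_size,
        )
    if over.get("k_f") is not None:
        stem.feature = StemFeatureConfig(k_f=int(over["k_f"]))
    if over.get("alpha1") is not None:
        stem.alpha1 = float(over["alpha1"])
    if over.get("mu") is not None:
        stem.mnvg = replace(stem.mnvg, mu=float(over["mu"]))
    leaf = cfg.leaf
    cfg.leaf = LeafConfig(
        k2=int(over.get("k2") or leaf.k2),
        beta2=float(over.get("beta2") or leaf.beta2),
        alpha2=float(over.get("alpha2") or leaf.alpha2),
        min_core_size=leaf.min_core_size,
    )
    if over.get("seed") is not None:
        cfg.seed = int(over["seed"])
    if over.get("upsample") is not None:
        cfg.upsample = bool(over["upsample"])
    return cfg
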