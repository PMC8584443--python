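"""Network and training configuration.

Defaults reproduce the published architecture: 256-filter first convolutions
(9x9; padding 1 on the biological branch, none on the sequence branch), CBAM
with reduction 16 and a 7x7 spatial kernel, 16-dimensional primary capsules
(kernel 7 biological / 9 sequence, stride 2), 3 routing iterations onto two
32-dimensional output capsules, margin loss with margins 0.9/0.1 and
down-weight 0.5, and Adam (lr 1e-3, eps 1e-8) for 6 epochs at batch size 32.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

CONFIG_SCHEMA_VERSION = 1

VALID_FEATURE_SUBSETS = ("rcc", "aac_dpc", "sec")


@dataclass
class NetworkConfig:
    # input geometry
    bio_shape: tuple[int, int] = (33, 20)
    seq_len: int = 50
    embedding_dim: int = 20
    # first convolution
    conv_channels: int = 256
    bio_kernel: int = 9
    bio_pad: int = 1
    seq_kernel: int = 9
    seq_pad: int = 0
    # CBAM
    use_cbam: bool = True
    cbam_reduction: int = 16
    spatial_kernel: int = 7
    # capsules
    caps_dim: int = 16
    primary_stride: int = 2
    bio_caps_kernel: int = 7
    seq_caps_kernel: int = 9
    # squash applied only at the output capsules by default; the published
    # routing diagram shows no squash at the primary layer
    primary_squash: bool = False
    routing_iters: int = 3
    n_classes: int = 2
    out_caps_dim: int = 32
    squash_norm_squared: bool = True  # False -> 1+||s|| denominator variant
    eps: float = 1e-8
    # ablations
    combined_input: bool = False
    feature_subsets: tuple[str, ...] = VALID_FEATURE_SUBSETS
    kurtosis_sigma2: bool = False
    # loss / optimizer
    m_pos: float = 0.9
    m_neg: float = 0.1
    lam: float = 0.5
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")
        if self.routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        if self.conv_channels % self.cbam_reduction:
            raise ValueError(
                f"conv_channels ({self.conv_channels}) must be divisible by "
                f"cbam_reduction ({self.cbam_reduction})"
            )
        bad = set(self.feature_subsets) - set(VALID_FEATURE_SUBSETS)
        if bad:
            raise ValueError(f"unknown feature subset(s): {sorted(bad)}")
        self.feature_subsets = tuple(self.feature_subsets)

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bio_shape"] = list(self.bio_shape)
        d["feature_subsets"] = list(self.feature_subsets)
        d["schema_version"] = CONFIG_SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d.pop("schema_version", None)
        if "bio_shape" in d:
            d["bio_shape"] = tuple(d["bio_shape"])
        if "feature_subsets" in d:
            d["feature_subsets"] = tuple(d["feature_subsets"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def small_config(**overrides) -> NetworkConfig:
    """A compute-scaled configuration for desk-scale training and tests.

    Keeps the architecture (two branches, CBAM, primary capsules, routing)
    while shrinking channel counts so that a few thousand peptides train in
    seconds on one CPU. Capsule counts scale accordingly; the published
    counts (544/704/1248) hold only for the default configuration.
    """
    base = dict(conv_channels=16, cbam_reduction=4, caps_dim=8, out_caps_dim=16)
    base.update(overrides)
    return NetworkConfig(**base)
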