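"""Declarative configuration objects.

Three dataclasses describe, as plain data, everything a run needs: the
network variant (:class:`ArchitectureSpec`), the optimisation protocol
(:class:`TrainConfig`) and the procedural fixture generator
(:class:`SyntheticSpec`). All of them round-trip through dict/YAML so a run
can always dump the resolved configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import yaml

DILATION_SET = (1, 6, 12, 18)

#: widest pyramid branch used by any variant (the five-depth design's width);
#: deeper bottlenecks do not widen the pyramid further
MAX_PYRAMID_BRANCH_CHANNELS = 512


@dataclass
class ArchitectureSpec:
    """One network variant of the modified SegNet family.

    ``convs_per_depth`` holds (count_3x3, count_5x5) per encoder depth; the
    5x5 blocks sit after the 3x3 blocks on the encoder side and before them
    at the mirrored decoder depth. The decoder plan is always the exact
    mirror of the encoder plan.
    """

    variant_name: str
    encoder_channels: List[int]
    convs_per_depth: List[Tuple[int, int]]
    dilation_set: Tuple[int, ...] = DILATION_SET
    num_classes: int = 2
    skip_merge_mode: str = "add"
    input_size: Tuple[int, int] = (288, 384)  # (height, width)
    pyramid_branch_channels: Optional[int] = None  # default: min(bottleneck, 512)
    pyramid_projection_kernel: int = 1

    def __post_init__(self):
        self.encoder_channels = [int(c) for c in self.encoder_channels]
        self.convs_per_depth = [tuple(int(v) for v in p)
                                for p in self.convs_per_depth]
        self.dilation_set = tuple(int(d) for d in self.dilation_set)
        self.input_size = tuple(int(v) for v in self.input_size)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        ch = self.encoder_channels
        if not ch:
            raise ValueError("encoder_channels must be non-empty")
        if any(b < a for a, b in zip(ch, ch[1:])):
            raise ValueError("encoder_channels must be non-decreasing")
        if len(self.convs_per_depth) != len(ch):
            raise ValueError("convs_per_depth must match encoder depth count")
        if self.dilation_set != DILATION_SET:
            raise ValueError(
                f"dilation_set must be {list(DILATION_SET)}, "
                f"got {list(self.dilation_set)}")
        if self.num_classes != 2:
            raise ValueError("binary polyp/background segmentation requires "
                             "num_classes == 2")
        if self.skip_merge_mode not in ("add", "concat"):
            raise ValueError("skip_merge_mode must be 'add' or 'concat'")
        if any(v < 1 for v in self.input_size):
            raise ValueError("input_size must be positive")
        if self.pyramid_projection_kernel not in (1, 3):
            raise ValueError("pyramid_projection_kernel must be 1 or 3")

    # -- derived ----------------------------------------------------------
    @property
    def depths(self) -> int:
        return len(self.encoder_channels)

    @property
    def bottleneck_channels(self) -> int:
        return self.encoder_channels[-1]

    @property
    def branch_channels(self) -> int:
        if self.pyramid_branch_channels is not None:
            return self.pyramid_branch_channels
        return min(self.bottleneck_channels, MAX_PYRAMID_BRANCH_CHANNELS)

    def encoder_kernels(self, depth_index: int) -> List[int]:
        n3, n5 = self.convs_per_depth[depth_index]
        return [3] * n3 + [5] * n5

    # -- IO ---------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["convs_per_depth"] = [list(p) for p in self.convs_per_depth]
        d["dilation_set"] = list(self.dilation_set)
        d["input_size"] = list(self.input_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ArchitectureSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


_VGG19_SHALLOW = [(2, 2), (2, 2)]  # 3x3 pairs plus the two extra 5x5 blocks


def variant_spec(name: str, **overrides) -> ArchitectureSpec:
    """The three published variants: ``small`` (100 layers), ``proposed``
    (154 layers) and ``large`` (208 layers)."""
    if name == "small":
        channels = [64, 128, 256]
        convs = _VGG19_SHALLOW + [(4, 0)]
    elif name == "proposed":
        channels = [64, 128, 256, 512, 512]
        convs = _VGG19_SHALLOW + [(4, 0)] * 3
    elif name == "large":
        channels = [64, 128, 256, 512, 512, 1024, 1024]
        convs = _VGG19_SHALLOW + [(4, 0)] * 5
    else:
        raise ValueError(
            f"unknown variant {name!r}; expected small, proposed or large")
    return ArchitectureSpec(variant_name=name, encoder_channels=channels,
                            convs_per_depth=convs, **overrides)


@dataclass
class TrainConfig:
    """The published optimisation protocol: SGD with momentum 0.9, base
    learning rate 0.001 dropped by x0.3 every 10 epochs, 100 epochs,
    mini-batches of four."""

    momentum: float = 0.9
    base_learning_rate: float = 0.001
    epochs: int = 100
    mini_batch_size: int = 4
    lr_drop_factor: float = 0.3
    lr_drop_period_epochs: int = 10
    seed: int = 0
    shuffle_each_epoch: bool = True
    #: 'rolling' streams shuffled samples continuously across epoch
    #: boundaries (floor(n*epochs/batch) iterations total); 'per_epoch'
    #: is conventional batching with a partial final batch each epoch.
    batching: str = "rolling"

    def __post_init__(self):
        if not 0.0 < self.lr_drop_factor < 1.0:
            raise ValueError("lr_drop_factor must lie in (0, 1)")
        if min(self.epochs, self.mini_batch_size,
               self.lr_drop_period_epochs) < 1:
            raise ValueError("epochs, mini_batch_size and "
                             "lr_drop_period_epochs must be >= 1")
        if self.batching not in ("rolling", "per_epoch"):
            raise ValueError("batching must be 'rolling' or 'per_epoch'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class SyntheticSpec:
    """Parameters of the procedural colonoscopy-like fixture generator.

    Every image carries at least one bright elliptical "polyp" on a textured,
    vignetted mucosa-toned background; the mask is the exact union of the
    ellipse interiors. Radii are fractions of min(height, width).
    """

    resolution: Tuple[int, int] = (288, 384)  # (height, width)
    polyps_per_image: Tuple[int, int] = (1, 3)
    polyp_radius_range: Tuple[float, float] = (0.06, 0.20)
    polyp_eccentricity_range: Tuple[float, float] = (1.0, 2.0)
    background_texture_scale: float = 0.08
    vignette_strength: float = 0.5
    specular_highlight_count: int = 3
    intensity_contrast: float = 0.35
    noise_std: float = 0.03
    seed: int = 0

    def __post_init__(self):
        self.resolution = tuple(int(v) for v in self.resolution)
        self.polyps_per_image = tuple(int(v) for v in self.polyps_per_image)
        if self.polyps_per_image[0] < 1:
            raise ValueError("every image must contain at least one polyp")
        if self.polyp_radius_range[0] <= 0:
            raise ValueError("polyp radii must be positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("resolution", "polyps_per_image", "polyp_radius_range",
                    "polyp_eccentricity_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))
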