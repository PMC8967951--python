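"""Run configuration: nested dataclasses with the published defaults.

A config file (YAML or JSON) may specify any subset of keys; everything else
falls back to the defaults below, which are the parameter values published
for the original confocal data set.  Unknown keys are rejected with the full
key path.  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple, get_args, get_origin

import yaml

from .core import DEFAULT_VOXEL_SIZE, SpineflowError


class ConfigError(SpineflowError):
    pass


Triple = Tuple[float, float, float]
ITriple = Tuple[int, int, int]


@dataclass
class ReconnectConfig:
    """Parameters of the automatic gap-reconnection algorithm.

    Ellipsoid sizes are per-axis semi-axes in voxels, (x, y, z); a zero
    semi-axis means no growth along that axis.
    """

    f_s: float = 1.0  # density-vs-length scale factor in the path cost
    median_mask: ITriple = (8, 8, 2)  # median filter window, voxels (x, y, z)
    tolerance: float = 0.10  # flood-fill relative intensity band
    max_ellipsoid_shaft: ITriple = (3, 3, 2)
    max_ellipsoid_spine: ITriple = (6, 6, 2)
    min_ellipsoid: ITriple = (1, 1, 0)
    connectivity: int = 26  # {6, 26}
    distance_units: str = "physical"  # {"physical", "voxel"}

    def __post_init__(self):
        if not 0 <= self.tolerance < 1:
            raise ConfigError(f"reconnect.tolerance must be in [0, 1), got {self.tolerance}")
        if self.connectivity not in (6, 26):
            raise ConfigError(f"reconnect.connectivity must be 6 or 26, got {self.connectivity}")
        if self.distance_units not in ("physical", "voxel"):
            raise ConfigError(f"reconnect.distance_units must be physical|voxel")
        for name in ("max_ellipsoid_shaft", "max_ellipsoid_spine", "min_ellipsoid"):
            if any(a < 0 for a in getattr(self, name)):
                raise ConfigError(f"reconnect.{name}: semi-axes must be >= 0")
        if any(m > M for m, M in zip(self.min_ellipsoid,
                                     map(min, zip(self.max_ellipsoid_shaft,
                                                  self.max_ellipsoid_spine)))):
            raise ConfigError("reconnect.min_ellipsoid must fit inside both max ellipsoids")


@dataclass
class WeightingConfig:
    """Loss and weight-map options (class weights and pixel distance weights)."""

    loss: str = "wcel"  # {"wcel", "cel", "gdl"}
    mode: str = "none"  # pixel weight: {"none", "exp", "window"}
    r_decay: float = 0.5  # exponential decay ratio, per μm
    d_max: float = 5.0  # window cutoff distance, μm
    class_scope: str = "patch"  # {"patch", "dataset"}

    def __post_init__(self):
        if self.loss not in ("wcel", "cel", "gdl"):
            raise ConfigError(f"weighting.loss must be wcel|cel|gdl, got {self.loss!r}")
        if self.mode not in ("none", "exp", "window"):
            raise ConfigError(f"weighting.mode must be none|exp|window, got {self.mode!r}")
        if not 0 <= self.r_decay <= 1:
            raise ConfigError("weighting.r_decay must be in [0, 1]")
        if self.d_max <= 0:
            raise ConfigError("weighting.d_max must be > 0")
        if self.class_scope not in ("patch", "dataset"):
            raise ConfigError("weighting.class_scope must be patch|dataset")


@dataclass
class UNetConfig:
    """Volumetric encoder-decoder size and patch contract.  Patch sizes (x, y, z)."""

    stages: int = 5
    base_channels: int = 16
    input_patch: ITriple = (300, 300, 66)
    output_patch: ITriple = (116, 116, 10)
    padding_mode: str = "reflective"  # {"reflective", "zero"}
    conv_mode: str = "valid"  # {"valid", "same"}
    pool_z: bool = True  # whether max pooling also halves z

    def __post_init__(self):
        if self.stages < 2:
            raise ConfigError("network.stages must be >= 2")
        if self.padding_mode not in ("reflective", "zero"):
            raise ConfigError("network.padding_mode must be reflective|zero")
        if self.conv_mode not in ("valid", "same"):
            raise ConfigError("network.conv_mode must be valid|same")
        if any(o > i for i, o in zip(self.input_patch, self.output_patch)):
            raise ConfigError("network.output_patch must be <= input_patch per axis")
        if any((i - o) % 2 for i, o in zip(self.input_patch, self.output_patch)):
            raise ConfigError("network patch margins (input - output)/2 must be integral")

    @property
    def margins(self) -> ITriple:
        """Per-axis context margin (input - output)/2, (x, y, z)."""
        return tuple((i - o) // 2 for i, o in zip(self.input_patch, self.output_patch))


@dataclass
class TrainConfig:
    """Optimization settings.  The published profile trains with Adam."""

    learning_rate: float = 1e-7  # published value; desk-scale runs use 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    batch_size: int = 8
    max_epochs: int = 50
    patch_filter: str = "any_labeled"  # {"any_labeled", "min_fraction"}
    min_label_fraction: float = 0.10
    augment: bool = True
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ConfigError("train.batch_size must be >= 1")
        if not 0 <= self.min_label_fraction <= 1:
            raise ConfigError("train.min_label_fraction must be in [0, 1]")
        if self.patch_filter not in ("any_labeled", "min_fraction"):
            raise ConfigError("train.patch_filter must be any_labeled|min_fraction")


@dataclass
class NoiseFilterConfig:
    """Disconnected-component noise filter: remove components farther than D μm
    from any sufficiently large shaft component and smaller than V_s μm³."""

    D: float = 3.0
    V_d: float = 0.16
    V_s: float = 0.024
    apply_to: Tuple[str, ...] = ("shaft", "spine")

    def __post_init__(self):
        if min(self.D, self.V_d, self.V_s) <= 0:
            raise ConfigError("noise filter D, V_d, V_s must all be positive")
        bad = set(self.apply_to) - {"shaft", "spine"}
        if bad:
            raise ConfigError(f"noise filter apply_to: unknown classes {sorted(bad)}")


@dataclass
class PhantomConfig:
    """Synthetic dendrite phantom parameters (lengths in μm)."""

    shape: ITriple = (96, 96, 32)  # (x, y, z) voxels
    voxel_size: Triple = DEFAULT_VOXEL_SIZE
    shaft_radius: float = 0.45
    spine_count: int = 8
    head_radius_range: Tuple[float, float] = (0.20, 0.35)
    neck_radius: float = 0.0751562  # ~1 voxel: necks at the resolution limit
    neck_length_range: Tuple[float, float] = (0.45, 0.80)
    neck_break_probability: float = 0.0
    missing_branch: bool = False
    psf_sigma_xy: float = 0.10
    psf_sigma_z: float = 0.30  # axial elongation sigma_z/sigma_xy = 3
    noise_sigma: float = 600.0  # additive Gaussian, 16-bit counts
    poisson_noise: bool = False
    peak_intensity: float = 20000.0
    seed: int = 0

    def __post_init__(self):
        if min(self.shaft_radius, self.neck_radius, *self.head_radius_range) <= 0:
            raise ConfigError("phantom radii must be positive")
        if not 0 <= self.neck_break_probability <= 1:
            raise ConfigError("phantom.neck_break_probability must be in [0, 1]")


@dataclass
class RunConfig:
    """Top-level configuration for every pipeline stage."""

    reconnect: ReconnectConfig = field(default_factory=ReconnectConfig)
    weighting: WeightingConfig = field(default_factory=WeightingConfig)
    network: UNetConfig = field(default_factory=UNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    noise_filter: NoiseFilterConfig = field(default_factory=NoiseFilterConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    seed: int = 0


def _coerce(ftype, value, path):
    origin = get_origin(ftype)
    if dataclasses.is_dataclass(ftype):
        return _build(ftype, value, path)
    if origin is tuple:
        if not isinstance(value, (list, tuple)):
            raise ConfigError(f"{path}: expected a sequence, got {type(value).__name__}")
        args = get_args(ftype)
        if args and args[-1] is not Ellipsis and len(value) != len(args):
            raise ConfigError(f"{path}: expected {len(args)} entries, got {len(value)}")
        return tuple(value)
    return value


def _build(cls, data, path=""):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown config key {(path + '.' if path else '') + key!r}")
    kwargs = {}
    for name, value in data.items():
        kwargs[name] = _coerce(_resolve(cls, name), value, (path + "." if path else "") + name)
    return cls(**kwargs)


def _resolve(cls, name):
    import typing
    hints = typing.get_type_hints(cls)
    return hints[name]


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run config; missing keys take the published defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _build(RunConfig, data)


def config_to_dict(cfg: RunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        return obj

    return clean(cfg)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
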