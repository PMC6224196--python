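"""Scene configuration: the full parameterization of a synthetic ASP scene.

A :class:`SceneConfig` describes a curved tubular epithelium of recipient
cells along a distal-proximal (D-P) axis, an exponential ligand gradient
sourced just beyond the distal tip, receptor/endosome punctum statistics,
marked clones with altered uptake, cytoneme emission parameters and the
imaging noise model.  Configs round-trip through YAML and are validated on
construction, so a schema error surfaces with the failing key path rather
than deep inside the renderer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "GradientConfig",
    "PunctaConfig",
    "CloneConfig",
    "CytonemeConfig",
    "NoiseConfig",
    "SceneConfig",
    "ConfigError",
    "load_scene_config",
    "save_scene_config",
]


class ConfigError(ValueError):
    """A configuration value violates the schema; ``key`` is the path."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"{key}: {message}")


def _require(cond: bool, key: str, message: str) -> None:
    if not cond:
        raise ConfigError(key, message)


@dataclass
class GradientConfig:
    """Exponential ligand gradient along the D-P axis (AU vs um)."""

    Cmax: float = 100.0      # amplitude at the distal tip, AU
    lam: float = 40.0        # decay length, um
    background: float = 0.0  # additive offset, AU

    def validate(self, prefix: str = "gradient") -> None:
        _require(self.Cmax >= 0, f"{prefix}.Cmax", "must be >= 0")
        _require(self.lam > 0, f"{prefix}.lambda", "decay length must be > 0")
        _require(self.background >= 0, f"{prefix}.background", "must be >= 0")

    def expected_intensity(self, distance_um):
        """Noise-free expected ligand intensity at a distance from the source."""
        import numpy as np

        d = np.asarray(distance_um, dtype=float)
        return self.background + self.Cmax * np.exp(-d / self.lam)


@dataclass
class PunctaConfig:
    density_scale: float = 2.0        # expected puncta per cell per AU of local intensity
    receptor_binding_prob: float = 1.0
    endosome_prob: float = 0.76       # P(punctum internalized into an endosome)
    amplitude: float = 60.0           # peak intensity of one punctum, AU
    sigma_um: float = 0.3             # rendered Gaussian spot sigma, um

    def validate(self, prefix: str = "puncta") -> None:
        _require(self.density_scale >= 0, f"{prefix}.density_scale", "must be >= 0")
        for name in ("receptor_binding_prob", "endosome_prob"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"{prefix}.{name}", "must be in [0, 1]")
        _require(self.amplitude >= 0, f"{prefix}.amplitude", "must be >= 0")
        _require(self.sigma_um > 0, f"{prefix}.sigma_um", "must be > 0")


@dataclass
class CloneConfig:
    """A marked clone: a 1-based inclusive cell range with altered uptake.

    The clone occupies one lateral half of each cell in ``cell_range`` so the
    mirrored region across the midline is available as an equal-area control
    ROI at the equivalent D-P position.
    """

    cell_range: tuple[int, int] = (4, 6)
    uptake_factor: float = 1.0
    label_channel: str = "clone"
    side: int = 1  # +1 / -1: which side of the midline the clone occupies

    def validate(self, prefix: str, n_cells: int) -> None:
        lo, hi = self.cell_range
        _require(1 <= lo <= hi <= n_cells, f"{prefix}.cell_range",
                 f"must satisfy 1 <= lo <= hi <= n_cells ({n_cells})")
        _require(self.uptake_factor >= 0, f"{prefix}.uptake_factor", "must be >= 0")
        _require(self.side in (-1, 1), f"{prefix}.side", "must be +1 or -1")


@dataclass
class CytonemeConfig:
    per_cell_counts: list[int] | None = None   # explicit counts; default Poisson mean below
    mean_per_cell: float = 6.0
    # proportions of the short (<15), mid (15-30) and long (>30 um) length classes
    length_mixture: tuple[float, float, float] = (0.5, 0.3, 0.2)
    length_ranges: tuple[tuple[float, float], ...] = ((2.0, 15.0), (15.0, 30.0), (30.0, 60.0))
    kappa: float = 4.0                         # von Mises concentration toward the source
    contact_puncta_mean: float = 5.0           # GRASP puncta per source-contacting trace
    noncontact_puncta_mean: float = 0.0

    def validate(self, prefix: str = "cytonemes") -> None:
        if self.per_cell_counts is not None:
            _require(all(c >= 0 for c in self.per_cell_counts),
                     f"{prefix}.per_cell_counts", "counts must be >= 0")
        _require(self.mean_per_cell >= 0, f"{prefix}.mean_per_cell", "must be >= 0")
        _require(len(self.length_mixture) == 3 and all(w >= 0 for w in self.length_mixture)
                 and sum(self.length_mixture) > 0,
                 f"{prefix}.length_mixture", "three non-negative weights, not all zero")
        _require(self.kappa >= 0, f"{prefix}.kappa", "must be >= 0")
        _require(self.contact_puncta_mean >= 0, f"{prefix}.contact_puncta_mean", "must be >= 0")


@dataclass
class NoiseConfig:
    gaussian_sd: float = 0.0   # additive read noise, AU
    poisson: bool = False      # Poisson shot noise on expected counts
    psf_sigma_um: float = 0.0  # extra Gaussian PSF blur applied to every channel

    def validate(self, prefix: str = "noise") -> None:
        _require(self.gaussian_sd >= 0, f"{prefix}.gaussian_sd", "must be >= 0")
        _require(self.psf_sigma_um >= 0, f"{prefix}.psf_sigma_um", "must be >= 0")


@dataclass
class SceneConfig:
    """Full parameterization of one synthetic multi-channel scene."""

    n_cells: int = 12
    cell_diameter: float = 10.0   # um; 12 cells -> ~120 um axis
    pixel_size: float = 0.2       # um / px
    curvature: float = 0.0        # 1/um; 0 = straight tube
    source_offset: float = 10.0   # um from the distal tip to the source center
    margin_um: float = 8.0        # canvas margin around the tube
    gradient: GradientConfig = field(default_factory=GradientConfig)
    puncta: PunctaConfig = field(default_factory=PunctaConfig)
    clones: list[CloneConfig] = field(default_factory=list)
    cytonemes: CytonemeConfig = field(default_factory=CytonemeConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    diffuse_fraction: float = 0.5  # fraction of expected intensity rendered as a smooth pool
    # optional per-cell expected ligand intensity override (AU, distal -> proximal);
    # replaces the exponential gradient, e.g. when exporting a simulated steady state
    per_cell_intensity: list[float] | None = None
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.gradient, dict):
            self.gradient = _gradient_from_dict(self.gradient)
        if isinstance(self.puncta, dict):
            self.puncta = PunctaConfig(**self.puncta)
        if isinstance(self.cytonemes, dict):
            self.cytonemes = _cytonemes_from_dict(self.cytonemes)
        if isinstance(self.noise, dict):
            self.noise = _noise_from_dict(self.noise)
        self.clones = [
            CloneConfig(**{**c, "cell_range": tuple(c["cell_range"])}) if isinstance(c, dict) else c
            for c in self.clones
        ]
        self.validate()

    def validate(self) -> None:
        _require(self.n_cells >= 2, "n_cells", "need at least 2 cells")
        _require(self.cell_diameter > 0, "cell_diameter", "must be > 0")
        _require(self.pixel_size > 0, "pixel_size", "must be > 0")
        _require(self.source_offset > 0, "source_offset", "must be > 0")
        self.gradient.validate()
        self.puncta.validate()
        self.cytonemes.validate()
        self.noise.validate()
        for k, clone in enumerate(self.clones):
            clone.validate(f"clones[{k}]", self.n_cells)
        _require(0.0 <= self.diffuse_fraction <= 1.0, "diffuse_fraction", "must be in [0, 1]")
        if self.per_cell_intensity is not None:
            _require(len(self.per_cell_intensity) == self.n_cells, "per_cell_intensity",
                     f"needs exactly n_cells ({self.n_cells}) values")
            _require(all(v >= 0 for v in self.per_cell_intensity),
                     "per_cell_intensity", "values must be >= 0")

    @property
    def axis_length(self) -> float:
        """Arc length of the D-P axis in um."""
        return self.n_cells * self.cell_diameter

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["gradient"]["lambda"] = d["gradient"].pop("lam")
        d["noise"]["psf_sigma"] = d["noise"].pop("psf_sigma_um")
        for c in d["clones"]:
            c["cell_range"] = list(c["cell_range"])
        d["cytonemes"]["length_mixture"] = list(d["cytonemes"]["length_mixture"])
        d["cytonemes"]["length_ranges"] = [list(r) for r in d["cytonemes"]["length_ranges"]]
        return d


def _gradient_from_dict(d: dict) -> GradientConfig:
    d = dict(d)
    if "lambda" in d:
        d["lam"] = d.pop("lambda")
    return GradientConfig(**d)


def _noise_from_dict(d: dict) -> NoiseConfig:
    d = dict(d)
    if "psf_sigma" in d:
        d["psf_sigma_um"] = d.pop("psf_sigma")
    return NoiseConfig(**d)


def _cytonemes_from_dict(d: dict) -> CytonemeConfig:
    d = dict(d)
    if "length_mixture" in d:
        d["length_mixture"] = tuple(d["length_mixture"])
    if "length_ranges" in d:
        d["length_ranges"] = tuple(tuple(r) for r in d["length_ranges"])
    return CytonemeConfig(**d)


def scene_config_from_dict(d: dict[str, Any]) -> SceneConfig:
    known = {f.name for f in dataclasses.fields(SceneConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(sorted(unknown)[0], "unknown configuration key")
    return SceneConfig(**d)


def load_scene_config(path) -> SceneConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("<root>", "scene config must be a YAML mapping")
    return scene_config_from_dict(raw)


def save_scene_config(config: SceneConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
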