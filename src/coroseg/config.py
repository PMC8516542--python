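"""Pipeline configuration: every tunable of every stage, with defaults.

A config file is a flat YAML mapping of ``section_field: value`` keys
(e.g. ``vesselness_beta: 0.7``, ``track_d: 5``); every key has a default,
so an empty file (or no file) is a valid configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "DenoiseParams",
    "UnsharpParams",
    "ClaheParams",
    "VesselnessParams",
    "CVParams",
    "RidgeParams",
    "TrackParams",
    "PipelineConfig",
    "load_config",
]


@dataclass
class DenoiseParams:
    """Collaborative block-matching filter parameters.

    ``noise_sigma`` is the assumed additive-noise standard deviation on the
    [0, 255] intensity scale; 0 disables the stage (identity).
    """

    noise_sigma: float = 10.0
    block_size: int = 8
    search_window: int = 11
    max_group: int = 8
    ref_stride: int = 3
    threshold_factor: float = 2.7

    def validate(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.block_size > self.search_window + self.block_size - 1:
            raise ValueError("block_size must fit in the search window")
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if self.max_group < 1:
            raise ValueError("max_group must be >= 1")


@dataclass
class UnsharpParams:
    """Unsharp masking: g = I + k * (I - lowpass(I))."""

    k: float = 0.8
    lowpass_kernel_size: int = 9

    def validate(self) -> None:
        if self.k < 0:
            raise ValueError("enlarge coefficient k must be >= 0")
        ks = self.lowpass_kernel_size
        if ks < 3 or ks % 2 == 0:
            raise ValueError("lowpass_kernel_size must be odd and >= 3")


@dataclass
class ClaheParams:
    """Contrast-limited adaptive histogram equalization.

    ``clip_limit`` is a multiple of the uniform bin height of a tile
    histogram; 1.0 clips everything to uniform, large values never clip.
    """

    clip_limit: float = 1.5
    tile_rows: int = 8
    tile_cols: int = 8
    n_bins: int = 256

    def validate(self) -> None:
        if self.clip_limit < 1:
            raise ValueError("clip_limit must be >= 1")
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise ValueError("tile counts must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class VesselnessParams:
    """Multiscale Hessian vesselness (tube-likeness) filter parameters.

    beta weights the blobness ratio |l1|/|l2|, c the Hessian-norm
    (structure) term, and m an extra damping factor that is neutral at 0.
    Scales are Gaussian sigmas in pixels, sampled uniformly on
    [sigma_min, sigma_max]; gamma_norm is the derivative-normalization
    exponent that makes responses comparable across scales.
    """

    beta: float = 0.5
    c: float = 20.0
    m: float = 0.0
    sigma_min: float = 1.0
    sigma_max: float = 10.0
    n_scales: int = 10
    gamma_norm: float = 2.0

    def validate(self) -> None:
        if self.beta <= 0 or self.c <= 0:
            raise ValueError("beta and c must be > 0")
        if self.m < 0:
            raise ValueError("m must be >= 0")
        if self.sigma_min > self.sigma_max or self.sigma_min <= 0:
            raise ValueError("need 0 < sigma_min <= sigma_max")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")


@dataclass
class CVParams:
    """Chan-Vese level-set segmentation parameters.

    u and v weight the contour-length and inside-area terms on the
    [0, 255] intensity-squared scale; lambda0/lambdab weight the outside/
    inside fit terms; epsilon is the Heaviside regularization width in
    pixels.
    """

    u: float = 0.2 * 255.0**2
    v: float = 0.0
    lambda0: float = 1.0
    lambdab: float = 1.0
    epsilon: float = 1.5
    dt: float = 0.5
    max_iter: int = 1500
    tol: float = 1e-5
    reinit_every: int = 0

    def validate(self) -> None:
        if self.lambda0 <= 0 or self.lambdab <= 0:
            raise ValueError("lambda0 and lambdab must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class RidgeParams:
    """Ridge detection and scattered-point prefiltering.

    gray_threshold screens ridge candidates on the enhanced image
    (shared intensity floor with the tracker's I0); a ridge point is kept
    only if at least tau_R other ridge points lie within
    neighborhood_radius_R pixels.
    """

    gray_threshold: float = 10.0
    tau_R: int = 3
    neighborhood_radius_R: float = 3.0

    def validate(self) -> None:
        if self.tau_R < 0:
            raise ValueError("tau_R must be >= 0")
        if self.neighborhood_radius_R <= 0:
            raise ValueError("neighborhood_radius_R must be > 0")


@dataclass
class TrackParams:
    """Adaptive centerline tracking parameters (pixel units, degrees).

    d is both the step length and the arc-search radius; delta_theta the
    forward arc half-angle; I0 the intensity floor on the enhanced image;
    tau_P the loop-guard count; (r1, r2, delta_theta_prime) the fan-ring
    search region for bifurcations; tau1/tau2 the minimum angle gaps a new
    branch must open with the current and previous directions; tau_B caps
    duplicate bifurcations within nb_radius.
    """

    d: float = 5.0
    delta_theta: float = 45.0
    I0: float = 10.0
    tau_P: int = 4
    r1: float = 7.0
    r2: float = 12.0
    delta_theta_prime: float = 135.0
    tau1: float = 45.0
    tau2: float = 30.0
    tau_B: int = 2
    arc_step_deg: float = 1.0
    np_radius: float = 5.0
    nb_radius: float = 12.0
    max_ray: float = 20.0
    max_points: int = 5000

    def validate(self) -> None:
        if not (0 < self.delta_theta < 90):
            raise ValueError("delta_theta must be in (0, 90)")
        if not (0 < self.delta_theta_prime <= 180):
            raise ValueError("delta_theta_prime must be in (0, 180]")
        if not (0 < self.r1 < self.r2):
            raise ValueError("need 0 < r1 < r2")
        for name in ("d", "I0", "arc_step_deg", "np_radius", "nb_radius", "max_ray"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tau_P < 1 or self.tau_B < 1:
            raise ValueError("tau_P and tau_B must be >= 1")


_SECTIONS = {
    "denoise": DenoiseParams,
    "unsharp": UnsharpParams,
    "clahe": ClaheParams,
    "vesselness": VesselnessParams,
    "cv": CVParams,
    "ridge": RidgeParams,
    "track": TrackParams,
}


@dataclass
class PipelineConfig:
    """Aggregate of all stage parameters plus pipeline-level switches."""

    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    unsharp: UnsharpParams = field(default_factory=UnsharpParams)
    clahe: ClaheParams = field(default_factory=ClaheParams)
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    cv: CVParams = field(default_factory=CVParams)
    ridge: RidgeParams = field(default_factory=RidgeParams)
    track: TrackParams = field(default_factory=TrackParams)
    vessel_polarity: str = "dark"
    rng_seed: int = 0
    enable_denoise: bool = True
    enable_unsharp: bool = True
    enable_clahe: bool = True
    cv_init: str = "checkerboard"

    def validate(self) -> None:
        if self.vessel_polarity not in ("dark", "bright"):
            raise ValueError("vessel_polarity must be 'dark' or 'bright'")
        if self.cv_init not in ("checkerboard", "circle"):
            raise ValueError("cv_init must be 'checkerboard' or 'circle'")
        for name in _SECTIONS:
            getattr(self, name).validate()

    @classmethod
    def from_dict(cls, flat: dict) -> "PipelineConfig":
        """Build a config from a flat ``section_field: value`` mapping."""
        cfg = cls()
        top_fields = {
            "vessel_polarity", "rng_seed", "enable_denoise",
            "enable_unsharp", "enable_clahe", "cv_init",
        }
        for key, value in (flat or {}).items():
            if key in top_fields:
                setattr(cfg, key, value)
                continue
            for section, klass in _SECTIONS.items():
                prefix = section + "_"
                if key.startswith(prefix):
                    fname = key[len(prefix):]
                    if fname not in {f.name for f in dataclasses.fields(klass)}:
                        raise KeyError(f"unknown config key: {key}")
                    setattr(getattr(cfg, section), fname, value)
                    break
            else:
                raise KeyError(f"unknown config key: {key}")
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        flat: dict = {
            "vessel_polarity": self.vessel_polarity,
            "rng_seed": self.rng_seed,
            "enable_denoise": self.enable_denoise,
            "enable_unsharp": self.enable_unsharp,
            "enable_clahe": self.enable_clahe,
            "cv_init": self.cv_init,
        }
        for section, _ in _SECTIONS.items():
            params = getattr(self, section)
            for f in dataclasses.fields(params):
                flat[f"{section}_{f.name}"] = getattr(params, f.name)
        return flat


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a flat YAML config; ``None`` or an empty file yields defaults."""
    if path is None:
        cfg = PipelineConfig()
        cfg.validate()
        return cfg
    with open(path) as fh:
        flat = yaml.safe_load(fh)
    return PipelineConfig.from_dict(flat or {})
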