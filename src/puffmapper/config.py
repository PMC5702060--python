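"""Pipeline and simulation configuration.

All detection constants default to the values the method was developed
with: 25 Hz acquisition (40 ms frames), 160 nm pixels, 50 pre-stimulus
frames for the baseline, thresholds T1 = mu + 3.4*sd and T2 = mu + 2.45*sd
on the delta-delta-F stack, a 5x5 candidate matrix requiring >= 18
supra-T2 pixels, a 10% line-occupancy fraction for boundary expansion,
and a 0.96 um (6 px) site merge radius.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml

logger = logging.getLogger("puffmapper")
if not logger.handlers:  # library default: quiet unless app configures logging
    logger.addHandler(logging.NullHandler())


@dataclass
class PipelineConfig:
    """Constants for preprocessing, puff detection, site mapping and stats.

    Units: seconds and micrometres throughout; frames are 0-based indices.
    """

    frame_interval: float = 0.040   # s/frame (25 Hz)
    pixel_size: float = 0.160       # um/pixel
    n_pre: int = 50                 # pre-stimulus frames used for F0
    stim_start_frame: int = 50      # first stimulated frame (config-supplied)
    t1_mult: float = 3.4            # T1 = mu + t1_mult * sd
    t2_mult: float = 2.45           # T2 = mu + t2_mult * sd
    matrix_size: int = 5            # candidate matrix side (pixels)
    min_supra: int = 18             # min supra-T2 pixels of matrix_size**2
    line_frac: float = 0.10         # row/column occupancy for expansion
    merge_radius_um: float = 0.96   # SiteMapper amalgamation radius (6 px)
    analysis_window_s: float = 2.0  # quantitative window before wave/end
    wave_k: float = 10.0            # wave onset: k baseline s.d. above mean
    wave_m: int = 5                 # consecutive frames above to call onset
    wave_min_rise: float = 0.3      # floor on the onset threshold (F/F0 units)
    site_recentre: str = "bbox"     # "bbox" (default) or "mean"
    dtype: str = "float64"          # derived-stack dtype ("float32" for big movies)

    def validate(self) -> None:
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")
        if self.n_pre < 1:
            raise ValueError("n_pre must be >= 1")
        if self.matrix_size < 1 or self.matrix_size % 2 == 0:
            raise ValueError("matrix_size must be a positive odd integer")
        if not (1 <= self.min_supra <= self.matrix_size ** 2):
            raise ValueError("min_supra must lie in [1, matrix_size**2]")
        if not (0 < self.line_frac < 1):
            raise ValueError("line_frac must lie in (0, 1)")
        if self.merge_radius_um <= 0:
            raise ValueError("merge_radius_um must be positive")
        if self.site_recentre not in ("bbox", "mean"):
            raise ValueError("site_recentre must be 'bbox' or 'mean'")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")

    @property
    def merge_radius_px(self) -> float:
        return self.merge_radius_um / self.pixel_size

    @property
    def analysis_window_frames(self) -> int:
        return int(round(self.analysis_window_s / self.frame_interval))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic TIRF movie generator.

    Defaults emulate the acquisition the detector was designed for:
    40 ms frames, 160 nm pixels, 50 pre-stimulus frames, puffs rising to
    peak in one frame and decaying over a few hundred ms with ~0.55 um
    Gaussian footprints, an optional creeping global rise and terminal
    wave, and additive Gaussian camera noise.
    """

    n_frames: int = 300
    frame_interval: float = 0.040        # s
    pixel_size: float = 0.160            # um
    image_shape: Tuple[int, int] = (128, 128)
    n_sites: int = 30
    pre_stim_frames: int = 50
    noise_sd: float = 50.0               # camera counts
    baseline: float = 1000.0             # in-cell resting fluorescence
    bg_level: float = 100.0              # extracellular level
    drift_rate: float = 0.0              # creeping F/F0 rise per s of stimulation
    wave_onset_frame: Optional[int] = None
    rng_seed: int = 0

    # geometry / kinetics
    cell_radius_um: float = 10.0         # mean radius of the simulated cell
    min_separation_um: float = 2.0       # between planted sites
    firing_rate: float = 0.5             # events/s per site during stimulation
    puff_amplitude_mean: float = 1.0     # peak dF/F0
    puff_amplitude_sd: float = 0.3
    puff_amplitude_min: float = 0.3
    spatial_sigma_um: float = 0.55       # Gaussian sd of rendered puffs
    decay_tau_s: float = 0.25            # exponential decay constant
    rise_frames: int = 1                 # frames to reach peak (robustness knob)
    wave_amplitude: float = 3.0          # F/F0 units of the terminal wave
    wave_speed_um_s: float = 15.0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")
        if min(self.image_shape) < 8:
            raise ValueError("image_shape too small")
        if self.pre_stim_frames < 0:
            raise ValueError("pre_stim_frames must be >= 0")
        if self.noise_sd < 0 or self.baseline <= 0 or self.bg_level < 0:
            raise ValueError("noise_sd >= 0, baseline > 0, bg_level >= 0 required")
        if self.spatial_sigma_um <= 0 or self.decay_tau_s <= 0:
            raise ValueError("spatial_sigma_um and decay_tau_s must be positive")
        if self.rise_frames < 1:
            raise ValueError("rise_frames must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
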