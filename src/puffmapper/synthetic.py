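"""Synthetic TIRF movie generator with ground truth.

Simulates the fluorescence signal a calcium indicator reports during
agonist stimulation: immobile release sites scattered on a cell footprint,
Ca2+ puffs firing at each site as a homogeneous Poisson process, each puff
an isotropic 2D Gaussian in space that steps to its peak within one
inter-frame interval and decays exponentially, a slowly creeping global
rise that may culminate in a propagating wave, and additive Gaussian pixel
noise. Ground truth (site positions, every puff's onset/amplitude) is
returned as a manifest so detection, clustering and abundance estimation
can be validated end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import SimulationConfig


@dataclass
class GroundTruthSite:
    """An immobile release site planted in the simulated cell."""

    id: int
    position: Tuple[float, float]  # (x, y) in um
    firing_rate: float             # events/s during stimulation

    def __post_init__(self):
        if self.firing_rate < 0:
            raise ValueError("firing_rate must be >= 0")


@dataclass
class GroundTruthPuff:
    """One scheduled puff: where, when and how big."""

    site_id: int
    onset_frame: int
    peak_amplitude: float   # dF/F0 units
    spatial_sigma: float    # um
    decay_tau: float        # s
    position: Tuple[float, float] = (0.0, 0.0)  # (x, y) um, copied from site

    def __post_init__(self):
        if self.spatial_sigma <= 0 or self.decay_tau <= 0:
            raise ValueError("spatial_sigma and decay_tau must be positive")


@dataclass
class ImageStack:
    """A fluorescence time series with acquisition metadata."""

    data: np.ndarray        # (frames, rows, cols)
    frame_interval: float   # s
    pixel_size: float       # um

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be 3D (frames, rows, cols)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


def generate_cell_mask(config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None
                       ) -> Tuple[np.ndarray, float]:
    """Generate a simply connected cell footprint.

    The cell is a star-convex blob: a disc of radius ``cell_radius_um``
    whose boundary is modulated by three low-order harmonics (+-8%),
    centred in the field. Returns ``(mask, area_um2)`` with
    ``area = true pixels * pixel_size**2``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    rows, cols = config.image_shape
    r_px = config.cell_radius_um / config.pixel_size
    if 2 * r_px + 2 > min(rows, cols):
        raise ValueError(
            f"image_shape {config.image_shape} too small for a cell of "
            f"radius {config.cell_radius_um} um at {config.pixel_size} um/px")
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    yy, xx = np.mgrid[0:rows, 0:cols]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    amp = rng.uniform(0.0, 0.08 / 3, size=3)  # total wobble bounded at 8%
    phase = rng.uniform(0, 2 * np.pi, size=3)
    wobble = sum(a * np.cos((k + 2) * theta + p)
                 for k, (a, p) in enumerate(zip(amp, phase)))
    r_bound = r_px * (1.0 + wobble)
    mask = (dx ** 2 + dy ** 2) <= r_bound ** 2
    area = float(mask.sum()) * config.pixel_size ** 2
    return mask, area


def mask_area_um2(mask: np.ndarray, pixel_size: float) -> float:
    """Area of a binary mask in um^2 (pixel count times pixel area)."""
    return float(np.count_nonzero(mask)) * pixel_size ** 2


def place_sites(mask: np.ndarray, n_sites: int, min_separation: float,
                pixel_size: float, rng: np.random.Generator,
                firing_rate: float = 0.5,
                max_attempts_per_site: int = 2000) -> List[GroundTruthSite]:
    """Scatter immobile sites uniformly on the mask with a minimum spacing.

    Positions are in um (x = column, y = row, 0-based pixel grid). Raises
    if the requested packing cannot be achieved within the retry budget.
    """
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    in_rows, in_cols = np.nonzero(mask)
    if in_rows.size == 0:
        raise ValueError("mask is empty")
    placed: List[Tuple[float, float]] = []
    attempts_left = max_attempts_per_site * max(n_sites, 1)
    while len(placed) < n_sites:
        if attempts_left <= 0:
            raise RuntimeError(
                f"could not place {n_sites} sites at separation "
                f"{min_separation} um; placed {len(placed)}")
        attempts_left -= 1
        i = rng.integers(0, in_rows.size)
        # uniform sub-pixel jitter within the chosen in-mask pixel
        y = (in_rows[i] + rng.uniform(-0.5, 0.5)) * pixel_size
        x = (in_cols[i] + rng.uniform(-0.5, 0.5)) * pixel_size
        ok = all((x - px) ** 2 + (y - py) ** 2 >= min_separation ** 2
                 for px, py in placed)
        if ok:
            placed.append((x, y))
    return [GroundTruthSite(id=i, position=pos, firing_rate=firing_rate)
            for i, pos in enumerate(placed)]


def schedule_puffs(sites: Sequence[GroundTruthSite],
                   stim_window: Tuple[int, int],
                   config: SimulationConfig,
                   rng: np.random.Generator) -> List[GroundTruthPuff]:
    """Draw puff onsets per site as a homogeneous Poisson process.

    ``stim_window`` is a half-open frame interval [start, end). Each site
    fires Poisson(rate * duration) puffs at uniform times in the window.
    Amplitudes are Gaussian around ``puff_amplitude_mean`` clipped at
    ``puff_amplitude_min``.
    """
    start, end = stim_window
    if not (0 <= start <= end <= config.n_frames):
        raise ValueError("stim_window must lie within the stack")
    duration_s = (end - start) * config.frame_interval
    puffs: List[GroundTruthPuff] = []
    for site in sites:
        n = rng.poisson(site.firing_rate * duration_s)
        for _ in range(n):
            onset = int(start + rng.integers(0, max(end - start, 1)))
            amp = float(max(rng.normal(config.puff_amplitude_mean,
                                       config.puff_amplitude_sd),
                            config.puff_amplitude_min))
            puffs.append(GroundTruthPuff(
                site_id=site.id, onset_frame=onset, peak_amplitude=amp,
                spatial_sigma=config.spatial_sigma_um,
                decay_tau=config.decay_tau_s, position=site.position))
    puffs.sort(key=lambda p: (p.onset_frame, p.site_id))
    return puffs


def _render_one_puff(data: np.ndarray, puff: GroundTruthPuff,
                     config: SimulationConfig, baseline: float) -> None:
    """Add one puff (in camera counts) into ``data`` in place."""
    px = config.pixel_size
    sig_px = puff.spatial_sigma / px
    x0, y0 = puff.position[0] / px, puff.position[1] / px
    half = int(math.ceil(4 * sig_px))
    rows, cols = data.shape[1:]
    r0 = max(int(round(y0)) - half, 0)
    r1 = min(int(round(y0)) + half + 1, rows)
    c0 = max(int(round(x0)) - half, 0)
    c1 = min(int(round(x0)) + half + 1, cols)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    kernel = np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sig_px ** 2))
    dt = config.frame_interval
    n_decay = int(math.ceil(8 * puff.decay_tau / dt))
    f0 = puff.onset_frame
    f1 = min(f0 + n_decay + 1, data.shape[0])
    frames = np.arange(f0, f1)
    # linear rise over rise_frames, then exponential decay from the peak
    rise = config.rise_frames
    peak_frame = f0 + rise - 1
    g = np.where(frames <= peak_frame,
                 (frames - f0 + 1) / rise,
                 np.exp(-(frames - peak_frame) * dt / puff.decay_tau))
    # pre-onset rise frames for rise > 1 are inside [f0, peak]; nothing before f0
    data[f0:f1, r0:r1, c0:c1] += (
        baseline * puff.peak_amplitude
        * g[:, None, None].astype(data.dtype) * kernel[None, :, :].astype(data.dtype))


def render_stack(config: SimulationConfig, mask: np.ndarray,
                 puffs: Sequence[GroundTruthPuff],
                 sites: Optional[Sequence[GroundTruthSite]] = None,
                 rng: Optional[np.random.Generator] = None,
                 dtype=np.float64) -> Tuple[ImageStack, dict]:
    """Render the movie and its ground-truth manifest.

    Signal model, per pixel inside the cell::

        F = baseline * (ramp_t + sum_puffs a * G(x, y) * g(t) + wave)

    with ``G`` an isotropic Gaussian of sd ``spatial_sigma``, ``g`` a
    one-frame (configurable) rise followed by exp(-t/tau) decay, ``ramp_t``
    a spatially uniform multiplicative drift starting at stimulation, and
    an optional saturating radial wave front after ``wave_onset_frame``.
    Extracellular pixels hold ``bg_level`` plus noise only. i.i.d.
    Gaussian noise of sd ``noise_sd`` is added everywhere.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    rows, cols = config.image_shape
    if mask.shape != (rows, cols):
        raise ValueError("mask shape does not match image_shape")
    n = config.n_frames
    for p in puffs:
        if not (0 <= p.onset_frame < n):
            raise ValueError("puff onset outside the stack")

    data = np.empty((n, rows, cols), dtype=dtype)
    data[:] = np.where(mask, config.baseline, config.bg_level)
    if config.drift_rate != 0.0:
        # spatially uniform multiplicative ramp inside the cell
        t_since_stim = np.maximum(
            np.arange(n) - config.pre_stim_frames, 0) * config.frame_interval
        ramp = 1.0 + config.drift_rate * t_since_stim
        data[:, mask] = (config.baseline * ramp)[:, None]

    for puff in puffs:
        _render_one_puff(data, puff, config, config.baseline)

    wave_origin = None
    if config.wave_onset_frame is not None:
        w0 = int(config.wave_onset_frame)
        if sites:
            i = int(rng.integers(0, len(sites)))
            wave_origin = sites[i].position
        else:
            yy, xx = np.nonzero(mask)
            i = int(rng.integers(0, yy.size))
            wave_origin = (xx[i] * config.pixel_size, yy[i] * config.pixel_size)
        yy, xx = np.mgrid[0:rows, 0:cols]
        r_um = np.hypot(xx * config.pixel_size - wave_origin[0],
                        yy * config.pixel_size - wave_origin[1])
        for f in range(w0, n):
            front = config.wave_speed_um_s * (f - w0 + 1) * config.frame_interval
            s = 1.0 / (1.0 + np.exp((r_um - front) / 0.8))
            data[f][mask] += config.baseline * config.wave_amplitude * s[mask]

    if config.noise_sd > 0:
        noise_dtype = np.float32 if np.dtype(dtype) == np.float32 else np.float64
        noise = rng.standard_normal(size=data.shape, dtype=noise_dtype)
        noise *= config.noise_sd
        data += noise

    stack = ImageStack(data=data, frame_interval=config.frame_interval,
                       pixel_size=config.pixel_size)
    manifest = {
        "config": config.to_dict(),
        "cell_area_um2": mask_area_um2(mask, config.pixel_size),
        "wave_origin_um": list(wave_origin) if wave_origin else None,
        "sites": [
            {"id": s.id, "x_um": s.position[0], "y_um": s.position[1],
             "firing_rate": s.firing_rate}
            for s in (sites or [])],
        "puffs": [
            {"site_id": p.site_id, "onset_frame": p.onset_frame,
             "peak_amplitude": p.peak_amplitude,
             "spatial_sigma_um": p.spatial_sigma, "decay_tau_s": p.decay_tau,
             "x_um": p.position[0], "y_um": p.position[1]}
            for p in puffs],
    }
    return stack, manifest


def simulate_movie(config: SimulationConfig,
                   stim_window: Optional[Tuple[int, int]] = None,
                   dtype=np.float64
                   ) -> Tuple[ImageStack, np.ndarray, dict]:
    """Convenience wrapper: mask -> sites -> puff schedule -> rendered movie.

    Returns ``(stack, mask, manifest)``. The stimulation window defaults to
    [pre_stim_frames, wave_onset_frame or n_frames).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    mask, _area = generate_cell_mask(config, rng)
    sites = place_sites(mask, config.n_sites, config.min_separation_um,
                        config.pixel_size, rng,
                        firing_rate=config.firing_rate)
    if stim_window is None:
        end = config.n_frames
        if config.wave_onset_frame is not None:
            end = min(end, int(config.wave_onset_frame))
        stim_window = (config.pre_stim_frames, end)
    puffs = schedule_puffs(sites, stim_window, config, rng)
    stack, manifest = render_stack(config, mask, puffs, sites=sites, rng=rng,
                                   dtype=dtype)
    manifest["stim_window"] = list(stim_window)
    return stack, mask, manifest
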