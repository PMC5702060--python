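"""Preprocessing: from a raw movie to the delta-delta-F stack and thresholds.

The chain is: per-frame background subtraction (mean of an extracellular
ROI), cell masking, optional 2x2 spatial smoothing, per-pixel baseline F0
from the pre-stimulus frames, F/F0 normalisation, frame-to-frame
differencing (dF), subtraction of the per-frame cell-mean dF (ddF, which
removes any creeping global rise), and per-pixel temporal mean/sd maps
from which the detection thresholds T1 and T2 are derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .config import PipelineConfig, logger
from .synthetic import ImageStack


@dataclass
class CellROI:
    """A single cell's binary footprint."""

    mask: np.ndarray
    pixel_size: float
    id: int = 0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("cell mask is empty")

    @property
    def area(self) -> float:
        """um^2: true-pixel count times pixel area."""
        return float(np.count_nonzero(self.mask)) * self.pixel_size ** 2


@dataclass
class DerivedStacks:
    """Per-cell derived quantities consumed by the puff detector.

    ``deltaF``/``deltadeltaF`` have one fewer frame than ``ratio``;
    difference frame ``n`` is ratio[n+1] - ratio[n], so an intensity step
    at stack frame k appears at difference frame k - 1.
    """

    F0_map: np.ndarray
    ratio: np.ndarray
    deltaF: np.ndarray
    deltadeltaF: np.ndarray
    mu_map: np.ndarray
    sd_map: np.ndarray
    T1_map: np.ndarray
    T2_map: np.ndarray
    mask: np.ndarray           # effective mask (F0 > 0 pixels only)
    stats_frames: int          # number of ddF frames used for mu/sd


def subtract_background(stack: ImageStack,
                        bg_roi: Tuple[int, int, int, int],
                        cell_mask: Optional[np.ndarray] = None) -> ImageStack:
    """Subtract, per frame, the mean over an extracellular rectangle.

    ``bg_roi`` is (row0, row1, col0, col1), half-open. Raises if the ROI
    overlaps the provided cell mask. Output may contain small negatives.
    """
    r0, r1, c0, c1 = bg_roi
    rows, cols = stack.data.shape[1:]
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError("bg_roi out of bounds or empty")
    if cell_mask is not None and cell_mask[r0:r1, c0:c1].any():
        raise ValueError("background ROI overlaps the cell mask")
    bg = stack.data[:, r0:r1, c0:c1].mean(axis=(1, 2))
    out = stack.data - bg[:, None, None]
    return ImageStack(out, stack.frame_interval, stack.pixel_size)


def apply_cell_mask(stack: ImageStack, roi: CellROI) -> ImageStack:
    """Zero every extracellular pixel; in-mask pixels are unchanged."""
    if roi.mask.shape != stack.data.shape[1:]:
        raise ValueError("mask shape does not match frames")
    out = stack.data * roi.mask[None, :, :]
    return ImageStack(out, stack.frame_interval, stack.pixel_size)


def smooth_2x2(stack: ImageStack) -> ImageStack:
    """2x2 box mean per frame, output anchored at the window's top-left.

    The bottom/right edges are replicate-padded so the shape is preserved.
    Smoothing is purely spatial; no mixing across time.
    """
    data = stack.data
    if data.shape[1] < 2 or data.shape[2] < 2:
        raise ValueError("frames must be at least 2x2")
    padded = np.pad(data, ((0, 0), (0, 1), (0, 1)), mode="edge")
    out = (padded[:, :-1, :-1] + padded[:, :-1, 1:]
           + padded[:, 1:, :-1] + padded[:, 1:, 1:]) / 4.0
    return ImageStack(out, stack.frame_interval, stack.pixel_size)


def compute_F0(stack: ImageStack, n_pre: int = 50) -> np.ndarray:
    """Per-pixel temporal mean of the first ``n_pre`` (pre-stimulus) frames."""
    if n_pre < 1:
        raise ValueError("n_pre must be >= 1")
    if stack.n_frames < n_pre:
        raise ValueError(
            f"stack has {stack.n_frames} frames, fewer than n_pre={n_pre}")
    return stack.data[:n_pre].mean(axis=0)


def compute_ratio(stack: ImageStack, F0_map: np.ndarray,
                  mask: np.ndarray) -> np.ndarray:
    """Elementwise F/F0 inside the mask; exactly 0 outside.

    Raises if F0 <= 0 anywhere inside the mask (such pixels should have
    been dropped from the mask upstream).
    """
    if np.any(F0_map[mask] <= 0):
        raise ValueError("F0 <= 0 inside the mask; exclude those pixels first")
    ratio = np.zeros_like(stack.data)
    ratio[:, mask] = stack.data[:, mask] / F0_map[mask]
    return ratio


def compute_deltaF(ratio: np.ndarray) -> np.ndarray:
    """Frame-to-frame difference of F/F0: dF[n] = ratio[n+1] - ratio[n]."""
    if ratio.shape[0] < 2:
        raise ValueError("need at least 2 ratio frames")
    return np.diff(ratio, axis=0)


def compute_deltadeltaF(deltaF: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Subtract the per-frame in-mask mean of dF from every in-mask pixel.

    The result has zero mean over the mask in every frame; extracellular
    pixels are 0.
    """
    if not mask.any():
        raise ValueError("mask is empty")
    out = np.zeros_like(deltaF)
    vals = deltaF[:, mask]
    out[:, mask] = vals - vals.mean(axis=1, dtype=np.float64, keepdims=True)
    return out


def compute_thresholds(deltadeltaF: np.ndarray, t1_mult: float = 3.4,
                       t2_mult: float = 2.45,
                       stats_frames: Optional[int] = None
                       ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel temporal mean/sd of ddF and the thresholds derived from them.

    T1 = mu + t1_mult*sd and T2 = mu + t2_mult*sd. ``stats_frames`` limits
    the statistics to the first frames (e.g. those before a global wave).
    Returns (mu_map, sd_map, T1_map, T2_map).
    """
    sub = deltadeltaF if stats_frames is None else deltadeltaF[:stats_frames]
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 ddF frames for mu/sd")
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    return mu, sd, mu + t1_mult * sd, mu + t2_mult * sd


def derive_stacks(stack: ImageStack, roi: CellROI, config: PipelineConfig,
                  smooth: bool = True,
                  bg_roi: Optional[Tuple[int, int, int, int]] = None,
                  stats_frames: Optional[int] = None) -> DerivedStacks:
    """Run the whole preprocessing chain for one cell.

    ``smooth=True`` gives the 2x2-smoothed stacks used to seed candidate
    matrices; ``smooth=False`` gives the unsmoothed stacks retained for
    puff measurement. Pixels whose F0 is <= 0 inside the mask (possible
    after background subtraction) are dropped from the effective mask with
    a warning.
    """
    config.validate()
    work = stack
    if bg_roi is not None:
        work = subtract_background(work, bg_roi, roi.mask)
    work = apply_cell_mask(work, roi)
    if smooth:
        work = smooth_2x2(work)
    dtype = np.dtype(config.dtype)
    if work.data.dtype != dtype:
        work = ImageStack(work.data.astype(dtype), work.frame_interval,
                          work.pixel_size)
    F0 = compute_F0(work, config.n_pre)
    eff_mask = roi.mask & (F0 > 0)
    n_bad = int(roi.mask.sum() - eff_mask.sum())
    if n_bad:
        warnings.warn(f"{n_bad} in-mask pixels had F0 <= 0 and were excluded")
    if not eff_mask.any():
        raise ValueError("no usable pixels: F0 <= 0 everywhere in the mask")
    ratio = compute_ratio(work, F0, eff_mask)
    dF = compute_deltaF(ratio)
    ddF = compute_deltadeltaF(dF, eff_mask)
    nstats = ddF.shape[0] if stats_frames is None else min(stats_frames,
                                                           ddF.shape[0])
    mu, sd, T1, T2 = compute_thresholds(ddF, config.t1_mult, config.t2_mult,
                                        stats_frames=nstats)
    logger.debug("derive_stacks: %d ddF frames, mu/sd over %d frames, "
                 "%d usable pixels", ddF.shape[0], nstats, eff_mask.sum())
    return DerivedStacks(F0_map=F0, ratio=ratio, deltaF=dF, deltadeltaF=ddF,
                         mu_map=mu, sd_map=sd, T1_map=T1, T2_map=T2,
                         mask=eff_mask, stats_frames=nstats)
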