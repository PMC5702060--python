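"""Ca2+ puff detection on the delta-delta-F stack.

Detection proceeds per difference frame: every in-mask pixel exceeding the
upper threshold T1 is a potential puff centre. Pixels are visited in
descending ddF order; each seeds a 5x5 binary matrix counting neighbours
above the lower threshold T2, and the matrix is accepted when at least 18
of its 25 pixels are supra-T2 (the count is rescaled proportionally where
the matrix is clipped by the image or mask edge). Accepted matrices are
ranked by their supra-T2 count, ties broken by signal mass. Each accepted
candidate's rectangular extent is then delineated by outward boundary
expansion, candidates in consecutive frames are merged into single events,
and each event is measured (2D elliptical Gaussian fit, amplitude, signal
mass, half-max duration) on the unsmoothed stack.

Exact rule set (shared by the brute-force oracle used in the tests):

* ranking of supra-T1 seeds: ddF descending, ties by (row, col);
* a seed is skipped when its matrix window would share any pixel with an
  already accepted candidate's footprint in the same frame, so accepted
  footprints are pixel-disjoint;
* acceptance: v_sum >= ceil(min_supra / matrix_size**2 * available) where
  ``available`` counts in-image, in-mask pixels of the clipped window;
* boundary expansion from a 3x3 box centred on the seed —
  pass 1: grow left then right while the adjacent column has at least one
  supra-T2 pixel (within the current row span); then grow up then down
  while the adjacent row's supra-T2 fraction is >= line_frac;
  pass 2 (columns then rows): keep growing outward while the adjacent
  line's supra-T2 fraction is strictly greater than line_frac; lines added
  in pass 1 are never removed;
* candidates whose centre pixel already lies inside an expanded rectangle
  of the same frame are not expanded again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .config import PipelineConfig, logger
from .preprocess import CellROI, DerivedStacks, derive_stacks
from .synthetic import ImageStack

Rect = Tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open


@dataclass
class CandidateMatrix:
    """An accepted 5x5 candidate matrix in one difference frame."""

    frame: int                    # ddF frame index
    center: Tuple[int, int]       # (row, col)
    v_sum: int                    # supra-T2 pixels in the (clipped) window
    signal_mass: float            # sum of ddF over supra-T2 window pixels
    footprint: Rect = (0, 0, 0, 0)


@dataclass
class GaussianFit:
    """Elliptical 2D Gaussian fit result, in region pixel coordinates."""

    x0: float
    y0: float
    sigma_major: float
    sigma_minor: float
    theta: float        # radians, major-axis angle from the x (column) axis, mod pi
    amplitude: float
    offset: float
    fallback: bool = False


@dataclass
class Puff:
    """One detected Ca2+ puff (a temporally merged event)."""

    id: int
    onset_frame: int                  # stack frame of the rise
    peak_frame: int                   # stack frame of max ddF
    rect: Rect                        # pixel bounds at the peak frame
    centroid: Tuple[float, float]     # (x, y) in um, sub-pixel
    amplitude: float                  # max ddF within rect over the event
    signal_mass: float                # sum ddF >= T2 in rect at the peak frame
    radii: Tuple[float, float]        # (major, minor) elliptical radii, um
    rotation: float                   # radians mod pi
    diameter: float                   # um, mean of major and minor diameters
    area: float                       # um^2 of the fitted ellipse
    duration_half_max: float          # s
    n_frames: int = 1                 # frames the event stayed above threshold
    fit_fallback: bool = False
    site_id: Optional[int] = None


def find_candidates(ddf_frame: np.ndarray, T1_map: np.ndarray,
                    T2_map: np.ndarray, mask: Optional[np.ndarray] = None,
                    matrix_size: int = 5, min_supra: int = 18,
                    frame_index: int = 0) -> List[CandidateMatrix]:
    """Rank-and-select candidate matrices in one difference frame.

    Returns accepted candidates sorted by v_sum descending, signal mass
    descending, then (row, col).
    """
    rows, cols = ddf_frame.shape
    if mask is None:
        mask = np.ones_like(ddf_frame, dtype=bool)
    half = matrix_size // 2
    supra1 = (ddf_frame > T1_map) & mask
    if not supra1.any():
        return []
    supra2 = (ddf_frame > T2_map) & mask

    rr, cc = np.nonzero(supra1)
    vals = ddf_frame[rr, cc]
    # descending ddF, ties broken by (row, col) ascending
    order = np.lexsort((cc, rr, -vals))
    blocked = np.zeros_like(mask, dtype=bool)
    full_area = matrix_size ** 2
    accepted: List[CandidateMatrix] = []
    for k in order:
        r, c = int(rr[k]), int(cc[k])
        r0, r1 = max(r - half, 0), min(r + half + 1, rows)
        c0, c1 = max(c - half, 0), min(c + half + 1, cols)
        if blocked[r0:r1, c0:c1].any():
            continue  # would share pixels with an accepted matrix
        available = int(mask[r0:r1, c0:c1].sum())
        if available <= 0:
            continue
        need = math.ceil(min_supra / full_area * available)
        win2 = supra2[r0:r1, c0:c1]
        v_sum = int(win2.sum())
        if v_sum < need:
            continue
        mass = float(ddf_frame[r0:r1, c0:c1][win2].sum())
        accepted.append(CandidateMatrix(frame=frame_index, center=(r, c),
                                        v_sum=v_sum, signal_mass=mass,
                                        footprint=(r0, r1, c0, c1)))
        blocked[r0:r1, c0:c1] = True
    accepted.sort(key=lambda m: (-m.v_sum, -m.signal_mass, m.center))
    return accepted


def expand_boundary(ddf_frame: np.ndarray, seed: Tuple[int, int],
                    T2_map: np.ndarray, mask: Optional[np.ndarray] = None,
                    line_frac: float = 0.10) -> Rect:
    """Delineate a puff's rectangle by two-pass outward expansion.

    Starts from a 3x3 box centred on the seed (clipped at edges). See the
    module docstring for the exact stopping rules of each pass.
    """
    rows, cols = ddf_frame.shape
    sr, sc = seed
    if not (0 <= sr < rows and 0 <= sc < cols):
        raise ValueError("seed outside the frame")
    supra2 = ddf_frame > T2_map
    if mask is not None:
        supra2 &= mask
    r0, r1 = max(sr - 1, 0), min(sr + 2, rows)
    c0, c1 = max(sc - 1, 0), min(sc + 2, cols)

    # pass 1, columns: grow while the next column contains any supra-T2 pixel
    while c0 > 0 and supra2[r0:r1, c0 - 1].any():
        c0 -= 1
    while c1 < cols and supra2[r0:r1, c1].any():
        c1 += 1
    # pass 1, rows: grow while the next row's supra-T2 fraction is >= line_frac
    while r0 > 0 and supra2[r0 - 1, c0:c1].sum() >= line_frac * (c1 - c0):
        r0 -= 1
    while r1 < rows and supra2[r1, c0:c1].sum() >= line_frac * (c1 - c0):
        r1 += 1
    # pass 2: keep expanding outward while the next line is > line_frac occupied
    while c0 > 0 and supra2[r0:r1, c0 - 1].sum() > line_frac * (r1 - r0):
        c0 -= 1
    while c1 < cols and supra2[r0:r1, c1].sum() > line_frac * (r1 - r0):
        c1 += 1
    while r0 > 0 and supra2[r0 - 1, c0:c1].sum() > line_frac * (c1 - c0):
        r0 -= 1
    while r1 < rows and supra2[r1, c0:c1].sum() > line_frac * (c1 - c0):
        r1 += 1
    return (r0, r1, c0, c1)


def elliptical_gaussian(shape: Tuple[int, int], amplitude: float,
                        x0: float, y0: float, sigma_x: float, sigma_y: float,
                        theta: float, offset: float = 0.0) -> np.ndarray:
    """Sample an elliptical 2D Gaussian on a pixel grid.

    ``x`` is the column coordinate, ``y`` the row coordinate; ``theta`` is
    the rotation of the sigma_x axis from the x axis. Used both by the
    fitter and to render test/benchmark spots.
    """
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    ct, st = math.cos(theta), math.sin(theta)
    xr = (xx - x0) * ct + (yy - y0) * st
    yr = -(xx - x0) * st + (yy - y0) * ct
    return offset + amplitude * np.exp(-(xr ** 2 / (2 * sigma_x ** 2)
                                         + yr ** 2 / (2 * sigma_y ** 2)))


def _moment_estimates(region: np.ndarray):
    """Intensity-weighted centroid and second-moment ellipse of a region."""
    w = region - region.min()
    total = w.sum()
    if total <= 0:
        raise ValueError("region has no signal")
    yy, xx = np.mgrid[0:region.shape[0], 0:region.shape[1]]
    x0 = float((w * xx).sum() / total)
    y0 = float((w * yy).sum() / total)
    cxx = float((w * (xx - x0) ** 2).sum() / total)
    cyy = float((w * (yy - y0) ** 2).sum() / total)
    cxy = float((w * (xx - x0) * (yy - y0)).sum() / total)
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 0.05)
    s_minor, s_major = np.sqrt(evals)
    vx, vy = evecs[0, 1], evecs[1, 1]  # eigenvector of the larger eigenvalue
    theta = math.atan2(vy, vx) % math.pi
    return x0, y0, float(s_major), float(s_minor), theta


def fit_gaussian_2d(region: np.ndarray) -> GaussianFit:
    """Least-squares elliptical Gaussian fit with constant offset.

    Returns sub-pixel centre, major/minor sigmas, rotation (mod pi) and
    amplitude. Falls back to moment estimates (``fallback=True``) if the
    optimiser fails to converge to a sane solution.
    """
    region = np.asarray(region, dtype=np.float64)
    if region.ndim != 2 or min(region.shape) < 3:
        raise ValueError("region must be at least 3x3")
    if not np.any(region):
        raise ValueError("all-zero region")
    h, wd = region.shape
    try:
        x0, y0, s_maj, s_min, th = _moment_estimates(region)
    except ValueError:
        raise
    amp0 = float(region.max() - region.min())
    off0 = float(region.min())
    p0 = [amp0, x0, y0, max(s_maj, 0.4), max(s_min, 0.4), th, off0]
    yy, xx = np.mgrid[0:h, 0:wd]
    flat = region.ravel()

    def residuals(p):
        a, px, py, sx, sy, t, off = p
        ct, st = math.cos(t), math.sin(t)
        xr = (xx - px) * ct + (yy - py) * st
        yr = -(xx - px) * st + (yy - py) * ct
        model = off + a * np.exp(-(xr ** 2 / (2 * sx ** 2)
                                   + yr ** 2 / (2 * sy ** 2)))
        return (model.ravel() - flat)

    span = max(h, wd)
    lb = [0.0, -1.0, -1.0, 0.25, 0.25, -2 * math.pi, -np.inf]
    ub = [10 * max(amp0, 1e-12), wd, h, 3 * span, 3 * span, 2 * math.pi, np.inf]
    fallback = False
    try:
        sol = optimize.least_squares(residuals, p0, bounds=(lb, ub),
                                     method="trf", max_nfev=400)
        a, px, py, sx, sy, t, off = sol.x
        ok = (sol.success and a > 0 and 0.2 < sx < 3 * span
              and 0.2 < sy < 3 * span and -1 <= px <= wd and -1 <= py <= h)
        if not ok:
            raise RuntimeError("fit rejected")
    except (RuntimeError, ValueError):
        fallback = True
        px, py, sx, sy, t, a, off = x0, y0, s_maj, s_min, th, amp0, off0

    if sx < sy:  # enforce major >= minor, rotate theta by 90 deg
        sx, sy = sy, sx
        t = t + math.pi / 2
    t = t % math.pi
    return GaussianFit(x0=float(px), y0=float(py), sigma_major=float(sx),
                       sigma_minor=float(sy), theta=float(t),
                       amplitude=float(a), offset=float(off),
                       fallback=fallback)


def _half_max_duration(trace: np.ndarray, onset_stack: int,
                       frame_interval: float, search_frames: int = 75,
                       pre_frames: int = 5) -> float:
    """Half-maximum duration of a rect-mean intensity trace.

    The local baseline is the mean of up to ``pre_frames`` frames ending
    just before the onset; the peak is sought within ``search_frames`` of
    the onset; crossings are linearly interpolated. Never less than one
    frame interval.
    """
    n = trace.size
    b0 = max(onset_stack - pre_frames, 0)
    base = trace[b0:onset_stack].mean() if onset_stack > b0 else trace[0]
    excess = trace - base
    hi = min(onset_stack + search_frames, n)
    if onset_stack >= n:
        return frame_interval
    pk = onset_stack + int(np.argmax(excess[onset_stack:hi]))
    half = excess[pk] / 2.0
    if half <= 0:
        return frame_interval
    # walk left
    t_left = float(max(onset_stack - 1, 0))
    i = pk
    while i > 0 and excess[i - 1] > half:
        i -= 1
    if i > 0:
        lo, hi_v = excess[i - 1], excess[i]
        t_left = (i - 1) + (half - lo) / (hi_v - lo)
    else:
        t_left = 0.0
    # walk right
    j = pk
    while j < n - 1 and excess[j + 1] > half:
        j += 1
    if j < n - 1:
        hi_v, lo = excess[j], excess[j + 1]
        t_right = j + (hi_v - half) / (hi_v - lo)
    else:
        t_right = float(n - 1)
    return max((t_right - t_left) * frame_interval, frame_interval)


def measure_puff(deltadeltaF: np.ndarray, rect: Rect, onset_ddf: int,
                 T2_map: np.ndarray, *, end_ddf: Optional[int] = None,
                 ratio: Optional[np.ndarray] = None,
                 mask: Optional[np.ndarray] = None,
                 frame_interval: float = 0.040, pixel_size: float = 0.160,
                 puff_id: int = 0) -> Puff:
    """Measure a puff from the unsmoothed stacks.

    ``onset_ddf``/``end_ddf`` are difference-frame indices (inclusive
    span); the reported onset is the corresponding intensity-stack frame
    (ddF frame + 1). Amplitude is the max ddF within the rectangle over
    the span; signal mass sums rectangle pixels >= T2 at the peak frame;
    the half-max duration is measured on the rectangle-mean F/F0 trace.
    """
    if end_ddf is None:
        end_ddf = onset_ddf
    r0, r1, c0, c1 = rect
    span = deltadeltaF[onset_ddf:end_ddf + 1, r0:r1, c0:c1]
    per_frame_max = span.reshape(span.shape[0], -1).max(axis=1)
    rel_peak = int(np.argmax(per_frame_max))
    peak_ddf = onset_ddf + rel_peak
    amplitude = float(per_frame_max[rel_peak])
    frame = deltadeltaF[peak_ddf, r0:r1, c0:c1]
    t2 = T2_map[r0:r1, c0:c1]
    supra = frame >= t2
    if mask is not None:
        supra &= mask[r0:r1, c0:c1]
    signal_mass = float(frame[supra].sum())

    fit = fit_gaussian_2d(frame)
    cx_um = (c0 + fit.x0) * pixel_size
    cy_um = (r0 + fit.y0) * pixel_size
    # elliptical radius convention: 1/e^2 radius = 2 sigma
    r_major = 2.0 * fit.sigma_major * pixel_size
    r_minor = 2.0 * fit.sigma_minor * pixel_size
    diameter = (2 * r_major + 2 * r_minor) / 2.0
    area = math.pi * r_major * r_minor

    duration = frame_interval
    if ratio is not None:
        if mask is not None:
            sub_mask = mask[r0:r1, c0:c1]
            if sub_mask.any():
                trace = ratio[:, r0:r1, c0:c1][:, sub_mask].mean(axis=1)
            else:
                trace = ratio[:, r0:r1, c0:c1].mean(axis=(1, 2))
        else:
            trace = ratio[:, r0:r1, c0:c1].mean(axis=(1, 2))
        duration = _half_max_duration(trace, onset_ddf + 1, frame_interval)

    return Puff(id=puff_id, onset_frame=onset_ddf + 1, peak_frame=peak_ddf + 1,
                rect=rect, centroid=(cx_um, cy_um), amplitude=amplitude,
                signal_mass=signal_mass, radii=(r_major, r_minor),
                rotation=fit.theta, diameter=diameter, area=area,
                duration_half_max=duration,
                n_frames=end_ddf - onset_ddf + 1, fit_fallback=fit.fallback)


@dataclass
class _Track:
    """An open multi-frame event during temporal merging."""

    first_frame: int
    last_frame: int
    centroid_px: Tuple[float, float]       # (row, col) of the latest member
    best_rect: Rect
    best_mass: float
    best_frame: int


@dataclass
class DetectionResult:
    """Puffs plus per-stage audit counts."""

    puffs: List[Puff]
    wave_onset: Optional[int]
    n_candidates: int
    n_regions: int
    n_tracks: int
    derived_smoothed: Optional[DerivedStacks] = None


def _region_centroid(ddf_frame: np.ndarray, rect: Rect,
                     T2_map: np.ndarray) -> Tuple[float, float]:
    """Weighted centroid (row, col) of supra-T2 pixels inside a rectangle."""
    r0, r1, c0, c1 = rect
    sub = ddf_frame[r0:r1, c0:c1]
    w = np.where(sub > T2_map[r0:r1, c0:c1], sub, 0.0)
    tot = w.sum()
    if tot <= 0:
        return ((r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    return (float((w * yy).sum() / tot), float((w * xx).sum() / tot))


def detect_puffs(stack: ImageStack, roi: CellROI, config: PipelineConfig,
                 bg_roi: Optional[Tuple[int, int, int, int]] = None,
                 keep_derived: bool = False) -> DetectionResult:
    """Full detection pipeline for one cell.

    Candidate seeding and boundary expansion run on the 2x2-smoothed
    stack; all measurements use the unsmoothed stack. Threshold statistics
    are computed over difference frames preceding the detected global wave
    onset, and detections at or after the wave onset are discarded.
    """
    from .sitestats import detect_wave_onset  # local import, no cycle

    config.validate()
    ds = derive_stacks(stack, roi, config, smooth=True, bg_roi=bg_roi)
    trace = ds.ratio[:, ds.mask].mean(axis=1)
    wave = detect_wave_onset(trace, baseline_window=(0, config.n_pre),
                             k=config.wave_k, m=config.wave_m,
                             start_frame=config.n_pre,
                             min_rise=config.wave_min_rise)
    if wave is not None:
        # recompute mu/sd excluding the explosive wave frames
        from .preprocess import compute_thresholds
        nstats = max(int(wave) - 1, 2)
        ds.mu_map, ds.sd_map, ds.T1_map, ds.T2_map = compute_thresholds(
            ds.deltadeltaF, config.t1_mult, config.t2_mult,
            stats_frames=nstats)
        ds.stats_frames = nstats
        logger.info("wave onset at frame %d; thresholds from %d ddF frames",
                    wave, nstats)

    n_ddf = ds.deltadeltaF.shape[0]
    last_ddf = n_ddf if wave is None else min(n_ddf, int(wave) - 1)
    # quick per-frame supra-T1 pre-screen
    supra1_any = np.empty(n_ddf, dtype=bool)
    for f in range(n_ddf):
        supra1_any[f] = bool(
            ((ds.deltadeltaF[f] > ds.T1_map) & ds.mask).any())

    merge_px = config.merge_radius_px
    open_tracks: List[_Track] = []
    closed: List[_Track] = []
    n_cand = 0
    n_regions = 0
    for f in range(last_ddf):
        regions: List[Tuple[Rect, Tuple[float, float], float]] = []
        if supra1_any[f]:
            cands = find_candidates(ds.deltadeltaF[f], ds.T1_map, ds.T2_map,
                                    ds.mask, config.matrix_size,
                                    config.min_supra, frame_index=f)
            n_cand += len(cands)
            rects: List[Rect] = []
            for cand in cands:
                r, c = cand.center
                if any(r0 <= r < r1 and c0 <= c < c1
                       for (r0, r1, c0, c1) in rects):
                    continue  # centre already inside an expanded rectangle
                rect = expand_boundary(ds.deltadeltaF[f], cand.center,
                                       ds.T2_map, ds.mask, config.line_frac)
                rects.append(rect)
                cen = _region_centroid(ds.deltadeltaF[f], rect, ds.T2_map)
                regions.append((rect, cen, cand.signal_mass))
            n_regions += len(regions)

        # close tracks that were not extended at frame f-1
        still_open: List[_Track] = []
        for tr in open_tracks:
            if tr.last_frame < f - 1:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        for rect, cen, mass in regions:
            best = None
            best_d = merge_px
            for tr in open_tracks:
                if tr.last_frame != f - 1:
                    continue
                d = math.hypot(cen[0] - tr.centroid_px[0],
                               cen[1] - tr.centroid_px[1])
                if d <= best_d:
                    best_d = d
                    best = tr
            if best is not None:
                best.last_frame = f
                best.centroid_px = cen
                if mass > best.best_mass:
                    best.best_mass = mass
                    best.best_rect = rect
                    best.best_frame = f
            else:
                open_tracks.append(_Track(first_frame=f, last_frame=f,
                                          centroid_px=cen, best_rect=rect,
                                          best_mass=mass, best_frame=f))
    closed.extend(open_tracks)

    puffs: List[Puff] = []
    if closed:
        du = derive_stacks(stack, roi, config, smooth=False, bg_roi=bg_roi,
                           stats_frames=ds.stats_frames)
        for tr in closed:
            p = measure_puff(du.deltadeltaF, tr.best_rect, tr.first_frame,
                             du.T2_map, end_ddf=tr.last_frame, ratio=du.ratio,
                             mask=du.mask,
                             frame_interval=stack.frame_interval,
                             pixel_size=stack.pixel_size)
            puffs.append(p)
        puffs.sort(key=lambda p: (p.onset_frame, -p.signal_mass))
        for i, p in enumerate(puffs):
            p.id = i
    logger.info("detected %d puffs (%d candidates, %d regions, %d tracks)",
                len(puffs), n_cand, n_regions, len(closed))
    return DetectionResult(puffs=puffs, wave_onset=wave, n_candidates=n_cand,
                           n_regions=n_regions, n_tracks=len(closed),
                           derived_smoothed=ds if keep_derived else None)
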