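"""File I/O: TIFF stacks, masks, puff/site tables, manifests.

CSV schema: one row per puff or site; coordinates in um, times in s,
amplitudes in ddF (F/F0) units; rectangle bounds are 0-based, half-open
pixel indices; floats are written with 6 significant digits.
"""

from __future__ import annotations

import json
import os
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .detect import Puff
from .sites import Site
from .synthetic import ImageStack

PUFF_COLUMNS = [
    "id", "onset_frame", "peak_frame", "onset_s", "x_um", "y_um",
    "amplitude", "signal_mass", "radius_major_um", "radius_minor_um",
    "rotation_rad", "diameter_um", "area_um2", "duration_half_max_s",
    "n_frames", "rect_row0", "rect_row1", "rect_col0", "rect_col1",
    "fit_fallback", "site_id",
]

SITE_COLUMNS = ["id", "x_um", "y_um", "puff_count", "activity_class",
                "puff_ids"]


def read_stack(path, frame_interval: float, pixel_size: float) -> ImageStack:
    """Read a single-channel multi-page TIFF as an ImageStack.

    Acquisition metadata comes from the arguments (config overrides any
    embedded tags). Multi-channel/RGB files and empty stacks are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"expected a single-channel stack, got shape {data.shape}")
    if data.shape[0] == 0:
        raise ValueError("stack has no frames")
    return ImageStack(data=data.astype(np.float64),
                      frame_interval=frame_interval, pixel_size=pixel_size)


def write_stack(path, stack: ImageStack, as_uint16: bool = True) -> None:
    """Write a stack as a multi-page TIFF (16-bit by default)."""
    data = stack.data
    if as_uint16:
        data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_mask(path) -> np.ndarray:
    """Read a binary mask image (any nonzero pixel counts as inside)."""
    m = tifffile.imread(path)
    if m.ndim != 2:
        raise ValueError(f"mask must be a single 2D image, got {m.shape}")
    return m > 0


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, mask.astype(np.uint8) * 255)


def puffs_to_dataframe(puffs: Sequence[Puff],
                       frame_interval: Optional[float] = None) -> pd.DataFrame:
    rows = []
    dt = 0.0 if frame_interval is None else frame_interval
    for p in puffs:
        rows.append({
            "id": p.id, "onset_frame": p.onset_frame,
            "peak_frame": p.peak_frame,
            "onset_s": p.onset_frame * dt,
            "x_um": p.centroid[0], "y_um": p.centroid[1],
            "amplitude": p.amplitude, "signal_mass": p.signal_mass,
            "radius_major_um": p.radii[0], "radius_minor_um": p.radii[1],
            "rotation_rad": p.rotation, "diameter_um": p.diameter,
            "area_um2": p.area, "duration_half_max_s": p.duration_half_max,
            "n_frames": p.n_frames,
            "rect_row0": p.rect[0], "rect_row1": p.rect[1],
            "rect_col0": p.rect[2], "rect_col1": p.rect[3],
            "fit_fallback": p.fit_fallback,
            "site_id": -1 if p.site_id is None else p.site_id,
        })
    return pd.DataFrame(rows, columns=PUFF_COLUMNS)


def write_puffs_csv(path, puffs: Sequence[Puff],
                    frame_interval: Optional[float] = None) -> None:
    puffs_to_dataframe(puffs, frame_interval).to_csv(
        path, index=False, float_format="%.6g")


def read_puffs_csv(path) -> List[Puff]:
    df = pd.read_csv(path)
    puffs: List[Puff] = []
    for _, r in df.iterrows():
        puffs.append(Puff(
            id=int(r["id"]), onset_frame=int(r["onset_frame"]),
            peak_frame=int(r["peak_frame"]),
            rect=(int(r["rect_row0"]), int(r["rect_row1"]),
                  int(r["rect_col0"]), int(r["rect_col1"])),
            centroid=(float(r["x_um"]), float(r["y_um"])),
            amplitude=float(r["amplitude"]),
            signal_mass=float(r["signal_mass"]),
            radii=(float(r["radius_major_um"]), float(r["radius_minor_um"])),
            rotation=float(r["rotation_rad"]),
            diameter=float(r["diameter_um"]), area=float(r["area_um2"]),
            duration_half_max=float(r["duration_half_max_s"]),
            n_frames=int(r["n_frames"]),
            fit_fallback=bool(r["fit_fallback"]),
            site_id=None if int(r["site_id"]) < 0 else int(r["site_id"])))
    return puffs


def sites_to_dataframe(sites: Sequence[Site]) -> pd.DataFrame:
    rows = [{"id": s.id, "x_um": s.center[0], "y_um": s.center[1],
             "puff_count": s.puff_count, "activity_class": s.activity_class,
             "puff_ids": ";".join(str(i) for i in s.puff_ids)}
            for s in sites]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def write_sites_csv(path, sites: Sequence[Site]) -> None:
    sites_to_dataframe(sites).to_csv(path, index=False, float_format="%.6g")


def read_sites_csv(path) -> List[Site]:
    df = pd.read_csv(path)
    out: List[Site] = []
    for _, r in df.iterrows():
        ids = [int(x) for x in str(r["puff_ids"]).split(";") if x != ""]
        out.append(Site(id=int(r["id"]),
                        center=(float(r["x_um"]), float(r["y_um"])),
                        puff_ids=ids, puff_count=int(r["puff_count"])))
    return out


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def plot_site_map(sites: Sequence[Site], puffs: Sequence[Puff],
                  merge_radius: float, out_path, mask=None,
                  pixel_size: float = 0.160) -> None:
    """Overlay figure: puff centroids plus site circles (review aid)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if mask is not None:
        extent = (0, mask.shape[1] * pixel_size, mask.shape[0] * pixel_size, 0)
        ax.imshow(mask, cmap="gray", alpha=0.3, extent=extent)
    if puffs:
        ax.scatter([p.centroid[0] for p in puffs],
                   [p.centroid[1] for p in puffs], s=8, c="k",
                   label="puff centroids")
    for s in sites:
        ax.add_patch(plt.Circle(s.center, merge_radius, fill=False,
                                color="tab:blue"))
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_aspect("equal")
    ax.invert_yaxis()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
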