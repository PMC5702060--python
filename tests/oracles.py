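"""Independent brute-force reference implementations used only by tests.

These transliterate the detection and clustering rules as plain loops,
with no shared code with the package, so they can serve as oracles.
"""

from __future__ import annotations

import math

import numpy as np


def naive_find_candidates(ddf, T1, T2, mask=None, matrix_size=5,
                          min_supra=18):
    """Literal candidate selection: ranked seeds, 5x5 binary matrices.

    Returns a list of dicts sorted by (v_sum desc, mass desc, (row, col)).
    """
    rows, cols = ddf.shape
    if mask is None:
        mask = np.ones_like(ddf, dtype=bool)
    half = matrix_size // 2
    seeds = [(ddf[r, c], r, c)
             for r in range(rows) for c in range(cols)
             if mask[r, c] and ddf[r, c] > T1[r, c]]
    seeds.sort(key=lambda t: (-t[0], t[1], t[2]))
    accepted = []
    for _v, r, c in seeds:
        r0, r1 = max(r - half, 0), min(r + half + 1, rows)
        c0, c1 = max(c - half, 0), min(c + half + 1, cols)
        overlaps = any(fr0 < r1 and r0 < fr1 and fc0 < c1 and c0 < fc1
                       for (fr0, fr1, fc0, fc1) in
                       (a["footprint"] for a in accepted))
        if overlaps:
            continue
        available = v_sum = 0
        mass = 0.0
        for i in range(r0, r1):
            for j in range(c0, c1):
                if mask[i, j]:
                    available += 1
                    if ddf[i, j] > T2[i, j]:
                        v_sum += 1
                        mass += ddf[i, j]
        if available == 0:
            continue
        need = math.ceil(min_supra / matrix_size ** 2 * available)
        if v_sum < need:
            continue
        accepted.append({"center": (r, c), "v_sum": v_sum, "mass": mass,
                         "footprint": (r0, r1, c0, c1)})
    accepted.sort(key=lambda a: (-a["v_sum"], -a["mass"], a["center"]))
    return accepted


def naive_expand(ddf, seed, T2, mask=None, line_frac=0.10):
    """Literal two-pass boundary expansion from a 3x3 box."""
    rows, cols = ddf.shape
    supra = (ddf > T2)
    if mask is not None:
        supra = supra & mask
    sr, sc = seed
    r0, r1 = max(sr - 1, 0), min(sr + 2, rows)
    c0, c1 = max(sc - 1, 0), min(sc + 2, cols)

    def col_count(c, a, b):
        return sum(1 for i in range(a, b) if supra[i, c])

    def row_count(r, a, b):
        return sum(1 for j in range(a, b) if supra[r, j])

    # pass 1: columns until supra count falls to zero
    while c0 > 0 and col_count(c0 - 1, r0, r1) > 0:
        c0 -= 1
    while c1 < cols and col_count(c1, r0, r1) > 0:
        c1 += 1
    # pass 1: rows until the supra fraction falls below line_frac
    while r0 > 0 and row_count(r0 - 1, c0, c1) >= line_frac * (c1 - c0):
        r0 -= 1
    while r1 < rows and row_count(r1, c0, c1) >= line_frac * (c1 - c0):
        r1 += 1
    # pass 2: outward only, lines strictly above line_frac
    while c0 > 0 and col_count(c0 - 1, r0, r1) > line_frac * (r1 - r0):
        c0 -= 1
    while c1 < cols and col_count(c1, r0, r1) > line_frac * (r1 - r0):
        c1 += 1
    while r0 > 0 and row_count(r0 - 1, c0, c1) > line_frac * (c1 - c0):
        r0 -= 1
    while r1 < rows and row_count(r1, c0, c1) > line_frac * (c1 - c0):
        r1 += 1
    return (r0, r1, c0, c1)


def naive_assign_sites(puffs, merge_radius=0.96, recentre="bbox"):
    """Step-by-step transliteration of the greedy site amalgamation.

    ``puffs`` are dicts with keys x, y, mass, onset, id. Returns a list of
    site dicts {center, members}.
    """
    remaining = sorted(puffs, key=lambda p: (-p["mass"], p["onset"],
                                             (p["x"], p["y"])))
    remaining = list(remaining)
    sites = []
    while remaining:
        seed = remaining.pop(0)
        members = [seed]
        cx, cy = seed["x"], seed["y"]
        changed = True
        while changed:
            changed = False
            keep = []
            for p in remaining:
                if math.hypot(p["x"] - cx, p["y"] - cy) <= merge_radius:
                    members.append(p)
                    changed = True
                else:
                    keep.append(p)
            remaining = keep
            if changed:
                xs = [p["x"] for p in members]
                ys = [p["y"] for p in members]
                if recentre == "bbox":
                    cx, cy = (min(xs) + max(xs)) / 2, (min(ys) + max(ys)) / 2
                else:
                    cx, cy = sum(xs) / len(xs), sum(ys) / len(ys)
        xs = [p["x"] for p in members]
        ys = [p["y"] for p in members]
        if recentre == "bbox":
            center = ((min(xs) + max(xs)) / 2, (min(ys) + max(ys)) / 2)
        else:
            center = (sum(xs) / len(xs), sum(ys) / len(ys))
        sites.append({"center": center,
                      "members": sorted(p["id"] for p in members)})
    return sites


def ztp_mle_bisect(counts, tol=1e-12):
    """Zero-truncated Poisson mean MLE by plain bisection (oracle)."""
    xbar = sum(counts) / len(counts)
    if xbar <= 1:
        raise ValueError("mean at truncation boundary")
    lo, hi = 1e-15, xbar

    def g(mu):
        return mu / (1.0 - math.exp(-mu)) - xbar

    for _ in range(200):
        mid = (lo + hi) / 2
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return (lo + hi) / 2
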