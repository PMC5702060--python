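"""Assignment of puffs to immobile release sites.

Puffs are amalgamated into sites greedily: the unassigned puff with the
greatest signal mass seeds a site at its centroid; unassigned puffs whose
centroids lie within the merge radius (default 0.96 um, 6 pixels) are
absorbed; the site centre is then redefined as the centre of the region
enclosing the member centroids and absorption repeats until membership is
stable. Accepted sites are frozen and their puffs removed; the loop
continues until every puff belongs to exactly one site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple


@dataclass
class Site:
    """An immobile release site: a cluster of puff centroids."""

    id: int
    center: Tuple[float, float]    # (x, y) um
    puff_ids: List[int]
    puff_count: int

    @property
    def activity_class(self) -> str:
        """'low' for a single puff, 'high' for several."""
        return "high" if self.puff_count > 1 else "low"


def _centroid_of(puff) -> Tuple[float, float]:
    return tuple(puff.centroid)


def _recentre(points: Sequence[Tuple[float, float]],
              method: str) -> Tuple[float, float]:
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    if method == "bbox":
        return ((min(xs) + max(xs)) / 2.0, (min(ys) + max(ys)) / 2.0)
    if method == "mean":
        return (sum(xs) / len(xs), sum(ys) / len(ys))
    raise ValueError("recentre method must be 'bbox' or 'mean'")


def assign_sites(puffs: Sequence, merge_radius: float = 0.96,
                 recentre: str = "bbox") -> List[Site]:
    """Partition puffs into sites by greedy, mass-ranked amalgamation.

    ``puffs`` need ``centroid`` (x, y in um), ``signal_mass``,
    ``onset_frame`` and ``id`` attributes. Ties in signal mass are broken
    by earlier onset, then lexicographic centroid. Every puff ends up in
    exactly one site.
    """
    if merge_radius <= 0:
        raise ValueError("merge_radius must be positive")
    order = sorted(range(len(puffs)),
                   key=lambda i: (-puffs[i].signal_mass,
                                  puffs[i].onset_frame,
                                  _centroid_of(puffs[i])))
    unassigned = set(range(len(puffs)))
    sites: List[Site] = []
    r2 = merge_radius ** 2
    for seed_idx in order:
        if seed_idx not in unassigned:
            continue
        members = [seed_idx]
        unassigned.discard(seed_idx)
        center = _centroid_of(puffs[seed_idx])
        grew = True
        while grew:
            grew = False
            for j in sorted(unassigned):
                cx, cy = _centroid_of(puffs[j])
                if (cx - center[0]) ** 2 + (cy - center[1]) ** 2 <= r2:
                    members.append(j)
                    unassigned.discard(j)
                    grew = True
            if grew:
                center = _recentre([_centroid_of(puffs[m]) for m in members],
                                   recentre)
        center = _recentre([_centroid_of(puffs[m]) for m in members], recentre)
        site = Site(id=len(sites), center=center,
                    puff_ids=[puffs[m].id for m in members],
                    puff_count=len(members))
        sites.append(site)
        for m in members:
            if hasattr(puffs[m], "site_id"):
                puffs[m].site_id = site.id
    return sites


def match_sites(sites_a: Sequence[Site], sites_b: Sequence[Site],
                match_radius: float = 0.96
                ) -> Tuple[List[Tuple[int, int]], List[int], List[int]]:
    """Greedy nearest-neighbour matching of two site lists.

    Pairs are formed in ascending order of centre distance; each site is
    matched at most once, and only pairs within ``match_radius`` count.
    Returns (matched index pairs (ia, ib), new-in-b indices,
    lost-from-a indices).
    """
    pairs = []
    for ia, a in enumerate(sites_a):
        for ib, b in enumerate(sites_b):
            d = math.hypot(a.center[0] - b.center[0],
                           a.center[1] - b.center[1])
            if d <= match_radius:
                pairs.append((d, ia, ib))
    pairs.sort()
    used_a, used_b = set(), set()
    matched: List[Tuple[int, int]] = []
    for _d, ia, ib in pairs:
        if ia in used_a or ib in used_b:
            continue
        matched.append((ia, ib))
        used_a.add(ia)
        used_b.add(ib)
    lost_a = [i for i in range(len(sites_a)) if i not in used_a]
    new_b = [i for i in range(len(sites_b)) if i not in used_b]
    return matched, new_b, lost_a
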