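"""Summary statistics and estimators of total release-site abundance.

Two routes estimate the total number of release sites per cell (N) from
short stimulations that each reveal only a fraction of the sites:

* capture-recapture: N = n2 / f, where n2 is the number of sites seen in
  the second challenge and f the fraction of those that had also responded
  in the first challenge (the Lincoln-Petersen form n1*n2/overlap is also
  provided);
* zero-truncated Poisson: the per-site puff count over an analysis window
  is modelled as Poisson(mu) conditioned on >= 1 (sites are only seen if
  they fire); mu is the MLE solving mu/(1 - exp(-mu)) = mean observed
  count, and N = observed sites / (1 - exp(-mu)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .sites import Site, assign_sites, match_sites


@dataclass
class StimulusEpoch:
    """One stimulation period and its quantitative analysis window."""

    label: str
    stim_start_frame: int
    stim_end_frame: int
    wave_onset_frame: Optional[int] = None
    analysis_window: Optional[Tuple[int, int]] = None

    def resolve_window(self, frame_interval: float,
                       window_s: Optional[float] = 2.0) -> Tuple[int, int]:
        """Half-open frame window used for quantitative analysis.

        Default: the ``window_s`` seconds ending at the wave onset or the
        end of stimulation, whichever comes first. ``window_s=None``
        selects the full record from stimulus start to wave/end.
        """
        end = self.stim_end_frame
        if self.wave_onset_frame is not None:
            end = min(end, self.wave_onset_frame)
        if window_s is None:
            start = self.stim_start_frame
        else:
            start = max(end - int(round(window_s / frame_interval)),
                        self.stim_start_frame)
        self.analysis_window = (start, end)
        return self.analysis_window


@dataclass
class SiteEstimate:
    """An estimate of the total number of release sites in a cell."""

    N_hat: float
    method: str                      # "capture_recapture" | "poisson"
    inputs_summary: Dict[str, float] = field(default_factory=dict)
    flagged: bool = False            # N_hat below the directly observed count


def detect_wave_onset(trace: np.ndarray,
                      baseline_window: Tuple[int, int] = (0, 50),
                      k: float = 10.0, m: int = 5,
                      start_frame: Optional[int] = None,
                      min_rise: float = 0.3) -> Optional[int]:
    """First frame where the cell-mean F/F0 leaves baseline explosively.

    Onset = first frame at which the trace exceeds baseline mean +
    max(k*sd, min_rise) for m consecutive frames; None if never. The
    ``min_rise`` floor (F/F0 units) keeps the slow creeping rise that
    precedes a wave — which the ddF correction is designed to tolerate —
    from being mistaken for the wave itself: spatial averaging makes the
    baseline s.d. of the trace far smaller than any systematic drift.
    """
    trace = np.asarray(trace, dtype=np.float64)
    b0, b1 = baseline_window
    if not (0 <= b0 < b1 <= trace.size):
        raise ValueError("baseline_window out of range")
    base = trace[b0:b1]
    thresh = base.mean() + max(k * base.std(ddof=1), min_rise)
    lo = b1 if start_frame is None else start_frame
    above = trace >= thresh
    run = 0
    for f in range(lo, trace.size):
        run = run + 1 if above[f] else 0
        if run >= m:
            return f - m + 1
    return None


def puff_frequency_density(puffs: Sequence, window: Tuple[int, int],
                           cell_area: float, frame_interval: float) -> float:
    """Puff frequency per unit area, Hz/um^2, over a half-open frame window."""
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    start, end = window
    duration = (end - start) * frame_interval
    if duration <= 0:
        raise ValueError("window duration must be positive")
    n = sum(1 for p in puffs if start <= p.onset_frame < end)
    return n / (duration * cell_area)


def site_density(sites: Sequence[Site], cell_area: float) -> float:
    """Sites per um^2."""
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    return len(sites) / cell_area


def puffs_per_site_histogram(sites: Sequence[Site]) -> Dict[int, int]:
    """Number of sites with k = 1, 2, ... puffs."""
    hist: Dict[int, int] = {}
    for s in sites:
        hist[s.puff_count] = hist.get(s.puff_count, 0) + 1
    return dict(sorted(hist.items()))


def estimate_N_capture_recapture(n_sites_challenge2: int,
                                 repeat_fraction: float) -> SiteEstimate:
    """N = sites seen in challenge 2 / fraction of them seen before.

    E.g. 17 sites with a repeat fraction of 0.26 gives N ~= 65.
    """
    if not (0 < repeat_fraction <= 1):
        raise ValueError("repeat_fraction must lie in (0, 1]")
    if n_sites_challenge2 < 1:
        raise ValueError("need at least one site in challenge 2")
    n_hat = n_sites_challenge2 / repeat_fraction
    return SiteEstimate(
        N_hat=n_hat, method="capture_recapture",
        inputs_summary={"n_sites_challenge2": n_sites_challenge2,
                        "repeat_fraction": repeat_fraction},
        flagged=n_hat < n_sites_challenge2)


def estimate_N_lincoln_petersen(n1: int, n2: int,
                                overlap: int) -> SiteEstimate:
    """Classical two-sample estimator N = n1 * n2 / overlap."""
    if overlap < 1:
        raise ValueError("overlap must be >= 1")
    n_hat = n1 * n2 / overlap
    return SiteEstimate(N_hat=n_hat, method="lincoln_petersen",
                        inputs_summary={"n1": n1, "n2": n2,
                                        "overlap": overlap},
                        flagged=n_hat < max(n1, n2))


def ztp_mean_mle(counts: Sequence[int], tol: float = 1e-10) -> float:
    """MLE of the Poisson mean from zero-truncated counts.

    Solves mu / (1 - exp(-mu)) = mean(counts) by bracketed root finding.
    """
    counts = np.asarray(counts)
    if counts.size == 0 or np.any(counts < 1):
        raise ValueError("counts must be >= 1 and non-empty")
    xbar = float(counts.mean())
    if xbar <= 1.0 + 1e-12:
        raise ValueError(
            "mean at truncation boundary, N unidentifiable (all counts = 1)")

    def g(mu):
        return mu / (1.0 - math.exp(-mu)) - xbar

    lo = 1e-12
    hi = xbar  # g(xbar) > 0 since mu/(1-e^-mu) > mu; g(lo) -> 1 - xbar < 0
    return float(optimize.brentq(g, lo, hi, xtol=tol))


def estimate_N_poisson(observed_puffs_per_site: Sequence[int]) -> SiteEstimate:
    """Zero-truncated Poisson estimate of total sites.

    ``observed_puffs_per_site`` are the puff counts of the sites that were
    seen (all >= 1). N = n_observed / (1 - exp(-mu_hat)).
    """
    counts = list(observed_puffs_per_site)
    mu = ztp_mean_mle(counts)
    p_seen = 1.0 - math.exp(-mu)
    n_hat = len(counts) / p_seen
    return SiteEstimate(N_hat=n_hat, method="poisson",
                        inputs_summary={"n_observed": len(counts),
                                        "mu_hat": mu,
                                        "mean_count": float(np.mean(counts))},
                        flagged=n_hat < len(counts))


def new_site_rate(challenge_puffs: Sequence[Sequence], protocol: str,
                  merge_radius: float = 0.96,
                  match_radius: float = 0.96) -> List[float]:
    """Fraction of newly discovered sites per comparison.

    ``challenge_puffs`` is an ordered list (one entry per stimulation) of
    puff lists in detection order.

    * ``between``: for each challenge after the first, the fraction of its
      sites not matched to any site of the preceding challenges.
    * ``within``: challenge 1 is split into halves T1/T2 with equal puff
      counts n; the reference is the T1 site set; comparisons are C1T2 and
      the first-n-puff intervals of each later challenge, each reported as
      the fraction of its sites not matched to the reference. Later
      challenges with fewer than n puffs are skipped with a warning.
    """
    if len(challenge_puffs) < 2 and protocol == "between":
        raise ValueError("need at least two challenges")
    fractions: List[float] = []
    if protocol == "between":
        seen_sites: List[Site] = []
        for i, puffs in enumerate(challenge_puffs):
            sites = assign_sites(list(puffs), merge_radius)
            if i > 0 and sites:
                _m, new_b, _lost = match_sites(seen_sites, sites, match_radius)
                fractions.append(len(new_b) / len(sites))
            seen_sites.extend(sites)
        return fractions
    if protocol == "within":
        first = list(challenge_puffs[0])
        n = len(first) // 2
        if n < 1:
            raise ValueError("challenge 1 has too few puffs to split")
        ref_sites = assign_sites(first[:n], merge_radius)
        comparisons = [first[n:2 * n]]
        for later in challenge_puffs[1:]:
            later = list(later)
            if len(later) < n:
                warnings.warn("challenge with fewer puffs than the matched "
                              "count n; comparison skipped")
                continue
            comparisons.append(later[:n])
        for interval in comparisons:
            sites = assign_sites(interval, merge_radius)
            if not sites:
                continue
            _m, new_b, _lost = match_sites(ref_sites, sites, match_radius)
            fractions.append(len(new_b) / len(sites))
        return fractions
    raise ValueError("protocol must be 'within' or 'between'")


def discovery_curve(puffs: Sequence) -> List[Tuple[int, int]]:
    """Cumulative unique-site count versus puff count, in detection order.

    Puffs must carry ``site_id``. The curve is non-decreasing and bounded
    above by the identity line.
    """
    seen = set()
    curve: List[Tuple[int, int]] = []
    for k, p in enumerate(puffs, start=1):
        if p.site_id is None:
            raise ValueError("puffs must carry site assignments")
        seen.add(p.site_id)
        curve.append((k, len(seen)))
    return curve


def classify_activity(sites_challenge1: Sequence[Site],
                      later_site_lists: Sequence[Sequence[Site]],
                      match_radius: float = 0.96) -> Dict[str, float]:
    """Re-firing behaviour of low- vs high-activity first-challenge sites.

    A first-challenge site counts as multi-refiring if, in any later
    challenge, it matches a site that produced more than one puff. Returns
    the fraction of multi-refiring sites per activity class (classes with
    no sites map to nan).
    """
    multi = [False] * len(sites_challenge1)
    for later in later_site_lists:
        matched, _new, _lost = match_sites(sites_challenge1, list(later),
                                           match_radius)
        for ia, ib in matched:
            if later[ib].puff_count > 1:
                multi[ia] = True
    out: Dict[str, float] = {}
    for cls in ("low", "high"):
        idx = [i for i, s in enumerate(sites_challenge1)
               if s.activity_class == cls]
        out[cls] = (sum(multi[i] for i in idx) / len(idx)) if idx else float("nan")
    return out
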