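"""Rich-club detection and delimitation.

A rich club is a set of high-degree nodes more densely interconnected than
their degrees alone predict. For each degree threshold k the raw rich-club
coefficient is

    phi(k) = 2 * E_>k / (N_>k * (N_>k - 1))

where N_>k counts nodes of degree strictly greater than k and E_>k counts
edges among them. phi is undefined (NaN, never 0) when N_>k < 2. Because phi
rises with k even in random graphs, significance is judged by the normalized
coefficient rho(k) = phi(k) / mean phi_random(k) over a degree-preserving
random ensemble; rho(k) > 1 marks a club that the degree sequence alone
cannot explain.

The profile is computed incrementally in O(|E|): nodes enter the club as the
threshold k sweeps downward, and each entering node contributes its edges to
already-present members once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class RichClubProfile:
    """Per-threshold rich-club statistics, indexed by degree threshold k.

    Raw fields (``n_gt``, ``e_gt``, ``phi``) are always present; normalized
    fields are filled by :func:`normalized_rho`.
    """

    k: np.ndarray
    n_gt: np.ndarray
    e_gt: np.ndarray
    phi: np.ndarray
    phi_rand_mean: np.ndarray | None = None
    phi_rand_sd: np.ndarray | None = None
    rho: np.ndarray | None = None
    empirical_p: np.ndarray | None = None
    degrees: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        data = {"k": self.k, "n_gt_k": self.n_gt, "e_gt_k": self.e_gt,
                "phi": self.phi}
        if self.rho is not None:
            data.update(phi_rand_mean=self.phi_rand_mean,
                        phi_rand_sd=self.phi_rand_sd,
                        rho=self.rho, empirical_p=self.empirical_p)
        return pd.DataFrame(data)


@dataclass
class RichClubCall:
    """Delimitation of the rich club from a normalized profile."""

    detected: bool
    significant_range: tuple[int, int] | None   # [k_low, k_high] with rho > 1
    peak_k: int | None
    peak_rho: float | None
    core_range: tuple[int, int] | None          # contiguous run with rho > core_threshold
    core_nodes: set = field(default_factory=set)
    strongest_component_nodes: set = field(default_factory=set)
    overlap_nodes: set = field(default_factory=set)
    flag: str = ""


def rich_club_phi(G: nx.Graph) -> RichClubProfile:
    """Raw rich-club profile phi(k) for every k from 0 to max_degree - 1."""
    if G.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    degrees = dict(G.degree())
    max_deg = max(degrees.values())
    ks = np.arange(max_deg)
    n_gt = np.zeros(max_deg, dtype=int)
    e_gt = np.zeros(max_deg, dtype=int)

    # nodes grouped by degree; sweep k downward, nodes of degree k+1 enter
    by_degree: dict[int, list] = {}
    for v, d in degrees.items():
        by_degree.setdefault(d, []).append(v)
    in_club: set = set()
    n_cur = 0
    e_cur = 0
    for k in range(max_deg - 1, -1, -1):
        entering = by_degree.get(k + 1, [])
        seen_batch: set = set()
        for v in entering:
            for u in G[v]:
                du = degrees[u]
                if du > k + 1 or (du == k + 1 and u in seen_batch):
                    e_cur += 1
            seen_batch.add(v)
        in_club.update(entering)
        n_cur += len(entering)
        n_gt[k] = n_cur
        e_gt[k] = e_cur
    phi = np.full(max_deg, np.nan)
    ok = n_gt >= 2
    phi[ok] = 2.0 * e_gt[ok] / (n_gt[ok] * (n_gt[ok] - 1.0))
    return RichClubProfile(k=ks, n_gt=n_gt, e_gt=e_gt, phi=phi, degrees=degrees)


def rich_club_phi_dict(G: nx.Graph) -> dict[int, float]:
    """phi(k) as a plain dict over defined thresholds (convenience)."""
    p = rich_club_phi(G)
    return {int(k): float(v) for k, v in zip(p.k, p.phi) if np.isfinite(v)}


def normalized_rho(G: nx.Graph, ensemble: list[nx.Graph],
                   profile: RichClubProfile | None = None,
                   average: str = "mean") -> RichClubProfile:
    """Normalize phi(k) by a degree-preserving random ensemble.

    rho(k) = phi(k) / average(phi_random(k)); undefined (NaN) where either
    term is undefined or the ensemble average is 0. The empirical p-value per
    k is the fraction of ensemble members with phi_random(k) >= phi(k).
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    if average not in ("mean", "median"):
        raise ValueError("average must be 'mean' or 'median'")
    prof = profile if profile is not None else rich_club_phi(G)
    max_k = prof.k.size
    mat = np.full((len(ensemble), max_k), np.nan)
    for i, H in enumerate(ensemble):
        ph = rich_club_phi(H)
        n = min(ph.phi.size, max_k)
        mat[i, :n] = ph.phi[:n]
    finite_cols = np.isfinite(mat).any(axis=0)
    center = np.full(max_k, np.nan)
    sd = np.full(max_k, np.nan)
    if finite_cols.any():
        sub = mat[:, finite_cols]
        center[finite_cols] = (np.nanmean(sub, axis=0) if average == "mean"
                               else np.nanmedian(sub, axis=0))
        sd[finite_cols] = np.nanstd(sub, axis=0)
    with np.errstate(invalid="ignore"):
        rho = np.where(center > 0, prof.phi / center, np.nan)
        emp_p = np.mean(mat >= prof.phi[None, :], axis=0)
    emp_p = np.where(np.isfinite(prof.phi), emp_p, np.nan)
    return RichClubProfile(k=prof.k, n_gt=prof.n_gt, e_gt=prof.e_gt,
                           phi=prof.phi, phi_rand_mean=center,
                           phi_rand_sd=sd, rho=rho, empirical_p=emp_p,
                           degrees=prof.degrees)


def _longest_true_run(mask: np.ndarray) -> tuple[int, int] | None:
    """Index bounds [lo, hi] of the longest contiguous True run (first on ties)."""
    best = None
    start = None
    for i, flag in enumerate(list(mask) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if best is None or (i - start) > (best[1] - best[0] + 1):
                best = (start, i - 1)
            start = None
    return best


def call_rich_club(profile: RichClubProfile,
                   core_threshold: float = 1.3,
                   plateau_threshold: float = 0.95,
                   core_rule: str = "min") -> RichClubCall:
    """Delimit the rich club from a normalized profile.

    * significant_range — longest contiguous run of k with defined rho(k) > 1.
    * peak_k — argmax rho within that run (ties -> smallest k, logged).
    * core_nodes — nodes with degree >= the lower bound of the contiguous
      run of rho(k) > ``core_threshold`` (``core_rule='min'``, the default:
      a rich club contains its own top hubs, whose degree always exceeds any
      defined threshold), or nodes whose degree falls inside that run
      (``core_rule='range'``).
    * strongest_component_nodes — nodes with degree > k*, where k* is the
      smallest k from which phi >= ``plateau_threshold`` holds for every
      larger defined k.
    """
    if profile.rho is None:
        raise ValueError("profile is not normalized; run normalized_rho first")
    if core_rule not in ("range", "min"):
        raise ValueError("core_rule must be 'range' or 'min'")
    rho = profile.rho
    sig = _longest_true_run(np.isfinite(rho) & (rho > 1.0))
    degrees = profile.degrees

    # strongest component: phi plateau sustained to the top of the profile
    phi = profile.phi
    defined = np.isfinite(phi)
    k_star = None
    ok_from_here = True
    for i in range(phi.size - 1, -1, -1):
        if defined[i]:
            if phi[i] >= plateau_threshold:
                if ok_from_here:
                    k_star = int(profile.k[i])
            else:
                ok_from_here = False
    strongest = set()
    if k_star is not None:
        strongest = {v for v, d in degrees.items() if d > k_star}

    if sig is None:
        return RichClubCall(detected=False, significant_range=None, peak_k=None,
                            peak_rho=None, core_range=None,
                            strongest_component_nodes=strongest,
                            flag="no rich-club detected")

    lo, hi = int(profile.k[sig[0]]), int(profile.k[sig[1]])
    seg = rho[sig[0]:sig[1] + 1]
    peak_rel = int(np.nanargmax(seg))
    peak_rho = float(seg[peak_rel])
    if np.sum(seg == peak_rho) > 1:
        logger.info("tie at peak rho=%.4g; reporting smallest k", peak_rho)
    peak_k = lo + peak_rel

    core = _longest_true_run(np.isfinite(rho) & (rho > core_threshold))
    core_nodes: set = set()
    core_range = None
    if core is not None:
        c_lo, c_hi = int(profile.k[core[0]]), int(profile.k[core[1]])
        core_range = (c_lo, c_hi)
        if core_rule == "range":
            core_nodes = {v for v, d in degrees.items() if c_lo <= d <= c_hi}
        else:
            core_nodes = {v for v, d in degrees.items() if d >= c_lo}
    overlap = core_nodes & strongest
    return RichClubCall(detected=True, significant_range=(lo, hi),
                        peak_k=peak_k, peak_rho=peak_rho,
                        core_range=core_range, core_nodes=core_nodes,
                        strongest_component_nodes=strongest,
                        overlap_nodes=overlap)


def compare_frequency(core_nodes: set, frequency: dict[str, int]
                      ) -> tuple[float, float]:
    """Literature-frequency contrast: club vs non-club nodes.

    Returns (fold change of mean frequency club/non-club, Welch two-tailed
    t-test p-value). Both groups must contain at least two annotated nodes.
    Zero-variance degenerate inputs yield p = 0 if the means differ and
    p = 1 if they are equal (logged).
    """
    club = [f for v, f in frequency.items() if v in core_nodes]
    non = [f for v, f in frequency.items() if v not in core_nodes]
    if len(club) < 2 or len(non) < 2:
        raise ValueError("each group needs >= 2 annotated nodes")
    m_club, m_non = float(np.mean(club)), float(np.mean(non))
    fold = m_club / m_non if m_non > 0 else float("inf")
    if np.var(club) == 0 and np.var(non) == 0:
        logger.warning("zero variance in both groups; degenerate t-test")
        return fold, (1.0 if m_club == m_non else 0.0)
    t, p = stats.ttest_ind(club, non, equal_var=False)
    return fold, float(p)
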