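"""Gene-set / drug-target enrichment via Fisher's exact test.

The 2x2 table for a drug against a foreground (the whole network, or its
rich club) within a background is

                 in foreground   not in foreground
    target            a                 c
    non-target        b                 d

The two-sided p-value is computed from the hypergeometric distribution with
fixed margins by the minimum-likelihood rule: the probabilities of all
tables no more likely than the observed one are summed. The test is
implemented here from the hypergeometric mass directly (and cross-checked
against an independent enumeration in the test-suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    """One drug/gene-set enrichment result against a foreground."""

    set_name: str
    a: int          # targets in foreground
    b: int          # foreground non-targets
    c: int          # targets outside foreground (within background)
    d: int          # remainder of background
    odds_ratio: float
    p_value: float
    enrichment_score: float     # -log10(raw p); heuristic display score
    adjusted_p: float | None = None
    continuity_corrected: bool = False


def fisher_exact(a: int, b: int, c: int, d: int,
                 alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns (p_value, odds_ratio). The two-sided p sums hypergeometric
    point probabilities over all tables with the observed margins whose
    probability does not exceed the observed table's (minimum-likelihood
    rule); 'greater' sums the upper tail in ``a``. The odds ratio is
    (a*d)/(b*c), with a 0.5 continuity correction applied to every cell when
    any cell is zero.
    """
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("cell counts must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    r1 = a + b          # foreground size
    c1 = a + c          # target count
    # support of a given the margins
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = float(pmf[support == a][0])
    if alternative == "two-sided":
        p = float(np.sum(pmf[pmf <= p_obs * (1.0 + 1e-9)]))
    elif alternative == "greater":
        p = float(np.sum(pmf[support >= a]))
    elif alternative == "less":
        p = float(np.sum(pmf[support <= a]))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = min(p, 1.0)
    if min(cells) == 0:
        a_, b_, c_, d_ = (x + 0.5 for x in cells)
    else:
        a_, b_, c_, d_ = cells
    odds = (a_ * d_) / (b_ * c_)
    return p, float(odds)


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg FDR adjustment (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj.tolist()


def drug_enrichment(drug_targets: dict[str, set[str]],
                    foreground: set[str],
                    background: set[str] | int,
                    alternative: str = "two-sided") -> list[EnrichmentRecord]:
    """Fisher enrichment of each drug's target set in a foreground.

    ``background`` is either a node set containing the foreground (e.g. the
    network when scoring the rich club) or an integer universe size (e.g.
    20,000 protein-coding genes when scoring the network itself). Drugs with
    no targets in the background are skipped with a log message. Records are
    sorted by raw p; BH-adjusted p-values are appended.
    """
    if isinstance(background, int):
        bg_size = background
        in_bg = None
        if bg_size < len(foreground):
            raise ValueError("background size smaller than foreground")
    else:
        if not foreground <= background:
            raise ValueError("foreground must be a subset of the background set")
        bg_size = len(background)
        in_bg = background
    records: list[EnrichmentRecord] = []
    for drug, targets in sorted(drug_targets.items()):
        t_bg = {t for t in targets if in_bg is None or t in in_bg}
        if in_bg is None:
            # integer universe: count every target as part of the universe
            t_bg = set(targets)
        if not t_bg:
            logger.info("drug %r has no targets in the background; skipped", drug)
            continue
        a = len(t_bg & foreground)
        b = len(foreground) - a
        c = len(t_bg) - a
        d = bg_size - a - b - c
        if d < 0:
            raise ValueError(f"background too small for drug {drug!r}")
        p, odds = fisher_exact(a, b, c, d, alternative=alternative)
        score = float(-np.log10(p)) if p > 0 else float("inf")
        records.append(EnrichmentRecord(
            set_name=drug, a=a, b=b, c=c, d=d, odds_ratio=odds, p_value=p,
            enrichment_score=score,
            continuity_corrected=min(a, b, c, d) == 0))
    records.sort(key=lambda r: (r.p_value, r.set_name))
    adj = benjamini_hochberg([r.p_value for r in records])
    for r, q in zip(records, adj):
        r.adjusted_p = q
    return records


def target_degree_comparison(G: nx.Graph, targets: set[str]
                             ) -> tuple[float, float, float]:
    """Compare degrees of target vs non-target nodes in the network.

    Returns (mean target degree, mean non-target degree, Welch two-tailed
    t-test p). Both groups must have at least two members in the network.
    """
    t_deg = [d for v, d in G.degree() if v in targets]
    n_deg = [d for v, d in G.degree() if v not in targets]
    if len(t_deg) < 2 or len(n_deg) < 2:
        raise ValueError("need >= 2 targets and >= 2 non-targets in the network")
    if np.var(t_deg) == 0 and np.var(n_deg) == 0:
        logger.warning("zero variance in both degree groups; degenerate t-test")
        p = 1.0 if np.mean(t_deg) == np.mean(n_deg) else 0.0
    else:
        _, p = stats.ttest_ind(t_deg, n_deg, equal_var=False)
    return float(np.mean(t_deg)), float(np.mean(n_deg)), float(p)
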