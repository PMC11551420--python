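"""Hypergeometric set overlap, term enrichment and group comparisons."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .expression import benjamini_hochberg

__all__ = [
    "OverlapResult",
    "TermEnrichment",
    "hypergeometric_overlap",
    "term_enrichment",
    "wilcoxon_rank_sum",
    "compare_expression_by_group",
]


@dataclass
class OverlapResult:
    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    expected_overlap: float
    pvalue_upper: float


@dataclass
class TermEnrichment:
    term: str
    k: int              # term genes in the set
    K: int              # term genes in the universe
    n: int              # set size
    N: int              # universe size
    pvalue: float
    qvalue: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.qvalue < 0.01


def hypergeometric_overlap(set_a: set, set_b: set, universe: set) -> OverlapResult:
    """Upper-tail probability of an overlap at least as large as observed.

    P(X >= k) for X ~ Hypergeom(N=|universe|, K=|A|, n=|B|); scipy
    evaluates the tail in log space internally, so small p-values are
    exact to double precision.
    """
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    N, K, n = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if N else 1.0
    return OverlapResult(N, K, n, k, K * n / N if N else 0.0, min(1.0, p))


def term_enrichment(gene_set: set, term_to_genes: Mapping[str, set],
                    universe: set) -> list[TermEnrichment]:
    """Per-term hypergeometric enrichment with BH correction across terms.

    Terms with no gene in the universe are dropped; results are sorted by
    q-value then term id.
    """
    for term, genes in term_to_genes.items():
        if not set(genes) <= universe:
            raise ValueError(f"term {term!r} has genes outside the universe")
    gene_set = set(gene_set) & universe
    N, n = len(universe), len(gene_set)
    results = []
    for term in sorted(term_to_genes):
        tg = set(term_to_genes[term]) & universe
        if not tg:
            continue
        k = len(gene_set & tg)
        p = 1.0 if n == 0 else float(stats.hypergeom.sf(k - 1, N, len(tg), n))
        results.append(TermEnrichment(term, k, len(tg), n, N, min(1.0, p)))
    if results:
        q = benjamini_hochberg([r.pvalue for r in results])
        for r, qi in zip(results, q):
            r.qvalue = float(qi)
    results.sort(key=lambda r: (r.qvalue, r.term))
    return results


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      exact_max_n: int = 8) -> tuple[float, float]:
    """Mann-Whitney U with a documented exact/approximate switch.

    Exact enumeration when min(|x|, |y|) <= ``exact_max_n`` and the pooled
    values have no ties; otherwise the normal approximation with tie and
    continuity corrections.  Returns (U for x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(x.size, y.size) <= exact_max_n and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(1.0, res.pvalue))


def compare_expression_by_group(expression: Mapping[str, float],
                                groups: Mapping[str, Sequence[str]]):
    """Pairwise Wilcoxon tests plus per-group median/quartile summaries.

    ``groups`` maps a label to a disjoint list of gene ids; groups with
    fewer than 2 measured genes get summaries but their tests are skipped
    (flagged with p = None).
    """
    labels = sorted(groups)
    seen: set[str] = set()
    for lab in labels:
        dup = seen & set(groups[lab])
        if dup:
            raise ValueError(f"groups not disjoint: {sorted(dup)[:3]}")
        seen |= set(groups[lab])
    values = {lab: np.array([expression[g] for g in groups[lab]
                             if g in expression]) for lab in labels}
    summaries = {
        lab: {
            "n": int(v.size),
            "median": float(np.median(v)) if v.size else float("nan"),
            "q1": float(np.percentile(v, 25)) if v.size else float("nan"),
            "q3": float(np.percentile(v, 75)) if v.size else float("nan"),
        }
        for lab, v in values.items()
    }
    tests = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if values[a].size < 2 or values[b].size < 2:
                tests[(a, b)] = {"U": None, "pvalue": None, "skipped": True}
            else:
                u, p = wilcoxon_rank_sum(values[a], values[b])
                tests[(a, b)] = {"U": u, "pvalue": p, "skipped": False}
    return tests, summaries
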