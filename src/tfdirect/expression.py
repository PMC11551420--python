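"""Count normalization, NB differential testing, and direct-target calls.

The differential-expression engine is a deliberately compact two-group
negative-binomial exact test: counts are rescaled to a common effective
library size by trimmed-mean-of-M-values (TMM) factors, a common
dispersion is estimated by the method of moments across genes, and the
p-value comes from the conditional distribution of one group's summed
count given the two-group total.  A gene is "coexpressed" with the TF
when it is up-regulated at least ``min_fold``-fold (FDR < ``fdr_max``)
in at least ``min_contrasts`` of the supplied tissue contrasts; direct
targets are the intersection of bound and coexpressed genes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DEResult",
    "tmm_factors",
    "estimate_common_dispersion",
    "nb_exact_test",
    "benjamini_hochberg",
    "call_coexpressed",
    "call_direct_targets",
]


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts with sample groups."""

    counts: pd.DataFrame                 # index = genes, columns = samples
    groups: dict[str, str]               # sample -> group label

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, groups: dict[str, str]) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, groups)


@dataclass
class DEResult:
    gene_id: str
    log2fc: float
    pvalue: float
    fdr: float


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """Per-sample effective size factors by trimmed mean of M-values.

    M and A values are computed on raw counts against a reference sample
    (the one whose upper quartile is closest to the mean upper quartile),
    genes zero in either sample are dropped, the ``trim_m``/``trim_a``
    extremes of M and A are doubly trimmed, and the factor is 2 to the
    precision-weighted mean of the surviving M values.  Factors absorb
    sequencing depth and are normalized to geometric mean 1, so dividing
    each sample's counts by its factor puts all samples on a common scale.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    mat = counts.to_numpy(dtype=float)
    if (mat.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample")
    uq = np.percentile(mat, 75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    yref = mat[:, ref]

    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        yj = mat[:, j]
        keep = (yj > 0) & (yref > 0)
        if not keep.any():
            raise ValueError(
                f"sample {counts.columns[j]} shares no nonzero gene with "
                "the reference")
        m = np.log2(yj[keep]) - np.log2(yref[keep])
        a = 0.5 * (np.log2(yj[keep]) + np.log2(yref[keep]))
        w = 1.0 / (1.0 / yj[keep] + 1.0 / yref[keep])   # delta-method precision
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not sel.any():
            sel = np.ones_like(m, dtype=bool)
        log_factors[j] = np.sum(w[sel] * m[sel]) / np.sum(w[sel])

    log_factors -= log_factors.mean()     # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=counts.columns)


def estimate_common_dispersion(scaled: np.ndarray,
                               group_cols: Sequence[np.ndarray]) -> float:
    """Method-of-moments common NB dispersion across genes.

    For each gene and group, (var - mean) / mean^2 estimates the
    dispersion; the estimates are pooled by precision (mean^2) weighting
    over genes with positive mean and floored at a small positive value.
    """
    num = 0.0
    den = 0.0
    for cols in group_cols:
        sub = scaled[:, cols]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 1.0
        num += np.sum(v[ok] - m[ok])
        den += np.sum(m[ok] ** 2)
    if den <= 0:
        return 1e-6
    return max(1e-6, num / den)


def _conditional_nb_pvalue(ya: int, yb: int, n_a: int, n_b: int,
                           phi: float) -> float:
    """Exact two-sided p for group sums conditional on the total.

    Group sums of n i.i.d. NB(mu, phi) counts are NB(n*mu, phi/n); with
    samples on a common scale, P(Y_A = y | Y_A + Y_B = t) is the ratio of
    NB pmf products, and the p-value sums all conditional outcomes no more
    probable than the observed one.  As phi -> 0 this reduces to binomial
    conditioning (the Poisson limit).
    """
    t = ya + yb
    if t == 0:
        return 1.0
    y = np.arange(t + 1)
    if phi < 1e-8:
        logp = stats.binom.logpmf(y, t, n_a / (n_a + n_b))
    else:
        r_a, r_b = n_a / phi, n_b / phi
        # success prob cancels in the conditional; use p=0.5 for stability
        logp = (stats.nbinom.logpmf(y, r_a, 0.5)
                + stats.nbinom.logpmf(t - y, r_b, 0.5))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return float(min(1.0, p[p <= p[ya] * (1 + 1e-8)].sum()))


def nb_exact_test(counts: CountMatrix, group_a: str, group_b: str,
                  dispersion: float | None = None,
                  pseudo_count: float = 0.5) -> list[DEResult]:
    """Two-group NB exact test on TMM-rescaled counts.

    log2fc is group B over group A from normalized means with a
    ``pseudo_count`` guard; FDR is Benjamini-Hochberg over all genes.
    Genes all-zero in both groups get p = 1 and log2fc = 0.
    """
    cols_a = [counts.samples.index(s) for s in counts.samples_in_group(group_a)]
    cols_b = [counts.samples.index(s) for s in counts.samples_in_group(group_b)]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    sub = counts.counts.iloc[:, cols_a + cols_b]
    factors = tmm_factors(sub).to_numpy()
    scaled = sub.to_numpy(dtype=float) / factors
    ia = np.arange(len(cols_a))
    ib = np.arange(len(cols_a), len(cols_a) + len(cols_b))
    if dispersion is None:
        dispersion = estimate_common_dispersion(scaled, [ia, ib])

    rounded = np.rint(scaled).astype(np.int64)
    ya = rounded[:, ia].sum(axis=1)
    yb = rounded[:, ib].sum(axis=1)
    mean_a = scaled[:, ia].mean(axis=1)
    mean_b = scaled[:, ib].mean(axis=1)
    log2fc = np.log2(mean_b + pseudo_count) - np.log2(mean_a + pseudo_count)

    pvals = np.ones(len(sub))
    for i in range(len(sub)):
        if ya[i] + yb[i] > 0:
            pvals[i] = _conditional_nb_pvalue(
                int(ya[i]), int(yb[i]), len(ia), len(ib), dispersion)
        else:
            log2fc[i] = 0.0
    fdr = benjamini_hochberg(pvals)
    return [DEResult(g, float(log2fc[i]), float(pvals[i]), float(fdr[i]))
            for i, g in enumerate(sub.index)]


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up BH q-values, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_results_to_frame(results: Iterable[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.log2fc, r.pvalue, r.fdr) for r in results],
        columns=["gene", "log2fc", "pvalue", "fdr"]).set_index("gene")


def call_coexpressed(de_tables: Sequence[pd.DataFrame], min_fold: float = 2,
                     fdr_max: float = 0.01, min_contrasts: int = 2) -> set[str]:
    """Genes up-regulated (>= min_fold, FDR < fdr_max) in enough contrasts.

    Each table must carry ``log2fc`` and ``fdr`` columns indexed by gene
    (as written by :func:`de_results_to_frame`).
    """
    if len(de_tables) < min_contrasts:
        raise ValueError(
            f"need >= {min_contrasts} contrast tables, got {len(de_tables)}")
    lfc_min = np.log2(min_fold)
    hits: dict[str, int] = {}
    for tab in de_tables:
        passed = tab.index[(tab["log2fc"] >= lfc_min) & (tab["fdr"] < fdr_max)]
        for g in passed:
            hits[g] = hits.get(g, 0) + 1
    return {g for g, n in hits.items() if n >= min_contrasts}


def call_direct_targets(bound: set[str], coexpressed: set[str]) -> set[str]:
    """Direct targets = genes both bound by the TF and coexpressed with it."""
    return set(bound) & set(coexpressed)
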