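"""Pairwise mutual-exclusivity screen on the binary mutation matrix.

For each candidate gene paired with each anchor (de/methylation) gene, a
2x2 contingency table of mutation co-occurrence is built and tested:

* exact two-sided Fisher p-value — the sum of hypergeometric probabilities
  of all tables with the observed margins no more likely than the observed
  table, computed in log-space via log-gamma;
* odds ratio OR = (a*d)/(b*c), Haldane-Anscombe corrected (+0.5 on every
  cell) whenever a zero cell would make it degenerate.

Pairs with OR < 0.5 show a strong tendency toward mutual exclusivity; OR > 2
toward co-occurrence. An additional significance gate (p <= 0.05 by default)
suppresses rare-gene pairs whose OR is small purely by sparsity, and
Benjamini-Hochberg q-values are attached over all tested pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .mutmatrix import AnchorPanel, BinaryMutationMatrix

logger = logging.getLogger("mutexm")

#: Relative tolerance for including tables tied with the observed probability
#: in the two-sided sum (floating-point-safe inclusion of exact ties).
TIE_RTOL = 1e-7


class InconsistentCountsError(ValueError):
    """Marginal counts that cannot form a valid 2x2 table."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for one gene pair: a = both mutated, b = A only, c = B only,
    d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("table total must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def transpose(self) -> "ContingencyTable2x2":
        """Swap the roles of gene A and gene B."""
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class PairResult:
    gene_a: str
    gene_b: str
    table: ContingencyTable2x2
    odds_ratio: float
    p_value: float
    q_value: float
    call: str  # exclusive | co_occurring | neutral


@dataclass
class ScreenConfig:
    """Thresholds of the screen.

    or_exclusive_max
        Call a pair exclusive when OR is below this (default 0.5).
    or_cooccur_min
        Call a pair co-occurring when OR is above this (default 2.0).
    p_max
        Significance gate applied to both calls; set to 1 to disable.
    fdr_method
        "bh" for Benjamini-Hochberg q-values over all tested pairs,
        "none" for q = p.
    """

    or_exclusive_max: float = 0.5
    or_cooccur_min: float = 2.0
    p_max: float = 0.05
    fdr_method: str = "bh"

    def __post_init__(self) -> None:
        if not 0 < self.or_exclusive_max < self.or_cooccur_min:
            raise ValueError(
                "need 0 < or_exclusive_max < or_cooccur_min, got "
                f"{self.or_exclusive_max} / {self.or_cooccur_min}"
            )
        if not 0 < self.p_max <= 1:
            raise ValueError(f"p_max must be in (0, 1], got {self.p_max}")
        if self.fdr_method not in ("bh", "none"):
            raise ValueError(f"fdr_method must be 'bh' or 'none', got {self.fdr_method!r}")


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------


def contingency(m: BinaryMutationMatrix, gene_a: str, gene_b: str) -> ContingencyTable2x2:
    """2x2 co-mutation table for a gene pair from the binary matrix."""
    if gene_a == gene_b:
        raise ValueError(f"gene_a and gene_b are both {gene_a!r}")
    x = m.column(gene_a).astype(bool)
    y = m.column(gene_b).astype(bool)
    return ContingencyTable2x2(
        a=int(np.count_nonzero(x & y)),
        b=int(np.count_nonzero(x & ~y)),
        c=int(np.count_nonzero(~x & y)),
        d=int(np.count_nonzero(~x & ~y)),
    )


def table_from_counts(
    n_total: int, n_a: int, n_b: int, n_both: int
) -> tuple[ContingencyTable2x2, int]:
    """Build a table from published marginal counts.

    Returns the table and the union size (samples mutated in at least one of
    the two genes), the quantity cohort meta-analyses typically report.
    """
    if n_both > min(n_a, n_b):
        raise InconsistentCountsError(
            f"n_both ({n_both}) > min(n_a, n_b) ({min(n_a, n_b)})"
        )
    union = n_a + n_b - n_both
    if union > n_total:
        raise InconsistentCountsError(
            f"n_a + n_b - n_both ({union}) > n_total ({n_total})"
        )
    table = ContingencyTable2x2(
        a=n_both, b=n_a - n_both, c=n_b - n_both, d=n_total - union
    )
    return table, union


# ---------------------------------------------------------------------------
# Fisher exact test (log-space)
# ---------------------------------------------------------------------------


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value, computed by log-space enumeration.

    Conditional on the margins, the (1,1) cell follows a hypergeometric
    distribution over its full support; the two-sided p is the sum of the
    probabilities of all support points whose probability does not exceed
    the observed one (within relative tolerance ``TIE_RTOL``). Degenerate
    margins (an empty row or column) give p = 1 by convention.
    """
    a, b, c, d = t.counts
    n = t.n
    r1, c1 = a + b, a + c  # margin of gene A mutants, gene B mutants
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        logger.debug("degenerate margins in %s; p = 1 by convention", t.counts)
        return 1.0
    # canonical margin order: makes the computation exactly transpose-symmetric
    if r1 > c1:
        r1, c1 = c1, r1

    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    # log P[X = k] for hypergeometric(n, r1, c1)
    logp = _log_binom(r1, k) + _log_binom(n - r1, c1 - k) - _log_binom(n, c1)
    log_obs = float(logp[a - lo])
    include = logp <= log_obs + math.log1p(TIE_RTOL)
    # stable summation of the selected probabilities
    sel = logp[include]
    m = float(sel.max())
    p = math.exp(m) * float(np.exp(sel - m).sum())
    return min(p, 1.0)


def odds_ratio(t: ContingencyTable2x2, correction: str = "haldane") -> float:
    """Odds ratio (a*d)/(b*c) of the 2x2 table.

    With ``correction="haldane"`` (default), 0.5 is added to every cell
    whenever any cell is zero, keeping the ratio finite and the OR < 0.5
    exclusivity cutoff well-defined. With ``correction="none"`` a zero
    denominator yields +inf (or 0/0 -> nan is avoided: an all-determined
    table with both b = c = 0 gives +inf, both a = d = 0 gives 0).
    """
    a, b, c, d = (float(x) for x in t.counts)
    if correction == "haldane":
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)
    if correction == "none":
        num, den = a * d, b * c
        if den == 0:
            return math.inf if num > 0 else 0.0
        return num / den
    raise ValueError(f"unknown correction {correction!r}")


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------


def _classify(or_value: float, p: float, cfg: ScreenConfig) -> str:
    if p <= cfg.p_max and or_value < cfg.or_exclusive_max:
        return "exclusive"
    if p <= cfg.p_max and or_value > cfg.or_cooccur_min:
        return "co_occurring"
    return "neutral"


def screen_pairs(
    m: BinaryMutationMatrix,
    anchors: AnchorPanel | Iterable[str] = None,
    cfg: ScreenConfig | None = None,
) -> list[PairResult]:
    """Test every candidate x anchor pair (plus anchor x anchor pairs).

    The pair universe is each non-anchor gene against each anchor, together
    with all anchor-anchor pairs (the de/methylation genes are themselves
    mutually exclusive with one another). Results carry BH q-values over all
    tested pairs and are sorted by p ascending, ties broken by gene names.
    """
    if anchors is None:
        anchors = AnchorPanel()
    elif not isinstance(anchors, AnchorPanel):
        anchors = AnchorPanel(tuple(anchors))
    cfg = cfg or ScreenConfig()

    anchor_genes = anchors.present_in(m)
    if not anchor_genes:
        raise ValueError("no anchor genes present in the matrix")
    anchor_set = set(anchor_genes)
    candidates = [g for g in m.genes if g not in anchor_set]

    pairs: list[tuple[str, str]] = []
    for cand in candidates:
        for anc in anchor_genes:
            pairs.append((cand, anc))
    for i, g1 in enumerate(anchor_genes):
        for g2 in anchor_genes[i + 1:]:
            pairs.append((g1, g2))

    tables = [contingency(m, ga, gb) for ga, gb in pairs]
    pvals = np.array([fisher_exact_two_sided(t) for t in tables])
    ors = [odds_ratio(t) for t in tables]
    if cfg.fdr_method == "bh":
        qvals = multipletests(pvals, method="fdr_bh")[1]
    else:
        qvals = pvals

    results = [
        PairResult(ga, gb, t, o, float(p), float(q), _classify(o, p, cfg))
        for (ga, gb), t, o, p, q in zip(pairs, tables, ors, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.gene_a, r.gene_b))
    return results


def results_to_frame(results: Iterable[PairResult]) -> pd.DataFrame:
    """Tabulate screen results in the output TSV layout."""
    rows = [
        {
            "gene_a": r.gene_a,
            "gene_b": r.gene_b,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "odds_ratio": r.odds_ratio,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "call": r.call,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "a", "b", "c", "d",
                 "odds_ratio", "p_value", "q_value", "call"],
    )
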