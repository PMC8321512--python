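"""Differential-expression thresholding and gene-set overlap statistics.

A DE result table (gene, log2 fold change, optional p/q) is thresholded
into up- and down-regulated gene sets at |log2FC| >= 0.585 (a 1.5-fold
change; the boundary is inclusive). Overlap between two gene sets within a
stated universe is quantified by the upper-tail hypergeometric probability
P[X >= k], computed in log-space, together with the overlap as a percentage
of each set — the form in which such overlaps are usually reported. The
p-value depends on the universe choice, which is therefore always explicit
in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

#: log2(1.5) to printed precision: "at least 1.5-fold" up or down.
DEFAULT_LOG2FC_MIN = 0.585


@dataclass
class DETable:
    """Per-gene differential-expression results with unique gene symbols."""

    frame: pd.DataFrame  # columns: gene, log2fc[, p, q]

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if not {"gene", "log2fc"} <= set(df.columns):
            raise ValueError("DE table needs columns 'gene' and 'log2fc'")
        df["gene"] = df["gene"].astype(str).str.upper()
        if df["gene"].duplicated().any():
            dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate genes in DE table: {dups[:5]}")
        if not np.isfinite(df["log2fc"]).all():
            raise ValueError("log2fc must be finite")
        for col in ("p", "q"):
            if col in df.columns:
                vals = df[col].dropna()
                if ((vals < 0) | (vals > 1)).any():
                    raise ValueError(f"{col} values must lie in [0, 1]")
        self.frame = df

    @property
    def genes(self) -> set[str]:
        return set(self.frame["gene"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DETable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GeneSet:
    """A named set of (upper-cased, unique) gene symbols."""

    name: str
    genes: frozenset[str]

    def __init__(self, name: str, genes: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes",
                           frozenset(str(g).upper() for g in genes))

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "GeneSet":
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()
                 if ln.strip() and not ln.startswith("#")]
        return cls(name or Path(path).stem, lines)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(sorted(self.genes)) + "\n")


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    pct_of_a: float
    pct_of_b: float
    p_hyper: float


# ---------------------------------------------------------------------------
# DE thresholding
# ---------------------------------------------------------------------------


def threshold_de(
    t: DETable,
    log2fc_min: float = DEFAULT_LOG2FC_MIN,
    require_sig: bool = False,
    q_max: float = 0.05,
) -> tuple[GeneSet, GeneSet]:
    """Split a DE table into up- and down-regulated gene sets.

    ``up`` collects genes with log2fc >= log2fc_min, ``down`` those with
    log2fc <= -log2fc_min (both boundaries inclusive, matching an "at least
    1.5-fold" change at the default cutoff). With ``require_sig``, genes
    must additionally satisfy q <= q_max.
    """
    if t.frame.empty:
        raise ValueError("empty DE table")
    if log2fc_min <= 0:
        raise ValueError("log2fc_min must be positive")
    df = t.frame
    if require_sig:
        if "q" not in df.columns:
            raise ValueError("require_sig needs a 'q' column in the DE table")
        sig = df["q"] <= q_max
    else:
        sig = pd.Series(True, index=df.index)
    up = GeneSet("up", df.loc[sig & (df["log2fc"] >= log2fc_min), "gene"])
    down = GeneSet("down", df.loc[sig & (df["log2fc"] <= -log2fc_min), "gene"])
    return up, down


# ---------------------------------------------------------------------------
# Hypergeometric overlap
# ---------------------------------------------------------------------------


def _log_binom(n: int, k) -> np.ndarray:
    return gammaln(n + 1) - gammaln(np.asarray(k) + 1) - gammaln(n - np.asarray(k) + 1)


def hypergeom_upper_tail(k: int, n_universe: int, n_a: int, n_b: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(n_universe, n_a, n_b), in log-space.

    X is the overlap size of a random n_b-subset with a fixed n_a-subset of
    the universe.
    """
    if n_a > n_b:  # canonical order: exactly symmetric in the two sets
        n_a, n_b = n_b, n_a
    lo = max(k, max(0, n_a + n_b - n_universe))
    hi = min(n_a, n_b)
    if lo > hi:
        return 0.0 if k > hi else 1.0
    if k <= max(0, n_a + n_b - n_universe):
        return 1.0  # the whole support is counted
    j = np.arange(lo, hi + 1)
    logp = (_log_binom(n_a, j) + _log_binom(n_universe - n_a, n_b - j)
            - _log_binom(n_universe, n_b))
    m = float(logp.max())
    p = math.exp(m) * float(np.exp(logp - m).sum())
    return min(p, 1.0)


def overlap_test(a: GeneSet, b: GeneSet, universe: GeneSet) -> OverlapResult:
    """Overlap counts, percentages and hypergeometric enrichment p.

    Both sets must be contained in the universe; the upper-tail p is the
    probability of an overlap at least as large under random draws of the
    two sets' sizes from the universe.
    """
    for s in (a, b):
        stray = sorted(s.genes - universe.genes)
        if stray:
            raise ValueError(
                f"set {s.name!r} not contained in universe; offending genes: {stray[:10]}"
            )
    if len(universe) == 0 or max(len(a), len(b)) == 0:
        raise ValueError("universe and at least one set must be non-empty")
    k = len(a.genes & b.genes)
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_overlap=k,
        n_universe=len(universe),
        pct_of_a=100.0 * k / len(a) if len(a) else 0.0,
        pct_of_b=100.0 * k / len(b) if len(b) else 0.0,
        p_hyper=hypergeom_upper_tail(k, len(universe), len(a), len(b)),
    )


def venn_counts(sets: Sequence[GeneSet]) -> dict[str, int]:
    """Disjoint-region counts for 2 or 3 gene sets.

    Region keys are '100', '010', '110', ... — one digit per input set,
    1 meaning the region lies inside that set. Counts sum to the union size.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError(f"venn_counts supports 2 or 3 sets, got {len(sets)}")
    union = frozenset().union(*(s.genes for s in sets))
    counts: dict[str, int] = {}
    n = len(sets)
    for bits in range(1, 2 ** n):
        key = format(bits, f"0{n}b")
        region = set(union)
        for i, s in enumerate(sets):
            if key[i] == "1":
                region &= s.genes
            else:
                region -= s.genes
        counts[key] = len(region)
    return counts
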