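"""Methylation beta-value signature analysis.

Given a CpG x sample matrix of array beta-values (methylated fraction per
CpG, in [0,1]), the analysis (i) keeps the most variably methylated probes
(sample SD above a cutoff, or a top-n by SD), (ii) clusters samples
hierarchically on those probes, and (iii) compares per-sample average beta
across mutation-defined groups with one-way ANOVA and Bonferroni-adjusted
pairwise tests against a control group, calling each group hypo- or
hyper-methylated relative to control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist
from scipy import stats

logger = logging.getLogger("mutexm")


class EmptyResultError(ValueError):
    """A filter removed every row; the caller should relax the cutoff."""


@dataclass
class BetaMatrix:
    """CpG x sample methylation fractions; NaN marks a missing value."""

    cpg_ids: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_cpgs, n_samples), float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValueError("duplicate CpG ids")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if self.values.shape != (len(self.cpg_ids), len(self.samples)):
            raise ValueError("value shape does not match id lists")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=pd.Index(self.cpg_ids, name="probe_id"),
                            columns=self.samples)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls([str(i) for i in df.index], [str(c) for c in df.columns],
                   df.to_numpy(dtype=float))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BetaMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class GroupLabels:
    """sample_id -> group label (e.g. DNMT3A-mut, IDH-mut, CBFB-mut, control)."""

    labels: dict[str, str]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.labels.items():
            out.setdefault(g, []).append(s)
        return out

    def validate_against(self, b: BetaMatrix) -> None:
        unknown = sorted(set(self.labels) - set(b.samples))
        if unknown:
            raise ValueError(f"labeled samples not in matrix: {unknown}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupLabels":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample", "group"} <= set(df.columns):
            raise ValueError(f"{path}: need columns 'sample' and 'group'")
        return cls(dict(zip(df["sample"], df["group"])))


@dataclass
class Dendrogram:
    """Sample dendrogram as a scipy linkage matrix plus the leaf order."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaves: list[str]    # sample ids in input order (leaf index -> id)

    def cut(self, k: int) -> dict[str, int]:
        """Cut into k clusters; returns sample -> cluster label (1..k)."""
        if not 1 <= k <= len(self.leaves):
            raise ValueError(f"k must be in [1, {len(self.leaves)}]")
        flat = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.leaves, (int(c) for c in flat)))

    def to_newick(self) -> str:
        """Serialize as a Newick string with merge-height branch lengths."""
        tree = sch.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


# ---------------------------------------------------------------------------
# Probe selection
# ---------------------------------------------------------------------------


def select_variable_cpgs(
    b: BetaMatrix,
    sd_min: float | None = None,
    top_n: int | None = None,
) -> BetaMatrix:
    """Keep the most variably methylated CpGs.

    Exactly one of ``sd_min`` (keep probes with sample SD strictly above the
    cutoff; n-1 denominator) or ``top_n`` (keep the n largest-SD probes, ties
    broken by probe id) must be given. Probes with any missing value are
    excluded before ranking.
    """
    if (sd_min is None) == (top_n is None):
        raise ValueError("give exactly one of sd_min or top_n")
    if b.n_samples < 2:
        raise ValueError("need at least 2 samples to compute SD")

    complete = ~np.isnan(b.values).any(axis=1)
    idx = np.flatnonzero(complete)
    sds = b.values[idx].std(axis=1, ddof=1)

    if sd_min is not None:
        sel = idx[sds > sd_min]
    else:
        order = sorted(range(len(idx)), key=lambda i: (-sds[i], b.cpg_ids[idx[i]]))
        sel = idx[order[: top_n]]
        sel = np.sort(sel)  # preserve input probe order
    if sel.size == 0:
        raise EmptyResultError(
            "no CpGs passed the variability filter; lower sd_min or use top_n"
        )
    return BetaMatrix([b.cpg_ids[i] for i in sel], list(b.samples),
                      b.values[sel])


# ---------------------------------------------------------------------------
# Hierarchical clustering of samples
# ---------------------------------------------------------------------------


def hierarchical_cluster(
    b: BetaMatrix,
    distance: str = "euclidean",
    linkage: str = "complete",
) -> Dendrogram:
    """Agglomerative clustering of samples (columns) of the beta matrix.

    distance: "euclidean" or "one_minus_pearson"; linkage: "complete",
    "average" or "ward" (ward requires euclidean distance). Missing values
    must be filtered out beforehand (see :func:`select_variable_cpgs`).
    """
    if b.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    if np.isnan(b.values).any():
        raise ValueError("beta matrix contains missing values; filter first")
    if linkage not in ("complete", "average", "ward"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    X = b.values.T  # samples as rows
    if distance == "euclidean":
        dists = pdist(X, metric="euclidean")
    elif distance == "one_minus_pearson":
        if linkage == "ward":
            raise ValueError("ward linkage requires euclidean distance")
        dists = pdist(X, metric="correlation")
    else:
        raise ValueError(f"unsupported distance {distance!r}")
    Z = sch.linkage(dists, method=linkage)
    return Dendrogram(Z, list(b.samples))


# ---------------------------------------------------------------------------
# Average beta and group comparison
# ---------------------------------------------------------------------------


def mean_beta(b: BetaMatrix) -> dict[str, float]:
    """Per-sample arithmetic mean beta over non-missing CpGs."""
    if b.n_cpgs == 0 or b.n_samples == 0:
        raise ValueError("empty beta matrix")
    out: dict[str, float] = {}
    for j, s in enumerate(b.samples):
        col = b.values[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            logger.warning("sample %s has no non-missing CpGs; excluded", s)
            continue
        out[s] = float(col.mean())
    return out


@dataclass
class MethylGroupSummary:
    """Group-level summary of average methylation.

    group_means / group_sds are per retained group; anova_f / anova_p the
    one-way ANOVA across them; pairwise_p the Bonferroni-adjusted two-sample
    p vs control; direction the hypo/hyper/none call per non-control group.
    """

    per_sample: dict[str, float]
    group_means: dict[str, float]
    group_sds: dict[str, float]
    anova_f: float
    anova_p: float
    pairwise_p: dict[str, float]
    direction: dict[str, str]
    control: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.group_means:
            rows.append({
                "group": g,
                "mean_beta": self.group_means[g],
                "sd_beta": self.group_sds[g],
                "p_vs_control_bonf": self.pairwise_p.get(g, np.nan),
                "direction": self.direction.get(g, "control"),
            })
        return pd.DataFrame(rows)


def compare_groups(
    avg: Mapping[str, float],
    g: GroupLabels,
    control: str,
    alpha: float = 0.05,
) -> MethylGroupSummary:
    """Compare per-sample average beta across groups.

    One-way ANOVA across all retained groups (those with >= 2 labeled
    samples that have an average), then each non-control group vs control by
    a pooled-variance two-sample t-test, Bonferroni-multiplied by the number
    of pairwise tests. A group is called ``hypo`` when its mean is below the
    control mean with adjusted p <= alpha, ``hyper`` when above, else
    ``none``. Degenerate zero-variance data give p = 1 when all group means
    are equal and p = 0 otherwise.
    """
    by_group: dict[str, np.ndarray] = {}
    for grp, samps in g.groups().items():
        vals = np.array([avg[s] for s in samps if s in avg])
        if vals.size < 2:
            logger.warning("group %s has <2 samples with data; excluded", grp)
            continue
        by_group[grp] = vals
    if control not in by_group:
        raise ValueError(f"control group {control!r} absent or too small")
    if len(by_group) < 2:
        raise ValueError("need >=2 groups with >=2 samples each")

    groups = list(by_group)
    arrays = [by_group[k] for k in groups]
    means = {k: float(v.mean()) for k, v in by_group.items()}
    sds = {k: float(v.std(ddof=1)) for k, v in by_group.items()}

    within_var = sum(float(((v - v.mean()) ** 2).sum()) for v in arrays)
    if within_var == 0.0:
        equal = len({round(m, 12) for m in means.values()}) == 1
        anova_f, anova_p = (0.0, 1.0) if equal else (np.inf, 0.0)
        logger.warning("zero within-group variance; ANOVA p set to %g", anova_p)
    else:
        anova_f, anova_p = (float(x) for x in stats.f_oneway(*arrays))

    others = [k for k in groups if k != control]
    m_tests = len(others)
    pairwise_p: dict[str, float] = {}
    direction: dict[str, str] = {}
    ctrl = by_group[control]
    for k in others:
        grp = by_group[k]
        pooled_var = (((grp - grp.mean()) ** 2).sum() + ((ctrl - ctrl.mean()) ** 2).sum())
        if pooled_var == 0.0:
            p_raw = 1.0 if np.isclose(grp.mean(), ctrl.mean()) else 0.0
        else:
            p_raw = float(stats.ttest_ind(grp, ctrl, equal_var=True).pvalue)
        p_adj = min(1.0, m_tests * p_raw)
        pairwise_p[k] = p_adj
        if p_adj <= alpha and means[k] < means[control]:
            direction[k] = "hypo"
        elif p_adj <= alpha and means[k] > means[control]:
            direction[k] = "hyper"
        else:
            direction[k] = "none"

    return MethylGroupSummary(
        per_sample=dict(avg),
        group_means=means,
        group_sds=sds,
        anova_f=float(anova_f),
        anova_p=float(anova_p),
        pairwise_p=pairwise_p,
        direction=direction,
        control=control,
    )
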