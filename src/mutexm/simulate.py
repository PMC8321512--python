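"""Synthetic generators for every input class the pipeline consumes.

Three generators emulate the statistical structure of the real inputs so the
whole pipeline can be exercised without downloads:

* mutation matrices with independent background genes plus gene pairs
  planted at a chosen marginal rate and odds ratio (the joint Bernoulli
  distribution with given margins and OR has a closed form: the (1,1) cell
  probability is the root of a quadratic inside the Frechet bounds);
* 450K-style beta matrices with a bimodal baseline (CpGs cluster near fully
  unmethylated and fully methylated), group-specific shifts applied on the
  logit scale to a block of signature CpGs, and logit-normal noise;
* DE tables from per-gene two-condition normal expression on the log2
  scale, Welch-tested with BH q-values.

Every generator is deterministic given its seed and returns ground-truth
labels alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit
from statsmodels.stats.multitest import multipletests

from .methylation import BetaMatrix, GroupLabels
from .mutmatrix import BinaryMutationMatrix
from .overlap import DETable


class InfeasibleConfigError(ValueError):
    """A requested (margins, odds ratio) combination has no joint law."""


# ---------------------------------------------------------------------------
# Mutation matrices
# ---------------------------------------------------------------------------


@dataclass
class PlantedPair:
    """One gene pair with prescribed margins and odds ratio."""

    rate_a: float
    rate_b: float
    target_or: float

    def __post_init__(self) -> None:
        for r in (self.rate_a, self.rate_b):
            if not 0 < r < 1:
                raise ValueError(f"rates must be in (0, 1), got {r}")
        if not self.target_or > 0:
            raise ValueError(f"target_or must be positive, got {self.target_or}")


@dataclass
class MutSimConfig:
    n_samples: int = 1000
    n_background_genes: int = 50
    background_rate_range: tuple[float, float] = (0.05, 0.20)
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        lo, hi = self.background_rate_range
        if not (0 < lo <= hi < 1):
            raise ValueError("background rates must satisfy 0 < lo <= hi < 1")


def joint_cell_probability(rate_a: float, rate_b: float, target_or: float) -> float:
    """P[A=1, B=1] for the Bernoulli pair with the given margins and OR.

    Solves (1-psi) p11^2 + [1 + (psi-1)(pa+pb)] p11 - psi pa pb = 0 and
    returns the root inside the Frechet bounds
    [max(0, pa+pb-1), min(pa, pb)]. For psi = 1 the equation is linear and
    gives the independence cell pa*pb.
    """
    pa, pb, psi = rate_a, rate_b, target_or
    lower = max(0.0, pa + pb - 1.0)
    upper = min(pa, pb)
    if math.isclose(psi, 1.0):
        p11 = pa * pb
    else:
        A = 1.0 - psi
        B = 1.0 + (psi - 1.0) * (pa + pb)
        C = -psi * pa * pb
        disc = B * B - 4 * A * C
        if disc < 0:
            raise InfeasibleConfigError(
                f"no joint law for rates ({pa}, {pb}) and OR {psi}"
            )
        sq = math.sqrt(disc)
        roots = [(-B + sq) / (2 * A), (-B - sq) / (2 * A)]
        valid = [r for r in roots if lower - 1e-12 <= r <= upper + 1e-12]
        if not valid:
            raise InfeasibleConfigError(
                f"rates ({pa}, {pb}) with OR {psi}: no root in the Frechet "
                f"interval [{lower:.6g}, {upper:.6g}]"
            )
        p11 = min(max(valid[0], lower), upper)
    return p11


def simulate_mutations(cfg: MutSimConfig) -> tuple[BinaryMutationMatrix, pd.DataFrame]:
    """Simulate a binary mutation matrix with planted pairs.

    Returns the matrix and a truth table with one row per planted pair
    (gene_a, gene_b, rate_a, rate_b, target_or, p11).  Background genes are
    named BG000..., planted genes PLa000/PLb000...
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    columns: dict[str, np.ndarray] = {}

    lo, hi = cfg.background_rate_range
    bg_rates = rng.uniform(lo, hi, size=cfg.n_background_genes)
    for i, r in enumerate(bg_rates):
        columns[f"BG{i:03d}"] = (rng.random(n) < r).astype(np.int8)

    truth_rows = []
    for i, pair in enumerate(cfg.planted_pairs):
        p11 = joint_cell_probability(pair.rate_a, pair.rate_b, pair.target_or)
        p10 = pair.rate_a - p11
        p01 = pair.rate_b - p11
        p00 = 1.0 - p11 - p10 - p01
        probs = np.array([p00, p01, p10, p11])
        probs = np.clip(probs, 0, None)
        probs /= probs.sum()
        draws = rng.choice(4, size=n, p=probs)
        ga, gb = f"PLA{i:03d}", f"PLB{i:03d}"
        columns[ga] = ((draws == 2) | (draws == 3)).astype(np.int8)
        columns[gb] = ((draws == 1) | (draws == 3)).astype(np.int8)
        truth_rows.append({
            "gene_a": ga, "gene_b": gb,
            "rate_a": pair.rate_a, "rate_b": pair.rate_b,
            "target_or": pair.target_or, "p11": p11,
        })

    genes = sorted(columns)
    values = np.column_stack([columns[g] for g in genes]) if genes else \
        np.zeros((n, 0), dtype=np.int8)
    matrix = BinaryMutationMatrix(
        samples=[f"S{i:05d}" for i in range(n)], genes=genes, values=values
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_a", "gene_b", "rate_a", "rate_b", "target_or", "p11"],
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Beta matrices
# ---------------------------------------------------------------------------


@dataclass
class BetaSimConfig:
    n_cpgs: int = 5000
    n_signature_cpgs: int = 500
    group_sizes: dict[str, int] = field(default_factory=lambda: {"control": 20, "mut": 20})
    group_shift: dict[str, float] = field(default_factory=lambda: {"mut": -1.0})
    noise_sd: float = 0.3
    # baseline beta mixture: Beta(a1,b1) near 0 and Beta(a2,b2) near 1
    baseline_mix: tuple[float, float, float, float, float] = (0.5, 2.0, 8.0, 8.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signature_cpgs > self.n_cpgs:
            raise ValueError("n_signature_cpgs cannot exceed n_cpgs")
        for g, s in self.group_sizes.items():
            if s < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.group_shift) - set(self.group_sizes)
        if unknown:
            raise ValueError(f"shifts for unknown groups: {sorted(unknown)}")


def simulate_beta(cfg: BetaSimConfig) -> tuple[BetaMatrix, GroupLabels, list[str]]:
    """Simulate a bimodal beta matrix with planted group-level shifts.

    Baseline per-CpG methylation is drawn from a two-component Beta mixture
    (mass near 0 and near 1, as array data exhibit). The first
    ``n_signature_cpgs`` probes are signature probes: their logit-mean is
    shifted by the group's delta for samples of that group. Logit-normal
    noise with SD ``noise_sd`` is added per (probe, sample), and values are
    mapped back through the logistic function, so everything stays in (0,1).

    Returns the matrix, group labels, and the list of signature probe ids.
    """
    rng = np.random.default_rng(cfg.seed)
    w, a1, b1, a2, b2 = cfg.baseline_mix
    n_cpg = cfg.n_cpgs

    comp = rng.random(n_cpg) < w
    base = np.where(comp, rng.beta(a1, b1, n_cpg), rng.beta(a2, b2, n_cpg))
    base = np.clip(base, 0.02, 0.98)  # keep logits finite
    base_logit = logit(base)

    samples: list[str] = []
    group_of: dict[str, str] = {}
    for gname, size in cfg.group_sizes.items():
        for i in range(size):
            sid = f"{gname}_{i:03d}"
            samples.append(sid)
            group_of[sid] = gname

    sig_ids = [f"cg{i:06d}" for i in range(cfg.n_signature_cpgs)]
    cpg_ids = sig_ids + [f"cg{i:06d}" for i in range(cfg.n_signature_cpgs, n_cpg)]

    values = np.empty((n_cpg, len(samples)))
    for j, sid in enumerate(samples):
        mu = base_logit.copy()
        delta = cfg.group_shift.get(group_of[sid], 0.0)
        if delta:
            mu[: cfg.n_signature_cpgs] += delta
        values[:, j] = expit(mu + rng.normal(0.0, cfg.noise_sd, n_cpg))

    return (
        BetaMatrix(cpg_ids, samples, values),
        GroupLabels(dict(group_of)),
        sig_ids,
    )


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------


@dataclass
class DESimConfig:
    n_genes: int = 2000
    n_up: int = 50
    n_down: int = 50
    effect_log2: float = 2.0
    null_sd: float = 0.5
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("planted counts exceed n_genes")
        if self.null_sd <= 0 or self.n_replicates < 2:
            raise ValueError("need null_sd > 0 and n_replicates >= 2")


def simulate_de(cfg: DESimConfig) -> tuple[DETable, pd.DataFrame]:
    """Simulate per-gene two-condition expression and a Welch-test DE table.

    Expression is normal on the log2 scale with per-gene SD ``null_sd``;
    planted up/down genes get a +/- ``effect_log2`` mean difference. The
    table carries the observed mean log2 fold change, the Welch t-test p and
    the BH q per gene; the truth table labels each gene up/down/null.
    """
    rng = np.random.default_rng(cfg.seed)
    n, r = cfg.n_genes, cfg.n_replicates
    effects = np.zeros(n)
    effects[: cfg.n_up] = cfg.effect_log2
    effects[cfg.n_up: cfg.n_up + cfg.n_down] = -cfg.effect_log2

    base = rng.uniform(2.0, 10.0, size=n)
    cond1 = rng.normal(base[:, None], cfg.null_sd, size=(n, r))
    cond2 = rng.normal((base + effects)[:, None], cfg.null_sd, size=(n, r))

    log2fc = cond2.mean(axis=1) - cond1.mean(axis=1)
    p = stats.ttest_ind(cond2, cond1, axis=1, equal_var=False).pvalue
    q = multipletests(p, method="fdr_bh")[1]

    genes = [f"G{i:05d}" for i in range(n)]
    table = DETable(pd.DataFrame({
        "gene": genes, "log2fc": log2fc, "p": p, "q": q,
    }))
    truth = pd.DataFrame({
        "gene": [g.upper() for g in genes],
        "label": np.where(effects > 0, "up", np.where(effects < 0, "down", "null")),
        "effect_log2": effects,
    })
    return table, truth
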