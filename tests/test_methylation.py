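import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mutexm import (
    BetaMatrix,
    GroupLabels,
    compare_groups,
    hierarchical_cluster,
    mean_beta,
    select_variable_cpgs,
)
from mutexm.methylation import EmptyResultError
from mutexm.simulate import BetaSimConfig, simulate_beta


def beta(values, cpgs=None, samples=None):
    values = np.asarray(values, dtype=float)
    cpgs = cpgs or [f"cg{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return BetaMatrix(cpgs, samples, values)


class TestSelectVariableCpgs:
    def test_constant_probe_dropped(self):
        b = beta([[0.5, 0.5, 0.5], [0.1, 0.5, 0.9]])
        out = select_variable_cpgs(b, sd_min=0.0)
        assert out.cpg_ids == ["cg1"]

    def test_two_sample_extremes_pass_027(self):
        # values (0, 1) across two samples: SD = sqrt(0.5) > 0.27
        b = beta([[0.0, 1.0], [0.4, 0.5]])
        out = select_variable_cpgs(b, sd_min=0.27)
        assert out.cpg_ids == ["cg0"]
        sd = np.std([0.0, 1.0], ddof=1)
        assert sd == pytest.approx(math.sqrt(0.5))

    def test_top_n_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, size=(10, 6))
        b = beta(vals)
        out = select_variable_cpgs(b, top_n=3)
        sds = vals.std(axis=1, ddof=1)
        expected = {b.cpg_ids[i] for i in np.argsort(-sds)[:3]}
        assert set(out.cpg_ids) == expected

    def test_missing_probe_excluded_before_ranking(self):
        b = beta([[0.0, 1.0, np.nan], [0.2, 0.5, 0.8]])
        out = select_variable_cpgs(b, sd_min=0.0)
        assert out.cpg_ids == ["cg1"]

    def test_all_filtered_raises(self):
        b = beta([[0.5, 0.5]])
        with pytest.raises(EmptyResultError):
            select_variable_cpgs(b, sd_min=0.9)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(1)
        b = beta(rng.uniform(0, 1, size=(50, 8)))
        keep_lo = set(select_variable_cpgs(b, sd_min=0.1).cpg_ids)
        keep_hi = set(select_variable_cpgs(b, sd_min=0.25).cpg_ids)
        assert keep_hi <= keep_lo

    def test_exactly_one_mode_required(self):
        b = beta([[0.1, 0.9]])
        with pytest.raises(ValueError):
            select_variable_cpgs(b)
        with pytest.raises(ValueError):
            select_variable_cpgs(b, sd_min=0.1, top_n=2)


class TestHierarchicalCluster:
    def test_two_samples_single_merge(self):
        b = beta([[0.1, 0.9], [0.2, 0.8]])
        d = hierarchical_cluster(b)
        assert d.linkage.shape == (1, 4)
        cut = d.cut(2)
        assert cut["S0"] != cut["S1"]

    def test_duplicate_columns_merge_at_zero(self):
        b = beta([[0.1, 0.1, 0.9], [0.3, 0.3, 0.6]])
        d = hierarchical_cluster(b, distance="euclidean", linkage="complete")
        assert d.linkage[0, 2] == 0.0
        first = {int(d.linkage[0, 0]), int(d.linkage[0, 1])}
        assert first == {0, 1}

    def test_recovers_planted_groups(self):
        cfg = BetaSimConfig(n_cpgs=2000, n_signature_cpgs=500,
                            group_sizes={"g1": 20, "g2": 20},
                            group_shift={"g2": -1.5}, noise_sd=0.3, seed=7)
        b, labels, _ = simulate_beta(cfg)
        sel = select_variable_cpgs(b, top_n=500)
        cut = hierarchical_cluster(sel).cut(2)
        truth = [labels.labels[s] for s in sel.samples]
        pred = [cut[s] for s in sel.samples]
        assert adjusted_rand_score(truth, pred) >= 0.9

    def test_partition_invariant_under_column_permutation(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, size=(30, 8))
        b = beta(vals)
        perm = rng.permutation(8)
        bp = BetaMatrix(b.cpg_ids, [b.samples[j] for j in perm], vals[:, perm])
        cut_a = hierarchical_cluster(b).cut(3)
        cut_b = hierarchical_cluster(bp).cut(3)
        # same partition of sample ids, up to cluster relabeling
        part_a = {frozenset(s for s in cut_a if cut_a[s] == k)
                  for k in set(cut_a.values())}
        part_b = {frozenset(s for s in cut_b if cut_b[s] == k)
                  for k in set(cut_b.values())}
        assert part_a == part_b

    def test_missing_values_rejected(self):
        b = beta([[0.1, np.nan], [0.2, 0.8]])
        with pytest.raises(ValueError, match="missing"):
            hierarchical_cluster(b)

    def test_ward_requires_euclidean(self):
        b = beta(np.random.default_rng(0).uniform(0, 1, (5, 4)))
        with pytest.raises(ValueError, match="ward"):
            hierarchical_cluster(b, distance="one_minus_pearson", linkage="ward")

    def test_newick_round_trips_leaf_names(self, tmp_path):
        from io import StringIO
        from Bio import Phylo

        b = beta(np.random.default_rng(2).uniform(0, 1, (20, 6)))
        nwk = hierarchical_cluster(b).to_newick()
        tree = Phylo.read(StringIO(nwk), "newick")
        assert {leaf.name for leaf in tree.get_terminals()} == set(b.samples)


class TestMeanBeta:
    def test_constant_matrix(self):
        b = beta(np.full((4, 3), 0.5))
        assert mean_beta(b) == {"S0": 0.5, "S1": 0.5, "S2": 0.5}

    def test_arithmetic(self):
        b = beta([[0.2], [0.4], [0.9]])
        assert mean_beta(b)["S0"] == pytest.approx(0.5)

    def test_all_missing_sample_excluded(self):
        b = beta([[np.nan, 0.5], [np.nan, 0.7]])
        out = mean_beta(b)
        assert "S0" not in out and out["S1"] == pytest.approx(0.6)

    def test_invariant_under_probe_reordering(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 1, (10, 4))
        b1 = beta(vals)
        perm = rng.permutation(10)
        b2 = BetaMatrix([b1.cpg_ids[i] for i in perm], b1.samples, vals[perm])
        assert mean_beta(b1) == pytest.approx(mean_beta(b2))


class TestCompareGroups:
    def test_planted_hypo_group_called(self):
        rng = np.random.default_rng(11)
        avg = {f"c{i}": v for i, v in enumerate(rng.normal(0.5, 0.03, 15))}
        avg |= {f"m{i}": v for i, v in enumerate(rng.normal(0.4, 0.03, 15))}
        labels = GroupLabels({s: ("control" if s.startswith("c") else "mut")
                              for s in avg})
        summ = compare_groups(avg, labels, control="control")
        assert summ.direction["mut"] == "hypo"
        assert summ.anova_p < 0.05

    def test_same_distribution_direction_none(self):
        rng = np.random.default_rng(12)
        avg = {f"s{i}": v for i, v in enumerate(rng.normal(0.5, 0.05, 30))}
        labels = GroupLabels({s: ("control" if i < 15 else "g2")
                              for i, s in enumerate(avg)})
        summ = compare_groups(avg, labels, control="control")
        assert summ.direction["g2"] == "none"

    def test_degenerate_identical_groups(self):
        avg = {"a1": 0.5, "a2": 0.5, "b1": 0.5, "b2": 0.5}
        labels = GroupLabels({"a1": "control", "a2": "control",
                              "b1": "g2", "b2": "g2"})
        summ = compare_groups(avg, labels, control="control")
        assert summ.anova_p == 1.0
        assert summ.direction["g2"] == "none"

    def test_degenerate_separated_groups(self):
        avg = {"a1": 0.5, "a2": 0.5, "b1": 0.3, "b2": 0.3}
        labels = GroupLabels({"a1": "control", "a2": "control",
                              "b1": "g2", "b2": "g2"})
        summ = compare_groups(avg, labels, control="control")
        assert summ.anova_p == 0.0
        assert summ.direction["g2"] == "hypo"

    def test_small_group_excluded_with_warning(self):
        avg = {"a1": 0.5, "a2": 0.52, "b1": 0.4, "b2": 0.42, "c1": 0.3}
        labels = GroupLabels({"a1": "control", "a2": "control",
                              "b1": "g2", "b2": "g2", "c1": "tiny"})
        summ = compare_groups(avg, labels, control="control")
        assert "tiny" not in summ.group_means

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(13)
        avg = {}
        groups = {}
        for g in ("control", "g2", "g3", "g4"):
            for i in range(10):
                s = f"{g}_{i}"
                avg[s] = float(rng.normal(0.5, 0.05))
                groups[s] = g
        summ = compare_groups(avg, GroupLabels(groups), control="control")
        assert all(0 < p <= 1 for p in summ.pairwise_p.values())

    def test_anova_p_uniform_under_null(self):
        # KS sanity check of the ANOVA p distribution across replicates
        import scipy.stats

        rng = np.random.default_rng(14)
        ps = []
        for _ in range(200):
            avg = {f"s{i}": v for i, v in enumerate(rng.normal(0.5, 0.05, 24))}
            labels = GroupLabels({s: ("control" if i < 12 else "g2")
                                  for i, s in enumerate(avg)})
            ps.append(compare_groups(avg, labels, control="control").anova_p)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01


def test_beta_matrix_validation():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        BetaMatrix(["cg0"], ["S0"], np.array([[1.5]]))
    with pytest.raises(ValueError, match="duplicate"):
        BetaMatrix(["cg0", "cg0"], ["S0"], np.zeros((2, 1)))
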