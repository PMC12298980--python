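"""Taxa screens: filtering, abundance classes, IndVal, network topology."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from emfkit.screen import (
    KeystoneRule,
    build_network,
    classify_abundance,
    detect_modules,
    filter_asvs,
    indicator_composite,
    indval,
    zi_pi,
)


def _ct(rows, taxa=None, samples=None):
    df = pd.DataFrame(rows)
    df.index = taxa or [f"t{i}" for i in range(len(df))]
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return df


class TestFilter:
    def test_minimum_count_in_enough_samples_retained(self):
        # 4 reads in 4 of 18 samples: 4 >= ceil(0.2 * 18) = 4 → kept
        row = [4] * 4 + [0] * 14
        ct = _ct([row, [1] + [0] * 17, [3] * 18])
        out = filter_asvs(ct)
        assert list(out.index) == ["t0"]  # singleton and the all-3s taxon go

    def test_prevalence_bounds_checked(self):
        with pytest.raises(ValueError):
            filter_asvs(_ct([[1]]), prevalence=0.0)

    def test_strict_mode_requires_every_sample(self):
        ct = _ct([[4, 4, 4], [4, 4, 3]])
        assert list(filter_asvs(ct, mode="strict").index) == ["t0"]


class TestAbundanceClasses:
    def test_threshold_classes(self):
        ct = _ct([[5], [150], [99_845]])
        out = classify_abundance(ct)
        assert out.loc["t0", "class"] == "rare"        # 0.005%
        assert out.loc["t1", "class"] == "abundant"    # 0.15%
        assert out.loc["t2", "class"] == "abundant"

    def test_exact_boundary_is_intermediate(self):
        ct = _ct([[10], [99_990]])  # exactly 0.01%
        assert classify_abundance(ct).loc["t0", "class"] == "intermediate"

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            classify_abundance(_ct([[0], [0]]))


class TestIndval:
    def test_perfect_indicator_scores_one(self):
        ct = _ct([[5, 8, 0, 0], [1, 1, 1, 1]])
        out = indval(ct, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert out.loc["t0", "indval"] == pytest.approx(1.0)
        assert out.loc["t0", "best_group"] == "a"

    def test_even_taxon_scores_sqrt_half(self):
        ct = _ct([[3, 3, 3, 3], [1, 2, 1, 2]])
        out = indval(ct, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert out.loc["t0", "indval"] == pytest.approx(np.sqrt(0.5), abs=1e-10)

    def test_indval_squared_equals_a_times_b(self):
        rng = np.random.default_rng(0)
        ct = _ct(rng.integers(0, 50, size=(20, 9)))
        out = indval(ct, ["a"] * 3 + ["b"] * 3 + ["c"] * 3, n_perm=49, seed=1)
        assert np.allclose(out["indval"] ** 2, out["A"] * out["B"], atol=1e-12)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """3+3 samples: the permutation p converges on the exact p over all
        C(6,3)=20 label assignments."""
        rng = np.random.default_rng(5)
        ct = _ct(rng.integers(0, 30, size=(4, 6)))
        labels = np.array(["a", "a", "a", "b", "b", "b"])

        def stat_for(lab):
            rel = (ct / ct.sum(axis=0)).T.to_numpy(float)
            pres = (rel > 0).astype(float)
            stats_ = []
            for k in range(ct.shape[0]):
                means = [rel[lab == g, k].mean() for g in ("a", "b")]
                bs = [pres[lab == g, k].mean() for g in ("a", "b")]
                a_ = [m / sum(means) if sum(means) else 0.0 for m in means]
                stats_.append(max(np.sqrt(np.array(a_) * np.array(bs))))
            return np.array(stats_)

        obs = stat_for(labels)
        exact = np.zeros(ct.shape[0])
        count = 0
        for pos in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(pos)] = "a"
            exact += stat_for(lab) >= obs - 1e-12
            count += 1
        exact_p = exact / count
        out = indval(ct, labels, n_perm=1999, seed=3)
        assert np.allclose(out["p_perm"], exact_p, atol=0.05)

    def test_invariant_to_permuting_samples_within_groups(self):
        rng = np.random.default_rng(2)
        ct = _ct(rng.integers(0, 40, size=(10, 6)))
        labels = ["a", "a", "a", "b", "b", "b"]
        base = indval(ct, labels, n_perm=9, seed=0)[["best_group", "A", "B", "indval"]]
        shuffled = ct[["s1", "s2", "s0", "s5", "s3", "s4"]]
        again = indval(shuffled, labels, n_perm=9, seed=0)[["best_group", "A", "B", "indval"]]
        pd.testing.assert_frame_equal(base, again)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            indval(_ct([[1, 2]]), ["a", "a"], n_perm=9)


class TestNetwork:
    def test_identical_vectors_share_full_edge(self):
        base = [3, 1, 4, 1, 5, 9, 2, 6]
        ct = _ct([base, base, [10] * 8])
        g = build_network(ct, r_min=0.6, p_max=0.05)
        assert g.has_edge("t0", "t1")
        assert g.edges["t0", "t1"]["sign"] == 1
        assert g.edges["t0", "t1"]["rho"] == pytest.approx(1.0)

    def test_constant_relative_abundance_left_isolated(self):
        ct = _ct([[1, 2, 3, 4, 5, 8], [5, 5, 5, 5, 5, 5], [0, 0, 0, 0, 0, 0]])
        with pytest.warns(UserWarning, match="constant"):
            g = build_network(ct)
        assert g.degree("t2") == 0

    def test_anticorrelated_pair_negative_sign(self):
        up = list(range(1, 9))
        down = list(range(8, 0, -1))
        ct = _ct([up, down, up, down])
        g = build_network(ct)
        assert g.edges["t0", "t1"]["sign"] == -1
        assert g.edges["t0", "t1"]["rho"] == pytest.approx(-1.0)

    def test_null_taxa_mostly_unconnected_after_bh(self, rng):
        counts = rng.integers(1, 1000, size=(60, 18))
        g = build_network(_ct(counts))
        n_pairs = 60 * 59 / 2
        assert g.number_of_edges() <= 0.01 * n_pairs

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            build_network(_ct([[1, 2, 3, 4]]))


class TestModules:
    @staticmethod
    def _modularity(graph, partition):
        return nx.community.modularity(graph, partition)

    def test_two_cliques_recovered_matching_exhaustive_bipartition(self):
        g = nx.Graph()
        left, right = list(range(5)), list(range(5, 10))
        for grp in (left, right):
            g.add_edges_from(itertools.combinations(grp, 2))
        g.add_edge(0, 5)
        modules = detect_modules(g)
        found = {frozenset(n for n in g if modules[n] == m) for m in set(modules.values())}
        # exhaustive bipartition oracle
        best, best_q = None, -np.inf
        nodes = list(g.nodes)
        for mask in range(1, 2 ** (len(nodes) - 1)):
            part_a = {nodes[i] for i in range(len(nodes)) if (mask >> i) & 1}
            part_b = set(nodes) - part_a
            q = self._modularity(g, [part_a, part_b])
            if q > best_q:
                best, best_q = {frozenset(part_a), frozenset(part_b)}, q
        assert found == best == {frozenset(left), frozenset(right)}

    def test_edgeless_graph_all_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcd")
        modules = detect_modules(g)
        assert len(set(modules.values())) == 4

    def test_single_clique_one_module(self):
        g = nx.complete_graph(6)
        assert len(set(detect_modules(g).values())) == 1


class TestZiPi:
    def test_all_edges_inside_module_pi_zero(self):
        g = nx.complete_graph(4)
        out = zi_pi(g, {n: 0 for n in g})
        assert (out["pi"] == 0).all()

    def test_even_split_pi_half(self):
        g = nx.star_graph(4)  # hub 0 with 4 leaves
        modules = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1}
        out = zi_pi(g, modules)
        assert out.loc[0, "pi"] == pytest.approx(0.5)

    def test_degenerate_module_sd_gives_zero_zi(self):
        g = nx.cycle_graph(5)
        out = zi_pi(g, {n: 0 for n in g})
        assert (out["zi"] == 0).all()

    def test_keystone_rule_flips_exactly_at_thresholds(self):
        rule = KeystoneRule()
        eps = 1e-6
        assert not rule(2.5, 0.0) and rule(2.5 + eps, 0.0)
        assert not rule(0.0, 0.62) and rule(0.0, 0.62 + eps)
        and_rule = KeystoneRule(combine="and")
        assert not and_rule(3.0, 0.0) and and_rule(3.0, 0.63)

    def test_modules_must_cover_nodes(self):
        with pytest.raises(ValueError):
            zi_pi(nx.complete_graph(3), {0: 0})


class TestIndicatorComposite:
    def test_perfectly_correlated_taxa_single_component(self):
        base = np.array([1, 2, 3, 4, 5, 6], float)
        ct = _ct([base, 2 * base, [50] * 6])
        res = indicator_composite(ct.iloc[:2], totals=ct.sum(axis=0))
        assert res.explained_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_loadings_match_brute_force_eigendecomposition(self, rng):
        ct = _ct(rng.integers(1, 200, size=(4, 12)))
        res = indicator_composite(ct)
        rel = (ct / ct.sum(axis=0)).T
        z = (rel - rel.mean()) / rel.std(ddof=1)
        w, v = np.linalg.eigh(np.cov(z.T))
        order = np.argsort(w)[::-1]
        for k in range(2):
            vec = v[:, order[k]]
            if vec[np.argmax(np.abs(vec))] < 0:
                vec = -vec
            assert np.allclose(res.loadings.iloc[:, k], vec, atol=1e-8)

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            indicator_composite(_ct([[1, 2, 3]]))
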