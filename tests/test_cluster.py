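"""Linkage clustering, cophenetic correlation, and bootstrap support."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy.stats import norm

from songculture import (
    BootstrapUPGMA,
    SimilarityMatrix,
    bootstrap_support,
    cophenetic_correlation,
    linkage_cluster,
    select_linkage,
)
from songculture.cluster import DEFAULT_SCALES, _fit_au
from songculture.corpus import CorpusError


def naive_agglomerate(D, method):
    """Brute-force agglomerative oracle: returns [(clade, height), ...].

    Ties break to the lexicographically smallest pair of current cluster
    creation indices, matching the deterministic rule of the implementation.
    """
    n = len(D)
    active = {i: frozenset([i]) for i in range(n)}
    dist = {
        (i, j): float(D[i][j]) for i, j in itertools.combinations(range(n), 2)
    }
    merges = []
    nxt = n
    while len(active) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        ci, cj = active.pop(i), active.pop(j)
        merged = ci | cj
        for k in list(active):
            a, b = dist.pop((min(i, k), max(i, k))), dist.pop((min(j, k), max(j, k)))
            if method == "single":
                d = min(a, b)
            elif method == "average":
                d = (len(ci) * a + len(cj) * b) / (len(ci) + len(cj))
            elif method == "weighted_average":
                d = (a + b) / 2.0
            dist[(min(k, nxt), max(k, nxt))] = d
        del dist[(i, j)]
        active[nxt] = merged
        merges.append((merged, h))
        nxt += 1
    return merges


def random_similarity(n, rng):
    v = rng.uniform(0.05, 0.95, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix([f"s{i}" for i in range(n)], v)


class TestLinkage:
    def test_identical_pair_merges_first_at_zero(self):
        v = np.array([[1.0, 1.0, 0.4], [1.0, 1.0, 0.5], [0.4, 0.5, 1.0]])
        sim = SimilarityMatrix(["a", "b", "c"], v)
        dend = linkage_cluster(sim, "average")
        assert dend.clades()[0] == frozenset({"a", "b"})
        assert dend.heights()[0] == pytest.approx(0.0)

    def test_block_structure_gives_two_clades(self):
        v = np.full((4, 4), 0.1)
        v[0, 1] = v[1, 0] = v[2, 3] = v[3, 2] = 0.9
        np.fill_diagonal(v, 1.0)
        sim = SimilarityMatrix(list("abcd"), v)
        clades = linkage_cluster(sim, "average").clades()
        assert frozenset("ab") in clades and frozenset("cd") in clades

    @pytest.mark.parametrize("method", ["average", "single", "weighted_average"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, method, seed):
        rng = np.random.default_rng(seed)
        sim = random_similarity(7, rng)
        dend = linkage_cluster(sim, method)
        expected = naive_agglomerate(1.0 - sim.values, method)
        got = list(zip(dend.clades(), dend.heights()))
        for (cl_exp, h_exp), (cl_got, h_got) in zip(expected, got):
            assert {sim.labels[i] for i in cl_exp} == cl_got
            assert h_got == pytest.approx(h_exp)

    def test_chaining_separates_single_from_average(self):
        # a—b—c—d chain: single linkage absorbs c into {a,b} through the
        # short b—c link; average linkage pairs {c,d} instead.  Expected
        # merge orders worked out by hand agglomeration:
        #   single : ab@0.30, abc@0.32 (min(0.60, 0.32) < 0.34)
        #   average: ab@0.30, cd@0.34 ((0.60 + 0.32)/2 = 0.46 > 0.34)
        v = 1.0 - np.array(
            [
                [0.0, 0.30, 0.60, 0.90],
                [0.30, 0.0, 0.32, 0.60],
                [0.60, 0.32, 0.0, 0.34],
                [0.90, 0.60, 0.34, 0.0],
            ]
        )
        sim = SimilarityMatrix(list("abcd"), v)
        single = set(linkage_cluster(sim, "single").clades(include_root=False))
        average = set(linkage_cluster(sim, "average").clades(include_root=False))
        exp_single = {frozenset(("a", "b")), frozenset(("a", "b", "c"))}
        exp_average = {frozenset(("a", "b")), frozenset(("c", "d"))}
        assert single == exp_single
        assert average == exp_average
        assert single != average

    def test_average_heights_monotone_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            dend = linkage_cluster(random_similarity(8, rng), "average")
            assert np.all(np.diff(dend.heights()) >= -1e-12)

    def test_invalid_similarity_rejected(self):
        with pytest.raises(CorpusError):
            SimilarityMatrix(["a", "b"], np.array([[1.0, 0.2], [0.4, 1.0]]))

    def test_weighted_equals_unweighted_on_balanced_blocks(self):
        # two equal-size, internally uniform blocks: UPGMA and WPGMA agree
        v = np.full((4, 4), 0.2)
        for i, j in [(0, 1), (2, 3)]:
            v[i, j] = v[j, i] = 0.8
        np.fill_diagonal(v, 1.0)
        sim = SimilarityMatrix(list("abcd"), v)
        zu = linkage_cluster(sim, "average").linkage
        zw = linkage_cluster(sim, "weighted_average").linkage
        assert np.allclose(zu, zw)


class TestCophenetic:
    def test_ultrametric_input_gives_one(self):
        # two blocks at within-distance 0.2, across 0.6: exactly ultrametric
        d = np.full((4, 4), 0.6)
        for i, j in [(0, 1), (2, 3)]:
            d[i, j] = d[j, i] = 0.2
        np.fill_diagonal(d, 0.0)
        sim = SimilarityMatrix(list("abcd"), 1.0 - d + np.eye(4) * 0.0)
        dend = linkage_cluster(sim, "average")
        assert cophenetic_correlation(dend, sim) == pytest.approx(1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        sim = random_similarity(8, rng)
        ccc = cophenetic_correlation(linkage_cluster(sim, "average"), sim)
        perm = rng.permutation(8)
        sim_p = SimilarityMatrix(
            [sim.labels[i] for i in perm], sim.values[np.ix_(perm, perm)]
        )
        ccc_p = cophenetic_correlation(linkage_cluster(sim_p, "average"), sim_p)
        assert ccc_p == pytest.approx(ccc)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        sim = random_similarity(4, rng)
        dend = linkage_cluster(sim, "average")
        other = SimilarityMatrix(["x", "y", "z", "w"], sim.values)
        with pytest.raises(ValueError):
            cophenetic_correlation(dend, other)

    def test_select_linkage_reports_all_methods(self):
        sim = random_similarity(6, np.random.default_rng(7))
        res = select_linkage(sim)
        assert set(res["ccc"]) == {"average", "single", "weighted_average"}
        assert res["best"] in res["ccc"]


class TestAUFit:
    def test_recovers_closed_form_model(self):
        # profiles generated from BP(r) = Phi(−(v·sqrt(r) + c/sqrt(r)))
        scales = np.array(DEFAULT_SCALES)
        B = 100000
        for v, c in [(0.5, 0.3), (-1.0, 0.4), (1.2, 0.8), (-2.0, 0.15)]:
            bp = norm.cdf(-(v * np.sqrt(scales) + c / np.sqrt(scales)))
            counts = np.round(bp * B).astype(int)
            au, vf, cf, flag = _fit_au(scales, counts, B)
            assert flag == ""
            assert vf == pytest.approx(v, abs=0.02)
            assert cf == pytest.approx(c, abs=0.02)
            assert au == pytest.approx(norm.cdf(c - v), abs=0.005)

    def test_extreme_profiles(self):
        scales = np.array(DEFAULT_SCALES)
        B = 1000
        assert _fit_au(scales, np.full(len(scales), B), B)[:1] == (1.0,)
        assert _fit_au(scales, np.zeros(len(scales), dtype=int), B)[0] == 0.0

    def test_single_scale_degrades_to_bp(self):
        au, v, c, flag = _fit_au(np.array([1.0]), np.array([700]), 1000)
        assert flag == "degenerate"
        assert au == pytest.approx(0.7)


def two_block_groups(noise_rng=None):
    """Six groups in two blocks with disjoint symbol inventories."""
    g = {}
    for i in range(3):
        g[f"p{i}"] = [(1, 2, 3, 4, 5)] * 5
        g[f"q{i}"] = [(6, 7, 8, 9)] * 5
    return g


class TestBootstrapSupport:
    def test_identical_strings_give_bp_one_everywhere(self):
        dend, supports = bootstrap_support(
            two_block_groups(), B=50, seed=0, scales=[0.8, 1.0, 1.25]
        )
        for s in supports:
            assert s.flag == "all_present"
            assert s.bp == 1.0 and s.au == 1.0
            assert all(p == 1.0 for p in s.bp_profile.values())

    def test_expected_clades_present(self):
        dend, supports = bootstrap_support(two_block_groups(), B=20, seed=0)
        clades = {s.clade for s in supports}
        assert frozenset({"p0", "p1", "p2"}) in clades
        assert frozenset({"q0", "q1", "q2"}) in clades

    def test_deterministic_given_seed(self, default_corpus):
        groups = default_corpus.song_groups()
        kw = dict(B=25, seed=42, scales=[0.9, 1.0, 1.1])
        _, s1 = bootstrap_support(groups, **kw)
        _, s2 = bootstrap_support(groups, **kw)
        assert [(x.clade, x.bp, x.au, x.bp_profile) for x in s1] == [
            (x.clade, x.bp, x.au, x.bp_profile) for x in s2
        ]

    def test_single_scale_au_equals_bp(self, default_corpus):
        groups = default_corpus.song_groups()
        _, supports = bootstrap_support(groups, B=100, seed=3, scales=[1.0])
        for s in supports:
            assert s.au == pytest.approx(s.bp)
            assert s.flag in ("degenerate", "all_present", "absent")

    def test_small_group_scale_skipped_with_warning(self, caplog):
        groups = two_block_groups()
        groups["tiny"] = [(10, 11, 12)]
        with caplog.at_level("WARNING", logger="songculture.cluster"):
            _, supports = bootstrap_support(
                groups, B=10, seed=0, scales=[0.3, 1.0]
            )
        assert any("skipped" in r.message for r in caplog.records)
        for s in supports:
            assert set(s.bp_profile) == {1.0}

    def test_scales_must_include_one(self):
        with pytest.raises(ValueError, match="1.0"):
            bootstrap_support(two_block_groups(), B=10, seed=0, scales=[0.9, 1.1])


class TestBootstrapUPGMAEstimator:
    def test_fit_attributes_and_newick(self, default_corpus):
        model = BootstrapUPGMA(n_boot=25, scales=[0.9, 1.0, 1.1], random_state=0)
        model.fit(default_corpus.song_groups())
        assert len(model.group_labels_) == 6
        assert model.dendrogram_.n_leaves == 6
        assert -1.0 <= model.ccc_ <= 1.0
        assert len(model.supports_) == 5  # n − 1 internal nodes
        tree = dendropy.Tree.get(data=model.to_newick("au"), schema="newick")
        leaves = {t.label.replace(" ", "_") for t in tree.taxon_namespace}
        assert leaves == set(model.group_labels_)

    def test_accepts_song_string_list(self, default_corpus):
        # SongStrings group per location/year/recording (18 recordings)
        model = BootstrapUPGMA(n_boot=10, scales=[1.0], random_state=0)
        model.fit(default_corpus.songs)
        assert len(model.group_labels_) == 18
        assert "west_2015_X" in model.group_labels_

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        model = BootstrapUPGMA(n_boot=7, random_state=1)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()
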