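"""Contingency statistics, enrichment, category tables and UPGMA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import evilit
from evilit.assoc_stats import (
    ContingencyTable2x2,
    DegenerateTableWarning,
    SmallCountWarning,
    upgma,
)
from evilit.synthetic_corpus import CorpusSpec


def fisher_greater_oracle(a, b, c, d):
    """Brute-force hypergeometric tail enumeration, P(X >= a)."""
    N = a + b + c + d
    r1, c1 = a + b, a + c
    if N == 0:
        return 1.0
    denom = math.comb(N, c1)
    hi = min(r1, c1)
    return sum(math.comb(r1, k) * math.comb(N - r1, c1 - k)
               for k in range(a, hi + 1)) / denom


def hand_index(n_a, n_b, overlap, N):
    """An index with two genera of prescribed margins over N articles."""
    arts = {str(i): evilit.Article(pmid=str(i)) for i in range(N)}
    pa = {str(i) for i in range(n_a)}
    pb = {str(i) for i in range(n_a - overlap, n_a - overlap + n_b)}
    idx = evilit.BackendIndex(
        articles=arts,
        genus_pmids={"Aaa": pa, "Bbb": pb},
        known_genera={"Aaa", "Bbb"},
    )
    return idx


class TestMakeContingency:
    def test_cell_arithmetic(self):
        idx = hand_index(30, 20, 10, 100)
        t = evilit.make_contingency(idx, "Aaa", "Bbb")
        assert (t.a, t.b, t.c, t.d) == (10, 20, 10, 60)

    def test_empty_index(self, genus_lex, disease_lex):
        idx = evilit.build_index([], genus_lex, disease_lex)
        t = evilit.make_contingency(idx, "Escherichia", "Lactobacillus")
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0)

    def test_margins_reproduce_occurrence_counts(self, random_index_factory):
        index, _, spec = random_index_factory(9, n_articles=50)
        g1, g2 = spec.genus_vocab[:2]
        t = evilit.make_contingency(index, g1, g2)
        assert t.a + t.b == evilit.count_occurrence(index, g1)
        assert t.a + t.c == evilit.count_occurrence(index, g2)
        assert t.N == index.N

    def test_undersized_universe_rejected(self):
        idx = hand_index(30, 20, 10, 100)
        with pytest.raises(ValueError, match="universe"):
            evilit.make_contingency(idx, "Aaa", "Bbb", universe={"0", "1"})

    def test_same_entity_rejected(self):
        idx = hand_index(30, 20, 10, 100)
        with pytest.raises(ValueError):
            evilit.make_contingency(idx, "Aaa", "Aaa")


class TestFisher:
    def test_symmetric_table_two_sided_is_one(self):
        p, _ = evilit.fisher_exact_test(ContingencyTable2x2(1, 1, 1, 1),
                                        "two_sided")
        assert p == pytest.approx(1.0)

    def test_hand_enumerated_tail(self):
        p, _ = evilit.fisher_exact_test(ContingencyTable2x2(3, 1, 1, 3))
        assert p == pytest.approx(17 / 70)

    def test_empty_table_p_one_with_warning(self):
        with pytest.warns(DegenerateTableWarning):
            p, odds = evilit.fisher_exact_test(ContingencyTable2x2(0, 0, 0, 0))
        assert p == 1.0 and math.isnan(odds)

    def test_infinite_odds_when_bc_zero(self):
        _, odds = evilit.fisher_exact_test(ContingencyTable2x2(5, 0, 0, 5))
        assert odds == math.inf

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_tail_identity(self, cells):
        """greater-p + less-p - point-prob = 1 on every table."""
        a, b, c, d = cells
        t = ContingencyTable2x2(a, b, c, d)
        if t.N == 0:
            return
        p_greater, _ = evilit.fisher_exact_test(t)
        _, p_less = sps.fisher_exact(t.as_array(), alternative="less")
        point = sps.hypergeom.pmf(a, t.N, a + b, a + c)
        assert p_greater + p_less - point == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 8)] * 4))
    def test_greater_matches_enumeration(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        p, _ = evilit.fisher_exact_test(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(fisher_greater_oracle(a, b, c, d), abs=1e-10)


class TestChi2:
    def test_hand_computed_statistic(self):
        stat, _ = evilit.chi2_test(ContingencyTable2x2(10, 20, 30, 40))
        assert stat == pytest.approx(0.793651, abs=1e-6)

    def test_identical_row_proportions_zero(self):
        stat, p = evilit.chi2_test(ContingencyTable2x2(10, 20, 20, 40))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_transposition_invariance(self):
        s1, _ = evilit.chi2_test(ContingencyTable2x2(7, 13, 21, 9))
        s2, _ = evilit.chi2_test(ContingencyTable2x2(7, 21, 13, 9))
        assert s1 == pytest.approx(s2)

    def test_zero_margin_flagged_nan(self):
        with pytest.warns(DegenerateTableWarning):
            stat, p = evilit.chi2_test(ContingencyTable2x2(0, 0, 5, 5))
        assert math.isnan(stat) and math.isnan(p)

    def test_small_expected_warns(self):
        with pytest.warns(SmallCountWarning):
            evilit.chi2_test(ContingencyTable2x2(1, 2, 2, 1))

    def test_yates_reduces_statistic(self):
        plain, _ = evilit.chi2_test(ContingencyTable2x2(10, 20, 30, 15))
        corrected, _ = evilit.chi2_test(ContingencyTable2x2(10, 20, 30, 15),
                                        yates=True)
        assert corrected < plain


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [
        (0.01, 5, 0.05), (0.4, 10, 1.0), (0.2, 1, 0.2),
    ])
    def test_values(self, p, m, expected):
        assert evilit.bonferroni_adjust(p, m) == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            evilit.bonferroni_adjust(1.5, 3)


class TestDiseaseGenusSignificance:
    def test_absent_disease_empty(self, tiny_index):
        assert evilit.disease_genus_significance(tiny_index, "asthma") == []

    def test_planted_association_detected_decoys_spared(self, genus_lex,
                                                        disease_lex):
        detected, decoy_flags, decoy_total = 0, 0, 0
        for rep in range(20):
            spec = CorpusSpec(
                n_articles=500, seed=1000 + rep,
                genus_vocab=["Prevotella", "Escherichia", "Lactobacillus",
                             "Bacteroides", "Veillonella", "Dialister"],
                disease_vocab=["asthma"],
                baseline_overrides={"Prevotella": 0.1, "asthma": 0.1},
                planted_pairs=[("Prevotella", "asthma", 10.0)],
            )
            arts, _ = evilit.generate_corpus(spec)
            idx = evilit.build_index(arts, genus_lex, disease_lex)
            results = {r.entity_pair[0]: r
                       for r in evilit.disease_genus_significance(idx, "asthma")}
            if results["Prevotella"].significant:
                detected += 1
            for g, r in results.items():
                if g != "Prevotella":
                    decoy_total += 1
                    decoy_flags += r.significant
        assert detected >= 18  # planted OR=10 found in >=90% of replicates
        assert decoy_flags <= 0.10 * decoy_total

    def test_pvalues_match_enumeration_on_small_corpus(self, genus_lex,
                                                       disease_lex):
        spec = CorpusSpec(n_articles=25, seed=77,
                          genus_vocab=["Escherichia", "Lactobacillus"],
                          disease_vocab=["ulcer"],
                          genus_baseline=0.4, disease_baseline=0.4)
        arts, _ = evilit.generate_corpus(spec)
        idx = evilit.build_index(arts, genus_lex, disease_lex)
        for r in evilit.disease_genus_significance(idx, "ulcer"):
            g = r.entity_pair[0]
            t = evilit.make_contingency(idx, g, "ulcer")
            assert r.p_fisher == pytest.approx(
                fisher_greater_oracle(t.a, t.b, t.c, t.d), abs=1e-10)

    def test_sorted_by_count_then_name(self, random_index_factory):
        index, _, spec = random_index_factory(13, n_articles=60)
        res = evilit.disease_genus_significance(index, spec.disease_vocab[0])
        keys = [(-r.cooccurrence_count, r.entity_pair[0]) for r in res]
        assert keys == sorted(keys)


class TestDiseaseSets:
    def test_empty_index_all_sets_empty(self, genus_lex, disease_lex):
        idx = evilit.build_index([], genus_lex, disease_lex)
        sets = evilit.build_disease_sets(idx)
        assert len(sets) == 51
        assert all(s == set() for s in sets.values())

    def test_sets_within_lexicon(self, random_index_factory, genus_lex):
        index, _, _ = random_index_factory(21, n_articles=80)
        for s in evilit.build_disease_sets(index).values():
            assert s <= genus_lex.genera


class TestEnrich:
    def test_closed_form_worked_instance(self):
        out = evilit.enrich({"a", "b", "c"}, {"d1": {"a", "b", "c", "d", "e"}},
                            set("abcdefghij"))
        assert out == [("d1", 3, pytest.approx(10 / 120))]

    def test_set_equal_universe_p_one(self):
        uni = set("abcdef")
        out = evilit.enrich({"a", "b"}, {"d": uni}, uni)
        assert out[0][2] == pytest.approx(1.0)

    def test_zero_overlap_p_one(self):
        out = evilit.enrich({"a"}, {"d": {"x", "y"}}, {"a", "x", "y", "z"})
        assert out[0][2] == pytest.approx(1.0)

    def test_query_outside_universe_listed(self):
        with pytest.raises(ValueError, match="zzz"):
            evilit.enrich({"zzz"}, {"d": set()}, {"a"})


class TestCategoryTopGenera:
    def test_planted_gut_dominance(self, genus_lex, disease_lex):
        spec = CorpusSpec(
            n_articles=800, seed=5,
            genus_vocab=["Clostridium", "Escherichia", "Lactobacillus"],
            disease_vocab=["diarrhea", "colitis"],
            baseline_overrides={"Clostridium": 0.1, "diarrhea": 0.15},
            planted_pairs=[("Clostridium", "diarrhea", 12.0)],
        )
        arts, _ = evilit.generate_corpus(spec)
        idx = evilit.build_index(arts, genus_lex, disease_lex)
        table = evilit.category_top_genera(idx, disease_lex, k=10)
        gut = table["gut"]
        assert gut[0].genus == "Clostridium"
        assert gut[0].significant_bonferroni

    def test_k_larger_than_observed_no_padding(self, tiny_index, disease_lex):
        table = evilit.category_top_genera(tiny_index, disease_lex, k=10)
        assert len(table["systemic"]) == 1  # only Escherichia with ulcer
        assert table["brain"] == []


class TestUPGMA:
    def test_three_leaf_hand_computation(self):
        D = np.array([[0, 2, 6], [2, 0, 8], [6, 8, 0]], float)
        tree = upgma(["A", "B", "C"], D)
        assert tree.merges[0][:3] == (0, 1, 2.0)
        assert tree.merges[1][2] == pytest.approx(7.0)

    def test_identical_rows_merge_at_zero(self):
        D = np.array([[0, 0, 5], [0, 0, 5], [5, 5, 0]], float)
        tree = upgma(["x", "y", "z"], D)
        assert tree.merges[0][2] == 0.0

    def test_matches_bruteforce_oracle_random(self):
        """Merge partitions and heights equal a from-scratch average-linkage
        oracle on random matrices (ties included) up to 8 leaves."""
        rng = np.random.default_rng(0)
        for trial in range(60):
            n = int(rng.integers(2, 9))
            vals = rng.integers(1, 5, size=(n, n)).astype(float)  # many ties
            D = np.triu(vals, 1)
            D = D + D.T
            labels = [f"L{i}" for i in range(n)]
            tree = upgma(labels, D)
            oracle = bruteforce_upgma(labels, D)
            assert [
                (frozenset({frozenset(m[0]), frozenset(m[1])}),
                 pytest.approx(m[2]))
                for m in oracle
            ] == merges_as_partitions(tree, labels)

    def test_agrees_with_scipy_on_distinct_distances(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            D = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            D[iu] = rng.permutation(np.arange(1, len(iu[0]) + 1)).astype(float)
            D = D + D.T
            tree = upgma([f"L{i}" for i in range(n)], D)
            Z = linkage(squareform(D), method="average")
            assert [m[2] for m in tree.merges] == pytest.approx(list(Z[:, 2]))

    def test_newick_emitted(self):
        D = np.array([[0, 2, 6], [2, 0, 8], [6, 8, 0]], float)
        nwk = upgma(["A", "B", "C"], D).newick
        assert nwk.endswith(";") and "A" in nwk and "(" in nwk


def bruteforce_upgma(labels, D):
    """Independent oracle: recompute mean leaf-pair distance each step."""
    clusters = [frozenset([i]) for i in range(len(labels))]
    merges = []
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                cx, cy = clusters[x], clusters[y]
                d = np.mean([D[i, j] for i in cx for j in cy])
                kx = min(labels[i] for i in cx)
                ky = min(labels[i] for i in cy)
                key = (d, tuple(sorted((kx, ky))))
                if best is None or key < best[0]:
                    best = (key, x, y)
        (d, _), x, y = best
        cx, cy = clusters[x], clusters[y]
        merges.append(({labels[i] for i in cx}, {labels[i] for i in cy}, d))
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(cx | cy)
    return merges


def merges_as_partitions(tree, labels):
    n = len(labels)
    members = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for step, (i, j, h, _) in enumerate(tree.merges):
        a, b = members[i], members[j]
        out.append((frozenset({a, b}), h))
        members[n + step] = a | b
    return [(pair, pytest.approx(h)) for pair, h in out]


class TestDiseaseSimilarity:
    def test_row_normalization_and_zero_rows(self, genus_lex, disease_lex):
        spec = CorpusSpec(
            n_articles=400, seed=8,
            genus_vocab=["Escherichia", "Lactobacillus", "Clostridium",
                         "Bacteroides"],
            disease_vocab=["diarrhea", "colitis", "constipation"],
            genus_baseline=0.2, disease_baseline=0.2,
        )
        arts, _ = evilit.generate_corpus(spec)
        idx = evilit.build_index(arts, genus_lex, disease_lex)
        sim = evilit.disease_similarity(idx, disease_lex, "gut", top_m=4)
        for i, d in enumerate(sim.diseases):
            s = sim.matrix[i].sum()
            if d in sim.zero_rows:
                assert s == 0
            else:
                assert s == pytest.approx(1.0, abs=1e-12)
        assert (sim.matrix[sim.raw_counts == 0] == 0).all()
        assert sim.disease_tree is not None

    def test_too_few_diseases_errors(self, tiny_index, disease_lex):
        with pytest.raises(ValueError, match="fewer than 2"):
            evilit.disease_similarity(tiny_index, disease_lex, "gut")
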