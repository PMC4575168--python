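import itertools
import math

import numpy as np
import pytest

from loopscape.library_model import build_design
from loopscape.population_sim import Population, SimulatedClone
from loopscape.repertoire_core import (
    FrequencyMatrix,
    cluster_loops,
    design_frequency_matrix,
    frequency_delta,
    frequency_matrix,
    loop_items,
    pairwise_identity,
    remove_background,
    singleton_clusters,
    weighted_sitewise_counts,
    _batch_identity,
)

from conftest import toy_design_spec, toy_site


def make_pop(counts):
    # distinct dummy sequences with given counts
    clones = [
        SimulatedClone(dna="A" * (i + 1), read_count=c)
        for i, c in enumerate(counts)
    ]
    return Population(clones=clones)


class TestRemoveBackground:
    def test_cumulative_share_example(self):
        pop = make_pop([50, 30, 18, 1, 1])
        out = remove_background(pop, 0.02)
        assert sorted(c.read_count for c in out.clones) == [18, 30, 50]

    def test_fraction_zero_identity(self):
        pop = make_pop([5, 3, 2])
        out = remove_background(pop, 0.0)
        assert out is pop

    def test_tie_rule_keeps_equal_counts(self):
        pop = make_pop([10, 10, 10, 10])
        out = remove_background(pop, 0.02)
        assert len(out.clones) == 4

    def test_partial_tie_group_not_removed(self):
        # the tie group of three singletons (3% > 2%) must stay whole
        pop = make_pop([49, 30, 18, 1, 1, 1])
        out = remove_background(pop, 0.02)
        assert len(out.clones) == 6

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            remove_background(Population(clones=[]), 0.02)

    def test_bad_fraction_rejected(self):
        pop = make_pop([1])
        with pytest.raises(ValueError):
            remove_background(pop, 0.5)

    def test_unique_share_mode(self):
        pop = make_pop([100, 100, 1])
        out = remove_background(pop, 0.4, mode="unique_share")
        assert len(out.clones) == 2


# ---------------------------------------------------------------------------
# Identity oracle: exhaustive alignment enumeration for tiny strings
# ---------------------------------------------------------------------------

def enumerate_identity(a, b):
    """Brute force: recursively enumerate all global alignments, maximize
    (matches, aligned pairs) lexicographically."""
    best = {}

    def rec(i, j, matches, pairs):
        if i == len(a) and j == len(b):
            key = (matches, pairs)
            best[key] = True
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, matches + (a[i] == b[j]), pairs + 1)
        if i < len(a):
            rec(i + 1, j, matches, pairs)
        if j < len(b):
            rec(i, j + 1, matches, pairs)

    rec(0, 0, 0, 0)
    m, p = max(best)
    return m / (len(a) + len(b) - p) if (a or b) else 1.0


class TestPairwiseIdentity:
    def test_disjoint_sequences(self):
        assert pairwise_identity("SSSSS", "YYYYY") == 0.0

    def test_single_mismatch_ten_mer(self):
        assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKY") == pytest.approx(0.9)

    def test_triple_mismatch_ten_mer(self):
        assert pairwise_identity("ACDEFGHIKL", "ACDEFGWYKV") == pytest.approx(0.7)

    def test_identical(self):
        assert pairwise_identity("SYNT", "SYNT") == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        alphabet = "ASDY"
        for _ in range(150):
            la, lb = rng.integers(0, 6, size=2)
            a = "".join(rng.choice(list(alphabet), size=la))
            b = "".join(rng.choice(list(alphabet), size=lb))
            assert pairwise_identity(a, b) == pytest.approx(
                enumerate_identity(a, b)
            ), (a, b)

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(8)
        pairs = []
        for _ in range(200):
            la, lb = rng.integers(1, 13, size=2)
            pairs.append((
                "".join(rng.choice(list("ASDYGNT"), size=la)),
                "".join(rng.choice(list("ASDYGNT"), size=lb)),
            ))
        batch = _batch_identity(pairs)
        scalar = [pairwise_identity(a, b) for a, b in pairs]
        assert np.allclose(batch, scalar)


class TestClusterLoops:
    def test_identical_sequences_one_cluster(self):
        cs = cluster_loops([("SYNT", 3), ("SYNT", 2)], "DE")
        assert len(cs) == 1
        assert cs.clusters[0].total_count == 5

    def test_dissimilar_sequences_two_clusters(self):
        cs = cluster_loops([("SSSSS", 1), ("YYYYY", 1)], "DE", threshold=0.8)
        assert len(cs) == 2

    def test_point_nine_identity_joins(self):
        cs = cluster_loops(
            [("ACDEFGHIKL", 5), ("ACDEFGHIKY", 1)], "BC", threshold=0.8
        )
        assert len(cs) == 1

    def test_point_seven_identity_splits(self):
        cs = cluster_loops(
            [("ACDEFGHIKL", 5), ("ACDEFGWYKV", 1)], "BC", threshold=0.8
        )
        assert len(cs) == 2

    def test_visiting_order_descending_count(self):
        # highest-count sequence founds the first cluster
        cs = cluster_loops([("AAAA", 1), ("CCCC", 9)], "BC")
        assert cs.clusters[0].centroid == "CCCC"

    def test_deterministic_lexicographic_tiebreak(self):
        a = cluster_loops([("CCCC", 1), ("AAAA", 1)], "BC")
        b = cluster_loops([("AAAA", 1), ("CCCC", 1)], "BC")
        assert [c.centroid for c in a.clusters] == [c.centroid for c in b.clusters]

    def test_matches_brute_force_greedy(self):
        rng = np.random.default_rng(9)
        seqs = {}
        for _ in range(60):
            base = "".join(rng.choice(list("ASDY"), size=5))
            seqs[base] = int(rng.integers(1, 10))
        items = list(seqs.items())

        # independent brute-force greedy clustering
        order = sorted(seqs, key=lambda s: (-seqs[s], s))
        centroids, assign = [], {}
        for s in order:
            for ci, c in enumerate(centroids):
                if enumerate_identity(s, c) >= 0.8 - 1e-12:
                    assign[s] = ci
                    break
            else:
                assign[s] = len(centroids)
                centroids.append(s)

        cs = cluster_loops(items, "BC", threshold=0.8)
        assert [c.centroid for c in cs.clusters] == centroids
        for ci, cluster in enumerate(cs.clusters):
            for seq, _ in cluster.members:
                assert assign[seq] == ci

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            cluster_loops([("AA", 1)], "BC", threshold=0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_loops([], "BC")


class TestWeightedCounts:
    @pytest.fixture
    def synt_design(self):
        de = [{"weight": 1.0, "sites": [toy_site(l, "SYNT") for l in
                                        ["V15", "K16"]]}]
        return build_design(toy_design_spec(de_variants=de))

    def test_four_identical_reads_weight_two(self, synt_design):
        cs = cluster_loops([("SY", 4)], "DE")
        wc = weighted_sitewise_counts(cs, synt_design, exponent=0.5)
        assert wc["V15"]["S"] == pytest.approx(2.0)
        assert wc["K16"]["Y"] == pytest.approx(2.0)

    def test_exponent_one_plain_counting(self, synt_design):
        cs = cluster_loops([("SY", 4), ("SN", 3)], "DE")
        wc = weighted_sitewise_counts(cs, synt_design, exponent=1.0)
        assert wc["V15"]["S"] == pytest.approx(7.0)
        assert wc["K16"]["Y"] == pytest.approx(4.0)
        assert wc["K16"]["N"] == pytest.approx(3.0)

    def test_additivity_across_clusters(self, synt_design):
        cs = cluster_loops([("SSSSS" [:2], 4), ("YY", 4)], "DE", threshold=0.9)
        assert len(cs) == 2
        wc = weighted_sitewise_counts(cs, synt_design, exponent=0.5)
        assert wc["V15"]["S"] == pytest.approx(2.0)
        assert wc["V15"]["Y"] == pytest.approx(2.0)

    def test_scale_compression_doubling_law(self, synt_design):
        items = [("SY", 4), ("SN", 2), ("YT", 5)]
        cs1 = cluster_loops(items, "DE")
        cs2 = cluster_loops([(s, 2 * c) for s, c in items], "DE")
        w1 = weighted_sitewise_counts(cs1, synt_design, exponent=0.5)
        w2 = weighted_sitewise_counts(cs2, synt_design, exponent=0.5)
        for site in w1:
            for aa in w1[site]:
                assert w2[site][aa] == pytest.approx(
                    math.sqrt(2.0) * w1[site][aa]
                )

    def test_cluster_weight_mode_doubling_law(self, synt_design):
        items = [("SY", 4), ("SN", 2)]
        cs1 = cluster_loops(items, "DE")
        cs2 = cluster_loops([(s, 2 * c) for s, c in items], "DE")
        w1 = weighted_sitewise_counts(cs1, synt_design, mode="cluster_weight")
        w2 = weighted_sitewise_counts(cs2, synt_design, mode="cluster_weight")
        for site in w1:
            for aa in w1[site]:
                assert w2[site][aa] == pytest.approx(
                    math.sqrt(2.0) * w1[site][aa]
                )

    def test_unaligned_members_excluded_with_warning(self, synt_design):
        cs = cluster_loops([("SYNTSYNTSYNT", 1)], "DE")  # impossible length
        with pytest.warns(UserWarning, match="could not be aligned"):
            wc = weighted_sitewise_counts(cs, synt_design)
        assert wc == {}


class TestFrequencyMatrix:
    def test_simple_normalization(self):
        fm = frequency_matrix({"D23": {"S": 2.0, "Y": 2.0}})
        assert fm.freqs.loc["D23", "S"] == pytest.approx(0.5)
        assert fm.weight["D23"] == pytest.approx(4.0)

    def test_absent_site_zero_weight(self):
        fm = frequency_matrix({"D23": {"S": 1.0}}, sites=["D23", "K54"])
        assert fm.weight["K54"] == 0.0
        assert fm.freqs.loc["K54"].sum() == 0.0

    def test_rows_are_probability_vectors(self):
        rng = np.random.default_rng(10)
        counts = {
            f"S{i}": {aa: float(rng.integers(1, 50)) for aa in "ACDY"}
            for i in range(10)
        }
        fm = frequency_matrix(counts)
        assert np.allclose(fm.freqs.sum(axis=1), 1.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            frequency_matrix({"D23": {"S": -1.0, "Y": 2.0}})

    def test_tsv_roundtrip(self, tmp_path):
        fm = frequency_matrix({"D23": {"S": 2.0, "Y": 6.0}, "A24": {"G": 1.0}})
        p = tmp_path / "fm.tsv"
        fm.to_tsv(p)
        back = FrequencyMatrix.from_tsv(p)
        assert np.allclose(back.freqs.values, fm.freqs.values)
        assert np.allclose(back.weight.values, fm.weight.values)

    def test_full_pipeline_singletons_equals_plain_counting(self, gen1,
                                                            gen1_records_small):
        items = loop_items(gen1_records_small, "DE")
        cs = singleton_clusters(items, "DE")
        wc = weighted_sitewise_counts(cs, gen1, exponent=1.0)
        fm = frequency_matrix(wc)
        # brute-force counting oracle
        plain = {}
        from loopscape.seq_processing import align_loop

        for seq, count in items:
            sm = align_loop(seq, "DE", gen1)
            for site, aa in sm.items():
                plain.setdefault(site, {})
                plain[site][aa] = plain[site].get(aa, 0) + count
        for site, by_aa in plain.items():
            total = sum(by_aa.values())
            for aa, c in by_aa.items():
                assert fm.freqs.loc[site, aa] == pytest.approx(c / total)


class TestFrequencyDelta:
    def test_identical_matrices_zero(self):
        fm = frequency_matrix({"D23": {"S": 1.0, "Y": 3.0}})
        d = frequency_delta(fm, fm)
        assert np.allclose(d.values, 0.0)

    def test_hand_example(self):
        b = frequency_matrix({"D23": {"Y": 3.0, "S": 1.0}})
        n = frequency_matrix({"D23": {"Y": 2.0, "S": 2.0}})
        d = frequency_delta(b, n)
        assert d.loc["D23", "Y"] == pytest.approx(0.25)
        assert d.loc["D23", "S"] == pytest.approx(-0.25)
        assert d.loc["D23"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_sites_rejected(self):
        a = frequency_matrix({"D23": {"S": 1.0}})
        b = frequency_matrix({"A24": {"S": 1.0}})
        with pytest.raises(ValueError):
            frequency_delta(a, b)


def test_design_frequency_matrix_rows_sum_to_one(gen1):
    fm = design_frequency_matrix(gen1)
    assert np.allclose(fm.freqs.sum(axis=1), 1.0)
    assert set(fm.sites) == set(gen1.all_site_labels())
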