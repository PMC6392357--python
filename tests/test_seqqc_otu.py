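"""Sequence QC, p-distance, OTU clustering and taxonomy assignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcoweb.seqqc_otu import (
    DistanceMatrix,
    ReferenceHit,
    SequenceRecord,
    assign_taxonomy,
    cluster_otus,
    p_distance,
    pairwise_distance_matrix,
    qc_filter,
)
from _oracles import average_linkage_partition


def _seq(bases, marker="rbcLa"):
    return SequenceRecord("s", marker, bases)


class TestQCFilter:
    @pytest.mark.parametrize(
        "length,marker,expected,keep",
        [
            (432, "rbcLa", None, True),    # exactly 80% of 540
            (300, "rbcLa", None, False),
            (280, "ITS2", None, True),     # exactly 80% of 350
            (279, "ITS2", None, False),
            (526, "COI", 658, False),      # one below 80% of 658 (526.4)
            (527, "COI", 658, True),
        ],
    )
    def test_length_rule_inclusive_at_80pct(self, length, marker, expected, keep):
        assert qc_filter(_seq("A" * length, marker), expected) is keep

    def test_gaps_do_not_count_toward_length(self):
        seq = _seq("A" * 400 + "-" * 140, "rbcLa")
        assert qc_filter(seq) is False  # 400 ungapped < 432

    def test_unknown_marker_raises(self):
        with pytest.raises(ValueError, match="unknown marker"):
            qc_filter(SequenceRecord("s", "matK", "ACGT" * 200))


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("ACGT", "ACGA", 0.25),
            ("AC-T", "ACGT", 0.0),   # 3 comparable sites, 0 mismatches
            ("ANGT", "ACGA", 1 / 3),  # N excluded: 3 sites, 1 mismatch
        ],
    )
    def test_pairwise_deletion(self, a, b, expected):
        assert p_distance(a, b) == pytest.approx(expected)

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError, match="unequal"):
            p_distance("ACG", "ACGT")

    def test_no_comparable_sites_raise(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance("--NN", "ACGT")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=40).flatmap(
        lambda a: st.tuples(st.just(a),
                            st.text(alphabet="ACGT-N", min_size=len(a),
                                    max_size=len(a)))))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_range(self, pair):
        a, b = pair
        try:
            d = p_distance(a, b)
        except ValueError:
            return  # all sites missing
        assert d == p_distance(b, a)
        assert 0.0 <= d <= 1.0


class TestClusterOTUs:
    def _dm(self, ids, entries):
        n = len(ids)
        m = np.zeros((n, n))
        for (i, j), d in entries.items():
            m[i, j] = m[j, i] = d
        return DistanceMatrix(list(ids), m)

    def test_pair_below_threshold_merges(self):
        dm = self._dm("ab", {(0, 1): 0.01})
        assert len(set(cluster_otus(dm).values())) == 1

    def test_pair_above_threshold_splits(self):
        dm = self._dm("ab", {(0, 1): 0.03})
        assert len(set(cluster_otus(dm).values())) == 2

    def test_average_linkage_triple(self):
        # AB merge at 0.015; then d(AB, C) = (0.015 + 0.030)/2 = 0.0225 > 0.02
        dm = self._dm("ABC", {(0, 1): 0.015, (1, 2): 0.015, (0, 2): 0.030})
        otus = cluster_otus(dm, threshold=0.02)
        assert otus["A"] == otus["B"] != otus["C"]

    def test_empty_and_singleton(self):
        assert cluster_otus(DistanceMatrix([], np.zeros((0, 0)))) == {}
        single = DistanceMatrix(["x"], np.zeros((1, 1)))
        assert cluster_otus(single) == {"x": "OTU_0001"}

    def test_matches_bruteforce_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            d = rng.uniform(0, 0.06, size=(n, n))
            d = np.triu(d, 1)
            d = d + d.T
            ids = [f"q{i}" for i in range(n)]
            got = cluster_otus(DistanceMatrix(ids, d), threshold=0.02)
            clusters = {}
            for sid, otu in got.items():
                clusters.setdefault(otu, set()).add(sid)
            expected = average_linkage_partition(ids, d, 0.02)
            assert set(map(frozenset, clusters.values())) == expected

    def test_threshold_monotonicity(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 9))
            d = rng.uniform(0, 0.08, size=(n, n))
            d = np.triu(d, 1)
            d = d + d.T
            dm = DistanceMatrix([f"q{i}" for i in range(n)], d)
            counts = [len(set(cluster_otus(dm, threshold=t).values()))
                      for t in (0.005, 0.02, 0.04, 0.08)]
            assert counts == sorted(counts, reverse=True)


class TestPairwiseDistanceMatrix:
    def test_matches_scalar_p_distance(self, rng):
        seqs = []
        for i in range(6):
            bases = "".join(rng.choice(list("ACGT-N"), size=30))
            if set(bases) <= {"-", "N"}:
                bases = "ACGT" * 7 + "AC"
            seqs.append(SequenceRecord(f"s{i}", "COI", bases))
        dm = pairwise_distance_matrix(seqs)
        for i in range(6):
            for j in range(6):
                if i != j:
                    assert dm.matrix[i, j] == pytest.approx(
                        p_distance(seqs[i].bases, seqs[j].bases))


class TestAssignTaxonomy:
    def _hits(self):
        return [
            ReferenceHit("SpX", "Geometridae", "Lepidoptera", 0.99, 650),
            ReferenceHit("SpY", "Noctuidae", "Lepidoptera", 0.98, 650),
            ReferenceHit("SpZ", "Erebidae", "Lepidoptera", 0.97, 650),
        ]

    def test_consistent_morphology_takes_best_hit(self):
        a = assign_taxonomy("o1", self._hits(), morph_family="Geometridae")
        assert (a.label, a.status) == ("SpX", "accepted")

    def test_no_morphology_takes_best_hit(self):
        a = assign_taxonomy("o1", self._hits(), morph_family=None)
        assert (a.label, a.status) == ("SpX", "accepted")

    def test_conflict_resolved_by_top5_family_match(self):
        a = assign_taxonomy("o1", self._hits(), morph_family="Erebidae")
        assert (a.label, a.status) == ("SpZ", "accepted")

    def test_unresolvable_conflict_discards_at_family_level(self):
        a = assign_taxonomy("o1", self._hits(), morph_family="Sphingidae")
        assert a.status == "discarded_other_family_conflict"
        assert a.family == "Sphingidae"

    def test_other_order_discarded(self):
        hits = [ReferenceHit("Beetle1", "Carabidae", "Coleoptera", 0.99, 650)]
        a = assign_taxonomy("o1", hits)
        assert a.status == "discarded_other_order"

    def test_empty_hits_unidentified(self):
        assert assign_taxonomy("o1", []).status == "unidentified"


class TestOnSyntheticData:
    def test_otu_count_equals_planted_species_count(self, small_dataset):
        """In the well-separated regime each insect species is one OTU."""
        _, _, larvae, _, bundle = small_dataset
        records = [SequenceRecord(l.larva_id, "COI", bundle.larva_coi[l.larva_id])
                   for l in larvae]
        dm = pairwise_distance_matrix(records)
        otus = cluster_otus(dm)
        planted = {l.insect_species for l in larvae}
        assert len(set(otus.values())) == len(planted)
        # and clusters coincide with species membership
        by_otu = {}
        for l in larvae:
            by_otu.setdefault(otus[l.larva_id], set()).add(l.insect_species)
        assert all(len(s) == 1 for s in by_otu.values())
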