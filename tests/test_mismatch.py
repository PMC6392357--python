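"""Mismatch classification, summary percentages and accuracy counts."""

import math

import pytest

from barcoweb.dietid import DietCall, MarkerResult, _make_item
from barcoweb.mismatch import (
    CATEGORIES,
    ClassificationError,
    accuracy_by_level,
    classify_larva,
    summarize_mismatch,
)
from barcoweb.syndata import LarvaRecord


def _larva(larva_id="L1", host="A", x=10.0, y=10.0):
    return LarvaRecord(larva_id, "I1", None, "s_A", host, x, y, 8.0)


def _call(member_sets, reflib, larva_id="L1"):
    return DietCall(larva_id, [_make_item(frozenset(m), ("rbcLa",), reflib)
                               for m in member_sets])


class TestClassifyLarva:
    def test_diet_equals_host_is_match(self, toy_reflib, toy_stems):
        cat = classify_larva(_larva(), _call([{"A"}], toy_reflib),
                             toy_stems, toy_reflib)
        assert cat == "match"

    def test_nontree_diet(self, toy_reflib, toy_stems):
        cat = classify_larva(_larva(), _call([{"N"}], toy_reflib),
                             toy_stems, toy_reflib)
        assert cat == "nontree"

    def test_near_and_far_by_nearest_stem(self, toy_reflib, toy_stems):
        # B's nearest stem is 1.4 m from the fogged stem; C's is 3.7 m
        assert classify_larva(_larva(), _call([{"B"}], toy_reflib),
                              toy_stems, toy_reflib) == "near_neighbor"
        assert classify_larva(_larva(), _call([{"C"}], toy_reflib),
                              toy_stems, toy_reflib) == "far_neighbor"

    def test_radius_boundary_inclusive(self, toy_reflib):
        import pandas as pd
        from barcoweb.reflib import StemMap
        stems = StemMap(pd.DataFrame([
            {"stem_id": "s_A", "species_id": "A", "x_m": 10.0, "y_m": 10.0},
            {"stem_id": "s_B", "species_id": "B", "x_m": 12.0, "y_m": 10.0},
        ]), 100.0, 100.0)
        # B's stem sits exactly 2.0 m away: "within 2 m" is inclusive
        assert classify_larva(_larva(), _call([{"B"}], toy_reflib),
                              stems, toy_reflib) == "near_neighbor"

    def test_ambiguous_item_near_is_observation_bias(self, toy_reflib,
                                                     toy_stems):
        # complex {B, C} not containing the host: B within 2 m -> near
        larva = _larva(host="X")
        toy_reflib.taxa.loc[len(toy_reflib.taxa)] = [
            "X", "X", "G4", "F4", "tree", True]
        lib = type(toy_reflib)(toy_reflib.taxa, toy_reflib.sequences)
        assert classify_larva(larva, _call([{"B", "C"}], lib),
                              toy_stems, lib) == "near_neighbor"

    def test_ambiguous_item_far_is_molecular_bias(self, toy_reflib, toy_stems):
        larva = _larva(x=80.0, y=80.0)  # far from every stem
        cat = classify_larva(larva, _call([{"B", "C"}], toy_reflib),
                             toy_stems, toy_reflib)
        assert cat == "low_resolution"

    def test_match_level_respects_complex_membership(self, toy_reflib,
                                                     toy_stems):
        # complex containing the host counts as a match
        cat = classify_larva(_larva(host="A"), _call([{"A", "B"}], toy_reflib),
                             toy_stems, toy_reflib)
        assert cat == "match"

    def test_multi_item_takes_most_favorable(self, toy_reflib, toy_stems):
        call = _call([{"N"}, {"B"}], toy_reflib)
        assert classify_larva(_larva(), call, toy_stems, toy_reflib) == \
            "near_neighbor"
        call2 = _call([{"N"}, {"A"}], toy_reflib)
        assert classify_larva(_larva(), call2, toy_stems, toy_reflib) == "match"

    def test_unmapped_tree_species_raises(self, toy_reflib, toy_stems):
        lib = toy_reflib
        lib.taxa.loc[len(lib.taxa)] = ["Z", "Z", "G9", "F9", "tree", False]
        lib = type(lib)(lib.taxa, lib.sequences)
        with pytest.raises(ClassificationError):
            classify_larva(_larva(), _call([{"Z"}], lib), toy_stems, lib)

    def test_empty_call_rejected(self, toy_reflib, toy_stems):
        with pytest.raises(ValueError, match="empty"):
            classify_larva(_larva(), DietCall("L1", []), toy_stems, toy_reflib)


class TestSummarize:
    def test_counts_partition_classified_larvae(self):
        cats = (["match"] * 5 + ["near_neighbor"] * 2 + ["far_neighbor"] * 3
                + ["nontree"] + ["low_resolution"] * 4)
        s = summarize_mismatch(cats)
        assert sum(s.counts.values()) == s.n_classified == len(cats)
        assert s.n_mismatched == 10

    def test_contributions_over_mismatched_only(self):
        s = summarize_mismatch({"match": 10, "near_neighbor": 3,
                                "far_neighbor": 4, "nontree": 1,
                                "low_resolution": 2})
        assert s.observation_contribution_pct == 80.0
        assert s.molecular_contribution_pct == 20.0

    def test_all_match_gives_nan_contributions(self):
        s = summarize_mismatch({"match": 7})
        assert s.percentages["match"] == 100.0
        assert math.isnan(s.observation_contribution_pct)
        assert math.isnan(s.molecular_contribution_pct)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            summarize_mismatch(["match", "banana"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no classified"):
            summarize_mismatch([])


class TestAccuracyByLevel:
    def test_counts_monotone_family_to_species(self, toy_reflib):
        larvae = [_larva("L1", host="A"), _larva("L2", host="A"),
                  _larva("L3", host="C")]
        calls = [
            _call([{"A"}], toy_reflib, "L1"),          # species match
            _call([{"A", "B"}], toy_reflib, "L2"),     # genus-level complex
            _call([{"A"}], toy_reflib, "L3"),          # other family entirely
        ]
        out = accuracy_by_level(larvae, calls, toy_reflib)
        assert out.loc["combined", "family"] == 2
        assert out.loc["combined", "genus"] == 2
        assert out.loc["combined", "species"] == 1
        assert (out.loc["combined", "family"] >= out.loc["combined", "genus"]
                >= out.loc["combined", "species"])

    def test_per_marker_uses_marker_candidates_only(self, toy_reflib):
        larvae = [_larva("L1", host="A")]
        calls = [_call([{"A"}], toy_reflib, "L1")]
        marker_results = {
            "rbcLa": [MarkerResult("L1", "rbcLa", "sequence",
                                   frozenset({"C"}), 1.0)],
            "ITS2": [],
        }
        out = accuracy_by_level(larvae, calls, toy_reflib, marker_results)
        assert out.loc["rbcLa", "species"] == 0
        assert out.loc["rbcLa", "n_larvae"] == 1
        assert out.loc["ITS2", "n_larvae"] == 0

    def test_planted_truth_recovery_on_synthetic_data(self, small_dataset,
                                                      small_params):
        """Larvae whose hidden diet is the collection tree are exactly the
        larvae classified as 'match' (well-separated sequences, combined
        call containing the true diet)."""
        reflib, stems, larvae, truth, bundle = small_dataset
        from barcoweb.pipeline import PipelineConfig, _diet_stage
        config = PipelineConfig()
        _, calls = _diet_stage(config, reflib, larvae, bundle)
        calls_by_larva = {c.larva_id: c for c in calls}
        truth_by_larva = truth.set_index("larva_id")
        hits = misses = 0
        for l in larvae:
            call = calls_by_larva.get(l.larva_id)
            if call is None or not call.items:
                continue
            cat = classify_larva(l, call, stems, reflib)
            is_focal = truth_by_larva.at[l.larva_id, "true_class"] == "focal"
            if (cat == "match") == is_focal:
                hits += 1
            else:
                misses += 1
        assert hits > 0
        # complexes can turn a focal larva into an ambiguous-but-near match,
        # so allow a small leak but require overwhelming agreement
        assert misses <= 0.05 * (hits + misses)
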