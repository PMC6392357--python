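"""Synthetic community, larvae and sequence generation."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from barcoweb.reflib import nearest_neighbor_distances
from barcoweb.seqqc_otu import p_distance
from barcoweb.syndata import (
    CommunityParams,
    generate_community,
    generate_larvae,
    generate_sequences,
)


class TestParams:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CommunityParams(p_stay_on_host=0.5, p_near_drop=0.1,
                            p_far_disperse=0.1, p_nontree_diet=0.1)

    def test_probability_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            CommunityParams(p_stay_on_host=1.4, p_near_drop=-0.4,
                            p_far_disperse=0.0, p_nontree_diet=0.0)

    def test_sampled_cannot_exceed_tree_species(self):
        with pytest.raises(ValueError, match="n_sampled_species"):
            CommunityParams(n_tree_species=5, n_sampled_species=6)

    def test_nontree_diet_requires_nontree_taxa(self):
        with pytest.raises(ValueError, match="nontree"):
            CommunityParams(n_nontree_taxa=0, p_nontree_diet=0.1)

    def test_scalar_amplify_prob_broadcasts(self):
        p = CommunityParams(marker_amplify_prob=0.5)
        assert set(p.marker_amplify_prob.values()) == {0.5}


class TestGenerateCommunity:
    def test_seeded_determinism_byte_identical(self, small_params):
        lib1, stems1 = generate_community(small_params)
        lib2, stems2 = generate_community(small_params)
        pd.testing.assert_frame_equal(lib1.taxa, lib2.taxa)
        pd.testing.assert_frame_equal(stems1.stems, stems2.stems)
        assert stems1.stems.to_csv() == stems2.stems.to_csv()

    def test_nontree_taxa_flagged_unsampled(self, small_community):
        reflib, _ = small_community
        nt = reflib.taxa[reflib.taxa["growth_form"] == "nontree"]
        assert len(nt) == 4
        assert not nt["sampled"].any()

    def test_every_tree_species_has_a_stem(self, small_community):
        reflib, stems = small_community
        assert set(stems.species_ids()) == set(reflib.tree_ids)

    def test_poisson_nearest_neighbor_distance_closed_form(self):
        """Pooled stems form complete spatial randomness; the mean
        nearest-neighbor distance is 1/(2*sqrt(density))."""
        means, densities = [], []
        for seed in range(20):
            params = CommunityParams(n_tree_species=30, n_sampled_species=5,
                                     stems_per_species=20.0, rng_seed=seed)
            _, stems = generate_community(params)
            means.append(nearest_neighbor_distances(stems).mean())
            densities.append(len(stems.stems)
                             / (params.plot_width_m * params.plot_height_m))
        expected = np.mean([1.0 / (2.0 * math.sqrt(d)) for d in densities])
        assert np.mean(means) == pytest.approx(expected, rel=0.05)

    def test_thomas_process_clusters_more_than_poisson(self):
        base = dict(n_tree_species=20, n_sampled_species=5,
                    stems_per_species=40.0, rng_seed=3)
        _, s_pois = generate_community(CommunityParams(**base))
        _, s_thom = generate_community(
            CommunityParams(point_process="thomas", thomas_sigma_m=5.0, **base))
        assert (nearest_neighbor_distances(s_thom).mean()
                < nearest_neighbor_distances(s_pois).mean())


class TestGenerateLarvae:
    def test_all_stay_on_host(self, small_params, small_community):
        reflib, stems = small_community
        params = dataclasses.replace(small_params, p_stay_on_host=1.0,
                                     p_near_drop=0.0, p_far_disperse=0.0,
                                     p_nontree_diet=0.0)
        larvae, truth = generate_larvae(params, reflib, stems)
        by_id = {l.larva_id: l for l in larvae}
        assert all(truth.loc[i, "true_diet"] == by_id[truth.loc[i, "larva_id"]]
                   .collection_species for i in truth.index)

    def test_all_nontree(self, small_params, small_community):
        reflib, stems = small_community
        params = dataclasses.replace(small_params, p_stay_on_host=0.0,
                                     p_near_drop=0.0, p_far_disperse=0.0,
                                     p_nontree_diet=1.0)
        _, truth = generate_larvae(params, reflib, stems)
        assert set(truth["true_diet"]) <= set(reflib.nontree_ids)

    def test_no_nontree_taxa_means_no_nontree_diets(self, small_params):
        params = dataclasses.replace(
            small_params, n_nontree_taxa=0, p_nontree_diet=0.0,
            p_stay_on_host=0.7, p_near_drop=0.1, p_far_disperse=0.2)
        reflib, stems = generate_community(params)
        _, truth = generate_larvae(params, reflib, stems)
        assert (truth["true_class"] != "nontree").all()

    def test_class_frequencies_within_3_sigma(self, small_params):
        probs = {"focal": 0.25, "near": 0.11, "far": 0.52, "nontree": 0.12}
        params = dataclasses.replace(
            small_params, n_larvae=2000, p_stay_on_host=probs["focal"],
            p_near_drop=probs["near"], p_far_disperse=probs["far"],
            p_nontree_diet=probs["nontree"], rng_seed=5)
        reflib, stems = generate_community(params)
        _, truth = generate_larvae(params, reflib, stems)
        freq = truth["true_class"].value_counts(normalize=True)
        n = len(truth)
        for cls, p in probs.items():
            sigma = math.sqrt(p * (1 - p) / n)
            assert abs(freq.get(cls, 0.0) - p) < 3 * sigma, cls

    def test_location_class_consistent_with_distances(self, small_dataset,
                                                      small_params):
        reflib, stems, larvae, truth, _ = small_dataset
        by_id = {l.larva_id: l for l in larvae}
        radius = small_params.near_radius_m
        for row in truth.itertuples():
            larva = by_id[row.larva_id]
            if row.true_class in ("focal", "nontree"):
                continue
            d = stems.nearest_stem_distance(larva.x_m, larva.y_m, row.true_diet)
            if row.true_class == "near":
                assert d <= radius
            else:
                assert d > radius


class TestGenerateSequences:
    def test_determinism(self, small_params, small_community):
        reflib, stems = small_community
        larvae, truth = generate_larvae(small_params, reflib, stems)
        b1 = generate_sequences(reflib, larvae, truth, seed=9)
        b2 = generate_sequences(reflib, larvae, truth, seed=9)
        assert b1.larva_coi == b2.larva_coi
        assert b1.gut == b2.gut

    def test_zero_intraspecific_divergence_gives_identical_reads(
            self, small_params, small_community):
        reflib, stems = small_community
        larvae, truth = generate_larvae(small_params, reflib, stems)
        bundle = generate_sequences(reflib, larvae, truth,
                                    intraspecific_div=0.0, seed=2)
        for l in larvae:
            assert bundle.larva_coi[l.larva_id] == bundle.insect_ref[l.insect_species]

    def test_divergence_regime_separates_species(self, small_dataset):
        """Conspecific COI reads diverge < 2%; heterospecific >= 3%."""
        _, _, larvae, _, bundle = small_dataset
        by_species = {}
        for l in larvae[:80]:
            by_species.setdefault(l.insect_species, []).append(
                bundle.larva_coi[l.larva_id])
        flat = [(sp, s) for sp, seqs in by_species.items() for s in seqs[:3]]
        for i, (sp_a, a) in enumerate(flat):
            for sp_b, b in flat[i + 1:]:
                d = p_distance(a, b)
                if sp_a == sp_b:
                    assert d < 0.02
                else:
                    assert d >= 0.03

    def test_indistinguishable_pairs_share_cpdna_bytes(self, small_dataset):
        reflib = small_dataset[0]
        shared = reflib.taxa[reflib.taxa["shares_cpdna_with"] != ""]
        assert len(shared) > 0, "fixture community should plant a complex"
        for row in shared.itertuples():
            donor = row.shares_cpdna_with
            assert reflib.sequences["rbcLa"][row.taxon_id] == \
                reflib.sequences["rbcLa"][donor]
            assert reflib.sequences["trnL"][row.taxon_id] == \
                reflib.sequences["trnL"][donor]

    def test_invalid_divergence_rejected(self, small_dataset):
        reflib, _, larvae, truth, _ = small_dataset
        with pytest.raises(ValueError, match="divergence"):
            generate_sequences(reflib, larvae, truth, intraspecific_div=1.2)

    def test_lowquality_sequences_truncated(self, small_dataset):
        reflib, _, larvae, truth, bundle = small_dataset
        lowq = truth[(truth[["rbcLa", "trnL", "ITS2"]] == "lowquality").any(axis=1)]
        assert len(lowq) > 0
        row = lowq.iloc[0]
        for marker in ("rbcLa", "trnL", "ITS2"):
            if row[marker] == "lowquality":
                seq = bundle.gut[row["larva_id"]][marker]
                full = len(reflib.sequences[marker][row["true_diet"]])
                assert len(seq) < 0.8 * full
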