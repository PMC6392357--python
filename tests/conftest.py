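import numpy as np
import pandas as pd
import pytest

from barcoweb.reflib import ReferenceLibrary, StemMap
from barcoweb.syndata import (
    CommunityParams,
    generate_community,
    generate_larvae,
    generate_sequences,
)


@pytest.fixture(scope="session")
def small_params() -> CommunityParams:
    """A small community: fast, but with every mechanism switched on."""
    return CommunityParams(
        n_tree_species=12,
        n_sampled_species=8,
        n_nontree_taxa=4,
        plot_width_m=400.0,
        plot_height_m=250.0,
        stems_per_species=60.0,
        n_insect_species=12,
        n_larvae=200,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_community(small_params):
    return generate_community(small_params)


@pytest.fixture(scope="session")
def small_dataset(small_params, small_community):
    reflib, stems = small_community
    larvae, truth = generate_larvae(small_params, reflib, stems)
    bundle = generate_sequences(reflib, larvae, truth,
                                seed=small_params.rng_seed)
    return reflib, stems, larvae, truth, bundle


@pytest.fixture()
def toy_reflib() -> ReferenceLibrary:
    """Hand-built four-taxon library: two congeneric trees, one other tree,
    one nontree taxon; rbcLa shared between the congeners, ITS2 not."""
    taxa = pd.DataFrame([
        {"taxon_id": "A", "species": "A", "genus": "G1", "family": "F1",
         "growth_form": "tree", "sampled": True},
        {"taxon_id": "B", "species": "B", "genus": "G1", "family": "F1",
         "growth_form": "tree", "sampled": True},
        {"taxon_id": "C", "species": "C", "genus": "G2", "family": "F2",
         "growth_form": "tree", "sampled": False},
        {"taxon_id": "N", "species": "N", "genus": "G3", "family": "F3",
         "growth_form": "nontree", "sampled": False},
    ])
    lib = ReferenceLibrary(taxa)
    lib.sequences = {
        "rbcLa": {"A": "ACGTACGTAC", "B": "ACGTACGTAC",
                  "C": "TTTTACGTAC", "N": "GGGGACGTAC"},
        "trnL": {"A": "ACGTACGTAC", "B": "ACGTACGTAC",
                 "C": "TTTTACGTAC", "N": "GGGGACGTAC"},
        "ITS2": {"A": "AAAAACGTAC", "B": "CCCCACGTAC",
                 "C": "TTTTACGTAC", "N": "GGGGACGTAC"},
    }
    return lib


@pytest.fixture()
def toy_stems() -> StemMap:
    """Stems at known distances from the fogged stem of species A at (10, 10):
    B at 1.4 m, C at 3.7 m."""
    stems = pd.DataFrame([
        {"stem_id": "s_A", "species_id": "A", "x_m": 10.0, "y_m": 10.0},
        {"stem_id": "s_B", "species_id": "B", "x_m": 11.4, "y_m": 10.0},
        {"stem_id": "s_C", "species_id": "C", "x_m": 13.7, "y_m": 10.0},
    ])
    return StemMap(stems, 100.0, 100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
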