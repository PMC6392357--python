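"""Local plant reference library and mapped stem data.

The reference library stands in for a local plant DNA-barcode database:
every plant taxon known from the plot (trees and shrubs) plus the
"additional nontree taxa" (bamboos, lianas, bryophytes, parasitic plants)
that can show up in gut contents but are not part of the mapped tree
community.  Each taxon carries taxonomy (species, genus, family), a growth
form (``tree`` / ``nontree``) and a ``sampled`` flag marking the focal
species that were fogged, together with per-marker reference sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

PLANT_MARKERS = ("rbcLa", "trnL", "ITS2")


@dataclass
class ReferenceLibrary:
    """Plant taxa of the plot with per-marker barcode sequences.

    Parameters
    ----------
    taxa
        One row per taxon with columns ``taxon_id``, ``species``, ``genus``,
        ``family``, ``growth_form`` ("tree" or "nontree") and ``sampled``
        (bool; True for fogged focal species).
    sequences
        ``marker -> {taxon_id: bases}``.  May be empty until sequences are
        generated or loaded.
    """

    taxa: pd.DataFrame
    sequences: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"taxon_id", "species", "genus", "family", "growth_form", "sampled"}
        missing = required - set(self.taxa.columns)
        if missing:
            raise ValueError(f"reference library misses columns: {sorted(missing)}")
        if self.taxa["taxon_id"].duplicated().any():
            raise ValueError("duplicate taxon_id in reference library")
        self.taxa = self.taxa.reset_index(drop=True)
        self._by_id = self.taxa.set_index("taxon_id")

    # -- lookups -------------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.taxa["taxon_id"])

    @property
    def tree_ids(self) -> list[str]:
        return list(self.taxa.loc[self.taxa["growth_form"] == "tree", "taxon_id"])

    @property
    def nontree_ids(self) -> list[str]:
        return list(self.taxa.loc[self.taxa["growth_form"] == "nontree", "taxon_id"])

    @property
    def sampled_ids(self) -> list[str]:
        return list(self.taxa.loc[self.taxa["sampled"], "taxon_id"])

    def is_nontree(self, taxon_id: str) -> bool:
        return self._by_id.at[taxon_id, "growth_form"] == "nontree"

    def genus_of(self, taxon_id: str) -> str:
        return self._by_id.at[taxon_id, "genus"]

    def family_of(self, taxon_id: str) -> str:
        return self._by_id.at[taxon_id, "family"]

    def label_at_level(self, taxon_id: str, level: str) -> str:
        """Taxon label aggregated to ``species`` / ``genus`` / ``family``."""
        if level == "species":
            return taxon_id
        if level == "genus":
            return self.genus_of(taxon_id)
        if level == "family":
            return self.family_of(taxon_id)
        raise ValueError(f"unknown level: {level!r}")

    # -- I/O -----------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.taxa.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceLibrary":
        return cls(pd.read_csv(path))

    def write_fasta(self, marker: str, path: str | Path) -> None:
        seqs = self.sequences.get(marker, {})
        with open(path, "w") as fh:
            for taxon_id in self.taxon_ids:
                if taxon_id in seqs:
                    fh.write(f">{taxon_id} marker={marker}\n{seqs[taxon_id]}\n")


@dataclass
class StemMap:
    """Mapped stems of a plot: one record per stem with coordinates.

    Supports nearest-stem queries per species, the geometric primitive
    behind near/far neighbor attribution of diet mismatches.
    """

    stems: pd.DataFrame  # columns: stem_id, species_id, x_m, y_m
    plot_width_m: float
    plot_height_m: float

    def __post_init__(self) -> None:
        required = {"stem_id", "species_id", "x_m", "y_m"}
        missing = required - set(self.stems.columns)
        if missing:
            raise ValueError(f"stem map misses columns: {sorted(missing)}")
        self.stems = self.stems.reset_index(drop=True)
        xs, ys = self.stems["x_m"].to_numpy(), self.stems["y_m"].to_numpy()
        if (xs < 0).any() or (xs > self.plot_width_m).any() or (ys < 0).any() or (
            ys > self.plot_height_m
        ).any():
            raise ValueError("stem coordinates outside plot bounds")
        self._trees: dict[str, cKDTree] = {}
        self._coords = self.stems.set_index("stem_id")[["x_m", "y_m"]]

    def species_ids(self) -> list[str]:
        return sorted(self.stems["species_id"].unique())

    def coords_of(self, stem_id: str) -> tuple[float, float]:
        row = self._coords.loc[stem_id]
        return float(row["x_m"]), float(row["y_m"])

    def _tree_for(self, species_id: str) -> cKDTree | None:
        if species_id not in self._trees:
            pts = self.stems.loc[
                self.stems["species_id"] == species_id, ["x_m", "y_m"]
            ].to_numpy()
            if len(pts) == 0:
                return None
            self._trees[species_id] = cKDTree(pts)
        return self._trees[species_id]

    def nearest_stem_distance(self, x: float, y: float, species_id: str) -> float:
        """Euclidean distance (m) from (x, y) to the closest stem of a species.

        Raises ``KeyError`` when the species has no stem in the map.
        """
        tree = self._tree_for(species_id)
        if tree is None:
            raise KeyError(f"species {species_id!r} has no mapped stem")
        dist, _ = tree.query([x, y])
        return float(dist)

    def species_within(self, x: float, y: float, radius_m: float,
                       exclude: str | None = None) -> list[str]:
        """Species with at least one stem within ``radius_m`` of (x, y)."""
        tree = cKDTree(self.stems[["x_m", "y_m"]].to_numpy())
        idx = tree.query_ball_point([x, y], radius_m)
        species = set(self.stems.iloc[idx]["species_id"])
        species.discard(exclude)
        return sorted(species)

    def to_csv(self, path: str | Path) -> None:
        self.stems.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, plot_width_m: float,
                 plot_height_m: float) -> "StemMap":
        return cls(pd.read_csv(path), plot_width_m, plot_height_m)


def nearest_neighbor_distances(stems: StemMap) -> np.ndarray:
    """Distance from every stem to its nearest other stem (any species)."""
    pts = stems.stems[["x_m", "y_m"]].to_numpy()
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    return dist[:, 1]
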