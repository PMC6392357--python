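"""Bipartite web construction and node/link overlap between the two methods.

The observation web links each larva's insect species to the tree it was
fogged from; the molecular web links it to the plant taxa identified from
its gut contents.  Both are larva-level count matrices (insects x plants).
Overlap tables mirror the T+M+/T+M-/T-M+ bookkeeping: nodes or links
found by both methods, only by observation (traditional), or only by the
molecular method — at the plant-species or plant-genus level, with link
overlap computed both over all plant nodes and restricted to plant nodes
present in both webs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from barcoweb.reflib import ReferenceLibrary
from barcoweb._util import percentage

LEVELS = ("species", "genus")


@dataclass
class BipartiteWeb:
    """Insect x plant count matrix with node labels.

    ``complexes`` maps a plant column label to the set of member species
    when the column is a species complex (molecular webs only).
    """

    matrix: pd.DataFrame  # rows: insect labels, columns: plant labels, int counts
    level: str
    complexes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level: {self.level!r}")
        m = self.matrix
        if (m.to_numpy() < 0).any():
            raise ValueError("web counts must be non-negative")
        # drop all-zero rows/columns introduced by construction
        self.matrix = m.loc[m.sum(axis=1) > 0, m.sum(axis=0) > 0]

    @property
    def n_insects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_plants(self) -> int:
        return self.matrix.shape[1]

    def total(self) -> int:
        return int(self.matrix.to_numpy().sum())

    def plant_members(self, column: str) -> frozenset[str]:
        """Member species/genera represented by a plant column."""
        return self.complexes.get(column, frozenset([column]))

    def links(self) -> set[tuple[str, str]]:
        m = self.matrix
        return {(i, p) for i in m.index for p in m.columns if m.at[i, p] > 0}

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path, index_label="insect")

    @classmethod
    def from_csv(cls, path, level: str = "species") -> "BipartiteWeb":
        return cls(pd.read_csv(path, index_col=0), level)

    def to_edge_list(self) -> pd.DataFrame:
        rows = [
            {"insect": i, "plant": p, "count": int(self.matrix.at[i, p])}
            for i in self.matrix.index
            for p in self.matrix.columns
            if self.matrix.at[i, p] > 0
        ]
        return pd.DataFrame(rows, columns=["insect", "plant", "count"])


def _tally(cells: list[tuple[str, str]]) -> pd.DataFrame:
    counts: dict[tuple[str, str], int] = {}
    for key in cells:
        counts[key] = counts.get(key, 0) + 1
    insects = sorted({i for i, _ in counts})
    plants = sorted({p for _, p in counts})
    m = pd.DataFrame(0, index=insects, columns=plants, dtype=int)
    for (i, p), c in counts.items():
        m.at[i, p] = c
    return m


def build_observation_web(larvae, level: str = "species",
                          reflib: ReferenceLibrary | None = None) -> BipartiteWeb:
    """Web of larvae counts on the trees they were collected from.

    Larvae without an accepted insect label are skipped.  At genus level
    host species are aggregated to their genus (requires ``reflib``).
    """
    cells = []
    for larva in larvae:
        if getattr(larva, "insect_species", None) is None:
            continue
        plant = larva.collection_species
        if level == "genus":
            if reflib is None:
                raise ValueError("genus-level web needs a reference library")
            plant = reflib.genus_of(plant)
        cells.append((larva.insect_species, plant))
    return BipartiteWeb(_tally(cells), level)


def build_molecular_web(larvae, calls, level: str = "species",
                        reflib: ReferenceLibrary | None = None) -> BipartiteWeb:
    """Web of gut-content diet items: one count per diet item per larva.

    Species complexes become single columns labeled by their sorted
    members joined with '+'; at genus level a complex confined to one
    genus merges into that genus column.
    """
    calls_by_larva = {c.larva_id: c for c in calls}
    cells: list[tuple[str, str]] = []
    complexes: dict[str, frozenset[str]] = {}
    for larva in larvae:
        call = calls_by_larva.get(larva.larva_id)
        if call is None or not call.items:
            continue
        insect = larva.insect_species
        if insect is None:
            continue
        for item in call.items:
            if level == "genus":
                if reflib is None:
                    raise ValueError("genus-level web needs a reference library")
                members = frozenset(reflib.genus_of(m) for m in item.members)
            else:
                members = item.members
            label = next(iter(members)) if len(members) == 1 else "+".join(sorted(members))
            if len(members) > 1:
                complexes[label] = members
            cells.append((insect, label))
    return BipartiteWeb(_tally(cells), level, complexes)


# -- overlap ----------------------------------------------------------


def overlap_percentages(t_both: int, t_only: int, m_only: int) -> tuple[float, float, float, int]:
    """Percentages (1 dp, half-up) of common/traditional-only/molecular-only."""
    total = t_both + t_only + m_only
    return (percentage(t_both, total), percentage(t_only, total),
            percentage(m_only, total), total)


def _match_plant(obs_plant: str, mol_web: BipartiteWeb) -> str | None:
    """Molecular column matching an observation plant (complex membership counts)."""
    for col in mol_web.matrix.columns:
        if obs_plant in mol_web.plant_members(col):
            return col
    return None


def overlap_tables(obs: BipartiteWeb, mol: BipartiteWeb) -> pd.DataFrame:
    """Node and link overlap between observation and molecular webs.

    Three scopes: plant-node overlap; link overlap restricted to plant
    nodes present in both webs; link overlap over all nodes.  A molecular
    species complex matches an observation species when that species is
    one of its members.
    """
    if obs.level != mol.level:
        raise ValueError("webs must be at the same taxonomic level")

    obs_plants = list(obs.matrix.columns)
    match_of = {p: _match_plant(p, mol) for p in obs_plants}
    matched_cols = {c for c in match_of.values() if c is not None}
    node_both = sum(1 for c in match_of.values() if c is not None)
    node_t_only = sum(1 for c in match_of.values() if c is None)
    node_m_only = mol.n_plants - len(matched_cols)

    obs_links = obs.links()
    mol_links = mol.links()
    # translate molecular links into observation-plant terms where possible
    mol_links_translated = set()
    for insect, col in mol_links:
        members = mol.plant_members(col)
        hits = [p for p in obs_plants if p in members]
        if hits:
            for p in hits:
                mol_links_translated.add((insect, p, col))
        else:
            mol_links_translated.add((insect, None, col))

    def link_counts(restrict_shared: bool) -> tuple[int, int, int]:
        if restrict_shared:
            obs_keep = {(i, p) for i, p in obs_links if match_of[p] is not None}
            mol_keep = {(i, p, c) for i, p, c in mol_links_translated
                        if c in matched_cols}
        else:
            obs_keep, mol_keep = set(obs_links), set(mol_links_translated)
        shared_obs = {(i, p) for i, p, _ in mol_keep if p is not None} & obs_keep
        both = len(shared_obs)
        t_only = len(obs_keep) - both
        shared_mol_cols = {(i, c) for i, p, c in mol_keep if (i, p) in shared_obs}
        m_only = len({(i, c) for i, _, c in mol_keep}) - len(shared_mol_cols)
        return both, t_only, m_only

    rows = []
    for scope, counts in (
        ("nodes", (node_both, node_t_only, node_m_only)),
        ("links_shared_nodes", link_counts(True)),
        ("links_all_nodes", link_counts(False)),
    ):
        pb, pt, pm, total = overlap_percentages(*counts)
        rows.append({
            "scope": scope, "level": obs.level,
            "t_plus_m_plus": counts[0], "t_plus_m_minus": counts[1],
            "t_minus_m_plus": counts[2], "total": total,
            "pct_t_plus_m_plus": pb, "pct_t_plus_m_minus": pt,
            "pct_t_minus_m_plus": pm,
        })
    return pd.DataFrame(rows)
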