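"""Per-larva agreement between fogged host and molecular diet, with spatial
attribution of mismatches.

A larva whose gut-content call contains its collection tree matches; a
mismatching larva is attributed either to the observation method's
sampling bias — it actually fed on a near (<= 2 m) or far (> 2 m)
neighboring tree, or on an unsampled nontree taxon (bamboos, lianas,
bryophytes, parasitic plants) — or to the molecular method's resolution
bias, when the diet could not be pinned to species and no candidate grows
within the 2 m drop zone of the fogging sheet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from barcoweb.dietid import DietCall, DietItem, MarkerResult
from barcoweb.reflib import ReferenceLibrary, StemMap
from barcoweb._util import percentage

#: Categories in order of decreasing favorability for multi-item larvae.
CATEGORIES = ("match", "near_neighbor", "far_neighbor", "nontree", "low_resolution")

OBSERVATION_BIAS = ("near_neighbor", "far_neighbor", "nontree")
MOLECULAR_BIAS = ("low_resolution",)


class ClassificationError(ValueError):
    """Diet species absent from the stem map and not a nontree taxon."""


def _classify_item(item: DietItem, collection_species: str, x: float, y: float,
                   stems: StemMap, reflib: ReferenceLibrary, radius_m: float,
                   level: str) -> str:
    members_at_level = {reflib.label_at_level(m, level) for m in item.members}
    if reflib.label_at_level(collection_species, level) in members_at_level:
        return "match"
    if item.nontree:
        return "nontree"
    tree_members = [m for m in item.members if not reflib.is_nontree(m)]
    missing = [m for m in tree_members if m not in set(stems.stems["species_id"])]
    if missing:
        raise ClassificationError(
            f"diet taxa {missing} absent from stem map and not nontree")
    if len(tree_members) > 1:
        # ambiguous at species level: observation bias if any candidate is a
        # near neighbor, else the molecular method could not resolve it
        near = any(stems.nearest_stem_distance(x, y, m) <= radius_m
                   for m in tree_members)
        return "near_neighbor" if near else "low_resolution"
    dist = stems.nearest_stem_distance(x, y, tree_members[0])
    return "near_neighbor" if dist <= radius_m else "far_neighbor"


def classify_larva(larva, call: DietCall, stems: StemMap,
                   reflib: ReferenceLibrary, radius_m: float = 2.0,
                   level: str = "species") -> str:
    """Mismatch category of one larva with a non-empty diet call.

    Each diet item is classified on its own; a larva with several items
    takes the most favorable category in the order match > near_neighbor >
    far_neighbor > nontree > low_resolution.
    """
    if not call.items:
        raise ValueError(f"larva {call.larva_id!r} has an empty diet call")
    x, y = larva.x_m, larva.y_m
    cats = [
        _classify_item(item, larva.collection_species, x, y, stems, reflib,
                       radius_m, level)
        for item in call.items
    ]
    return min(cats, key=CATEGORIES.index)


@dataclass
class MismatchSummary:
    counts: dict[str, int]
    percentages: dict[str, float]
    observation_contribution_pct: float
    molecular_contribution_pct: float
    n_classified: int
    n_mismatched: int

    def to_frame(self) -> pd.DataFrame:
        rows = {c: {"count": self.counts[c], "pct": self.percentages[c]}
                for c in CATEGORIES}
        return pd.DataFrame.from_dict(rows, orient="index")


def summarize_mismatch(tallies) -> MismatchSummary:
    """Category percentages plus each method's contribution to mismatch.

    ``tallies`` is either a list of per-larva categories or a mapping
    ``{category: count}``.  Percentages are over all classified larvae;
    contributions are over mismatched larvae only (observation bias =
    near + far + nontree, molecular bias = low_resolution) and are NaN
    when nothing mismatched.
    """
    if isinstance(tallies, dict):
        counts = {c: int(tallies.get(c, 0)) for c in CATEGORIES}
        extra = set(tallies) - set(CATEGORIES)
    else:
        counts = {c: 0 for c in CATEGORIES}
        extra = set()
        for cat in tallies:
            if cat not in counts:
                extra.add(cat)
                continue
            counts[cat] += 1
    if extra:
        raise ValueError(f"unknown mismatch categories: {sorted(extra)}")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no classified larvae")
    mismatched = total - counts["match"]
    obs_bias = sum(counts[c] for c in OBSERVATION_BIAS)
    mol_bias = sum(counts[c] for c in MOLECULAR_BIAS)
    return MismatchSummary(
        counts=counts,
        percentages={c: percentage(counts[c], total) for c in CATEGORIES},
        observation_contribution_pct=percentage(obs_bias, mismatched),
        molecular_contribution_pct=percentage(mol_bias, mismatched),
        n_classified=total,
        n_mismatched=mismatched,
    )


def accuracy_by_level(larvae, combined_calls: list[DietCall],
                      reflib: ReferenceLibrary,
                      marker_results: dict[str, list[MarkerResult]] | None = None,
                      ) -> pd.DataFrame:
    """Counts of larvae whose fogged host the molecular call confirms.

    Rows: 'combined' plus one per marker (from that marker's candidate
    sets alone, when given).  Columns: confirmations at family, genus and
    species level and the denominator of larvae with a usable call.
    Confirmation at a level requires the candidate set to name a single
    taxon at that level equal to the host's — a congeneric complex
    containing the host confirms the genus but not the species — so
    family counts are necessarily >= genus >= species.
    """
    by_larva = {l.larva_id: l for l in larvae}

    def confirmed(members: frozenset[str], host: str, level: str) -> bool:
        labels = {reflib.label_at_level(m, level) for m in members}
        return labels == {reflib.label_at_level(host, level)}

    rows = {}

    def tally(name: str, member_sets: dict[str, list[frozenset[str]]]) -> None:
        out = {"n_larvae": len(member_sets)}
        for level in ("family", "genus", "species"):
            out[level] = sum(
                1 for larva_id, sets in member_sets.items()
                if any(confirmed(s, by_larva[larva_id].collection_species, level)
                       for s in sets)
            )
        rows[name] = out

    combined_sets = {
        c.larva_id: [it.members for it in c.items]
        for c in combined_calls if c.items and c.larva_id in by_larva
    }
    tally("combined", combined_sets)
    for marker, results in (marker_results or {}).items():
        sets = {
            r.larva_id: [r.candidates]
            for r in results if r.outcome == "sequence" and r.larva_id in by_larva
        }
        tally(marker, sets)
    return pd.DataFrame.from_dict(rows, orient="index")


def write_mismatch_tsv(path, categories: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("larva_id\tcategory\n")
        for larva_id in sorted(categories):
            fh.write(f"{larva_id}\t{categories[larva_id]}\n")


def write_summary_tsv(path, summary: MismatchSummary) -> None:
    with open(path, "w") as fh:
        fh.write("category\tcount\tpct\n")
        for c in CATEGORIES:
            fh.write(f"{c}\t{summary.counts[c]}\t{summary.percentages[c]}\n")
        obs, mol = (summary.observation_contribution_pct,
                    summary.molecular_contribution_pct)
        fh.write(f"observation_contribution\t\t{'' if math.isnan(obs) else obs}\n")
        fh.write(f"molecular_contribution\t\t{'' if math.isnan(mol) else mol}\n")
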