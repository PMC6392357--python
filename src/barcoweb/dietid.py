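"""Diet identification from gut-content barcodes and resolution scoring.

Each QC-passed gut sequence is matched against the local plant reference
library; the candidate set for a marker is the set of reference taxa at
maximal identity (several congeners may share a marker sequence, which is
exactly how species complexes arise).  Candidate sets from different
markers are intersected when they overlap — a second marker can only
sharpen a call — while disjoint sets are kept as separate diet items,
read as a larva having eaten more than one plant.

Resolution scoring follows the local-database convention: a taxon scores
1 at a level when the markers distinguish it from every other taxon at
that level, 0 when ambiguous, and 0.5 at species level for nontree taxa
that lack local references but are distinguishable from all local plant
sequences.  Summary means are taken over diet individuals, not taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from barcoweb.reflib import PLANT_MARKERS, ReferenceLibrary
from barcoweb.seqqc_otu import SequenceRecord, identity_fraction
from barcoweb._util import round_half_up


@dataclass(frozen=True)
class MarkerResult:
    """Outcome of one marker for one larva."""

    larva_id: str
    marker: str
    outcome: str  # no_amplification | discarded_low_quality | sequence
    candidates: frozenset[str] = frozenset()
    identity: float = float("nan")

    def __post_init__(self) -> None:
        if (self.outcome == "sequence") != bool(self.candidates):
            raise ValueError("candidate set must be non-empty iff outcome is 'sequence'")


@dataclass(frozen=True)
class DietItem:
    """One food plant of a larva: a taxon or an indistinguishable complex."""

    members: frozenset[str]
    level: str          # species | genus | family | unresolved
    nontree: bool
    markers: tuple[str, ...]

    def label(self, reflib: ReferenceLibrary) -> str:
        if len(self.members) == 1:
            return next(iter(self.members))
        return "+".join(sorted(self.members))


@dataclass
class DietCall:
    larva_id: str
    items: list[DietItem] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.items)


def resolve_marker(seq: SequenceRecord, reflib: ReferenceLibrary,
                   min_identity: float = 0.95) -> MarkerResult:
    """Match one gut sequence against the reference library for its marker.

    The candidate set contains every reference taxon achieving the maximal
    identity fraction.  Below ``min_identity`` the marker is treated as
    unidentified (outcome ``discarded_low_quality``): the library offers no
    credible match.
    """
    refs = reflib.sequences.get(seq.marker)
    if not refs:
        raise ValueError(f"reference library has no sequences for marker {seq.marker!r}")
    larva = seq.source_larva or seq.id
    taxon_ids = list(refs)
    lengths = {len(refs[t]) for t in taxon_ids}
    if lengths == {len(seq.bases)}:
        idents = _identities_vectorized(seq.bases, [refs[t] for t in taxon_ids])
    else:
        idents = np.array([identity_fraction(seq.bases, refs[t])
                           for t in taxon_ids])
    best = float(idents.max())
    if best < min_identity:
        return MarkerResult(larva, seq.marker, "discarded_low_quality")
    candidates = [t for t, i in zip(taxon_ids, idents) if i >= best - 1e-12]
    return MarkerResult(larva, seq.marker, "sequence", frozenset(candidates), best)


def _identities_vectorized(query: str, refs: list[str]) -> "np.ndarray":
    """Identity fractions of one query against equal-length references."""
    q = np.frombuffer(query.upper().encode(), dtype=np.uint8)
    r = np.frombuffer("".join(s.upper() for s in refs).encode(),
                      dtype=np.uint8).reshape(len(refs), len(q))
    missing_q = (q == ord("N")) | (q == ord("-"))
    missing_r = (r == ord("N")) | (r == ord("-"))
    ok = ~missing_q[None, :] & ~missing_r
    compared = ok.sum(axis=1)
    if (compared == 0).any():
        raise ValueError("a reference pair has no comparable sites")
    matches = ((q[None, :] == r) & ok).sum(axis=1)
    return matches / compared


def _item_level(members: frozenset[str], reflib: ReferenceLibrary) -> str:
    if len(members) == 1:
        return "species"
    genera = {reflib.genus_of(m) for m in members}
    if len(genera) == 1:
        return "genus"
    families = {reflib.family_of(m) for m in members}
    if len(families) == 1:
        return "family"
    return "unresolved"


def _make_item(members: frozenset[str], markers: tuple[str, ...],
               reflib: ReferenceLibrary) -> DietItem:
    nontree = all(reflib.is_nontree(m) for m in members)
    return DietItem(members, _item_level(members, reflib), nontree, markers)


def combine_markers(results: list[MarkerResult], reflib: ReferenceLibrary) -> DietCall:
    """Merge per-marker candidate sets into diet items.

    Markers are processed in the fixed order rbcLa, trnL, ITS2; a marker
    whose candidate set intersects an existing item narrows that item to
    the intersection, otherwise it opens a new item (an additional food
    plant).  A larva with no usable marker gets an empty call and is
    excluded from the molecular web.
    """
    usable = [r for r in results if r.outcome == "sequence"]
    if not usable:
        larva = results[0].larva_id if results else ""
        return DietCall(larva)
    larva = usable[0].larva_id
    order = {m: i for i, m in enumerate(PLANT_MARKERS)}
    usable.sort(key=lambda r: order.get(r.marker, len(order)))
    items: list[tuple[set[str], list[str]]] = []
    for res in usable:
        cand = set(res.candidates)
        for members, markers in items:
            if members & cand:
                members &= cand
                markers.append(res.marker)
                break
        else:
            items.append((cand, [res.marker]))
    return DietCall(
        larva,
        [_make_item(frozenset(members), tuple(markers), reflib)
         for members, markers in items],
    )


def score_resolution(item: DietItem, reflib: ReferenceLibrary, level: str) -> float:
    """Resolution of one diet item at a taxonomic level: 1, 0.5 or 0.

    1 when the item names a single taxon at that level; 0 when ambiguous;
    0.5 at species level for nontree taxa without local references.
    """
    if level not in ("family", "genus", "species"):
        raise ValueError(f"unknown level: {level!r}")
    labels = {reflib.label_at_level(m, level) for m in item.members}
    if len(labels) > 1:
        return 0.0
    if level == "species" and item.nontree:
        return 0.5
    return 1.0


def resolution_summary(calls_by_marker: dict[str, list[DietCall]],
                       combined_calls: list[DietCall],
                       reflib: ReferenceLibrary) -> pd.DataFrame:
    """Mean diet-identification resolution per marker and for the combination.

    ``calls_by_marker`` holds, per marker, calls built from that marker
    alone (one call per larva that yielded the marker).  Means are taken
    over diet individuals: each diet item of each larva contributes once,
    so a plant eaten by ten larvae counts ten times.
    """
    rows = {}
    for name, calls in list(calls_by_marker.items()) + [("combined", combined_calls)]:
        items = [item for call in calls for item in call.items]
        n_seq = sum(1 for call in calls if call.items)
        if not items:
            rows[name] = {"family_pct": float("nan"), "genus_pct": float("nan"),
                          "species_pct": float("nan"), "n_sequences": 0}
            continue
        rows[name] = {
            f"{level}_pct": round_half_up(
                100.0 * sum(score_resolution(it, reflib, level) for it in items)
                / len(items), 1)
            for level in ("family", "genus", "species")
        }
        rows[name]["n_sequences"] = n_seq
    return pd.DataFrame.from_dict(rows, orient="index")


def read_diet_calls_tsv(path, reflib: ReferenceLibrary) -> list[DietCall]:
    """Read a diet_calls.tsv written by :func:`write_diet_calls_tsv`."""
    df = pd.read_csv(path, sep="\t")
    calls: dict[str, DietCall] = {}
    for row in df.itertuples(index=False):
        call = calls.setdefault(row.larva_id, DietCall(row.larva_id))
        members = frozenset(str(row.taxa).split("|"))
        call.items.append(_make_item(members, tuple(str(row.markers).split(",")),
                                     reflib))
    return list(calls.values())


def write_diet_calls_tsv(path, calls: list[DietCall], reflib: ReferenceLibrary) -> None:
    with open(path, "w") as fh:
        fh.write("larva_id\titem_index\ttaxa\tlevel\tnontree\tmarkers\n")
        for call in calls:
            for i, item in enumerate(call.items):
                fh.write(
                    f"{call.larva_id}\t{i}\t{'|'.join(sorted(item.members))}\t"
                    f"{item.level}\t{int(item.nontree)}\t{','.join(item.markers)}\n"
                )
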