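"""Sequence QC, pairwise distances, OTU delimitation and taxonomy assignment.

Insect COI sequences are quality-filtered (a sequence is kept when its
ungapped length is at least 80% of the marker's expected amplicon length),
pairwise uncorrected p-distances are computed with pairwise deletion of
gap/N positions, and OTUs are delimited by hierarchical clustering cut at
a divergence threshold (2% by default, the standard barcoding-gap cutoff
for Lepidoptera).  Each OTU is then given a taxonomic label by combining
ranked reference-library hits with an optional morphological family,
discarding OTUs that conflict at the family level or fall outside the
target insect order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

#: Expected amplicon lengths (bp).  The plant markers are fixed by their
#: primer systems; COI depends on the primer pair and is configurable.
MARKER_EXPECTED_LENGTH: dict[str, int] = {
    "COI": 658,
    "rbcLa": 540,
    "trnL": 500,
    "ITS2": 350,
}

IUPAC_LETTERS = set("ACGTRYSWKMBDHVN-")
#: Characters excluded from comparable sites under pairwise deletion.
_MISSING = set("N-")


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence tied to a marker and, optionally, a larva."""

    id: str
    marker: str
    bases: str
    source_larva: str | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.bases.upper()) - IUPAC_LETTERS
        if bad:
            raise ValueError(f"sequence {self.id!r} has non-IUPAC characters: {sorted(bad)}")


def qc_filter(seq: SequenceRecord, expected_length_bp: int | None = None) -> bool:
    """Keep a sequence iff its ungapped length is >= 80% of the expected length.

    ``expected_length_bp`` defaults to the marker's standard amplicon
    length.  The boundary is inclusive ("no less than 80%").
    """
    if expected_length_bp is None:
        try:
            expected_length_bp = MARKER_EXPECTED_LENGTH[seq.marker]
        except KeyError:
            raise ValueError(f"unknown marker: {seq.marker!r}") from None
    if expected_length_bp <= 0:
        raise ValueError("expected_length_bp must be positive")
    ungapped = sum(1 for b in seq.bases if b != "-")
    return ungapped >= 0.8 * expected_length_bp


def p_distance(a: str, b: str) -> float:
    """Uncorrected p-distance between two aligned sequences.

    Mismatches divided by compared sites, where positions with a gap or N
    in either sequence are excluded (pairwise deletion).  Sequences must
    be pre-aligned to equal length.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal sequence lengths ({len(a)} vs {len(b)})")
    a, b = a.upper(), b.upper()
    compared = mismatches = 0
    for x, y in zip(a, b):
        if x in _MISSING or y in _MISSING:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable sites (all positions gapped or N)")
    return mismatches / compared


def identity_fraction(a: str, b: str) -> float:
    """Matches / compared sites under pairwise deletion (1 - p_distance)."""
    return 1.0 - p_distance(a, b)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise divergence fractions with sequence ids."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if len(self.ids) and (
            not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0)
        ):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if len(self.ids) and ((m < 0).any() or (m > 1).any()):
            raise ValueError("divergence fractions must lie in [0, 1]")
        self.matrix = m

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for name, row in zip(self.ids, self.matrix):
                fh.write(name + "  " + "  ".join(f"{d:.6f}" for d in row) + "\n")


def pairwise_distance_matrix(seqs: Sequence[SequenceRecord]) -> DistanceMatrix:
    """All pairwise p-distances, vectorized over equal-length sequences."""
    ids = [s.id for s in seqs]
    n = len(seqs)
    if n == 0:
        return DistanceMatrix([], np.zeros((0, 0)))
    lengths = {len(s.bases) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    enc = np.frombuffer(
        "".join(s.bases.upper() for s in seqs).encode(), dtype=np.uint8
    ).reshape(n, lengths.pop())
    missing = (enc == ord("N")) | (enc == ord("-"))
    dm = np.zeros((n, n))
    for i in range(n):
        ok = ~missing[i] & ~missing[i + 1:]
        compared = ok.sum(axis=1)
        mism = ((enc[i] != enc[i + 1:]) & ok).sum(axis=1)
        if (compared == 0).any():
            raise ValueError("a sequence pair has no comparable sites")
        d = mism / compared
        dm[i, i + 1:] = d
        dm[i + 1:, i] = d
    return DistanceMatrix(ids, dm)


def cluster_otus(dm: DistanceMatrix, threshold: float = 0.02,
                 linkage_method: str = "average") -> dict[str, str]:
    """Delimit OTUs by hierarchical clustering cut at a divergence threshold.

    Sequences whose (average/single/complete) linkage distance is <= the
    threshold end up in one OTU.  OTU ids are ``OTU_0001`` etc., numbered
    by the lexicographically smallest member sequence id so the output is
    deterministic under input order.

    Returns ``{sequence id -> OTU id}``.
    """
    if linkage_method not in ("single", "complete", "average"):
        raise ValueError(f"unsupported linkage: {linkage_method!r}")
    if not dm.ids:
        return {}
    if len(dm.ids) == 1:
        return {dm.ids[0]: "OTU_0001"}
    Z = linkage(squareform(dm.matrix, checks=False), method=linkage_method)
    flat = fcluster(Z, t=threshold, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for sid, c in zip(dm.ids, flat):
        clusters.setdefault(int(c), []).append(sid)
    ordered = sorted(clusters.values(), key=lambda members: min(members))
    out: dict[str, str] = {}
    for k, members in enumerate(ordered, start=1):
        for sid in members:
            out[sid] = f"OTU_{k:04d}"
    return out


# -- taxonomy assignment ----------------------------------------------


@dataclass(frozen=True)
class ReferenceHit:
    """One ranked hit of an OTU's representative sequence in a reference."""

    label: str
    family: str
    order: str
    identity: float
    aln_length: int = 0


@dataclass
class OTUAssignment:
    otu_id: str
    label: str | None
    family: str | None
    status: str  # accepted | discarded_other_family_conflict | discarded_other_order | unidentified


def rank_hits(hits: Iterable[ReferenceHit]) -> list[ReferenceHit]:
    """Order hits by identity (desc), then alignment length (desc), then label."""
    return sorted(hits, key=lambda h: (-h.identity, -h.aln_length, h.label))


def assign_taxonomy(otu_id: str, hits: Sequence[ReferenceHit],
                    morph_family: str | None = None,
                    target_order: str = "Lepidoptera") -> OTUAssignment:
    """Assign a taxonomic label to an OTU from ranked hits plus morphology.

    Rules: a best hit outside the target order discards the OTU.  If the
    morphological family agrees with the best hit's family (or no
    morphology is available), the best hit's species label is used;
    otherwise the highest-ranked of the top-5 hits matching the
    morphological family wins; if none does, the OTU is discarded as a
    family-level conflict (its morphological family retained as a
    family-level label for the record).
    """
    if not hits:
        return OTUAssignment(otu_id, None, None, "unidentified")
    ranked = rank_hits(hits)
    best = ranked[0]
    if best.order != target_order:
        return OTUAssignment(otu_id, None, None, "discarded_other_order")
    if morph_family is None or best.family == morph_family:
        return OTUAssignment(otu_id, best.label, best.family, "accepted")
    for hit in ranked[:5]:
        if hit.family == morph_family:
            return OTUAssignment(otu_id, hit.label, hit.family, "accepted")
    return OTUAssignment(otu_id, morph_family, morph_family,
                         "discarded_other_family_conflict")


def search_reference(bases: str, reference: dict[str, tuple[str, str, str]]) -> list[ReferenceHit]:
    """Identity search of one sequence against ``{label: (bases, family, order)}``.

    A local stand-in for a database search: identity is computed over the
    full query with pairwise deletion, and hits are returned ranked.
    """
    hits = []
    for label, (ref_bases, family, order) in reference.items():
        ident = identity_fraction(bases, ref_bases)
        hits.append(ReferenceHit(label, family, order, ident, len(ref_bases)))
    return rank_hits(hits)


def write_otus_tsv(path, assignments: dict[str, str],
                   labels: dict[str, OTUAssignment]) -> None:
    """Write ``otus.tsv`` (seq_id, otu_id, label, family, status)."""
    with open(path, "w") as fh:
        fh.write("seq_id\totu_id\tlabel\tfamily\tstatus\n")
        for sid in sorted(assignments):
            otu = assignments[sid]
            a = labels[otu]
            fh.write(f"{sid}\t{otu}\t{a.label or ''}\t{a.family or ''}\t{a.status}\n")
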