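"""Synthetic forest communities, larvae and toy barcode sequences.

The generator emulates the sampling design the analysis assumes: a fully
mapped plot (default 1000 x 500 m, i.e. 50 ha) of tree species of which a
subset are fogged focal species (one fogged stem per species), plus
unsampled nontree taxa (bamboos, lianas, bryophytes, parasitic plants)
that occur only in gut contents.  Each larva belongs to a Lepidoptera
species, is collected on a fogged stem, and has a hidden true diet drawn
from a four-way location mechanism: it fed on the focal tree itself, on a
near neighbor (another tree species with a stem within 2 m — larvae drop
onto the fogging sheet), on a far neighbor (> 2 m — dispersal), or on a
nontree taxon.  Plant markers amplify independently per larva with
per-marker probabilities, and a fraction of amplified sequences are
truncated below the quality threshold.  Some congeneric plant species are
indistinguishable at the chloroplast markers (and some also at ITS2),
planting the species complexes that limit molecular resolution.

All randomness flows from ``rng_seed``; identical parameters give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json
import math

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from barcoweb.reflib import PLANT_MARKERS, ReferenceLibrary, StemMap

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Marker lengths used for generated sequences (bp).
SEQ_LENGTHS = {"COI": 658, "rbcLa": 540, "trnL": 500, "ITS2": 350}


@dataclass
class CommunityParams:
    """Knobs of the synthetic community; defaults mirror the sampling design.

    The four diet-location probabilities must sum to 1.  Marker
    amplification is an independent Bernoulli per marker per larva;
    ``p_lowquality`` is the chance an amplified sequence comes out
    truncated below the 80% length rule.  ``p_species_indistinguishable``
    is the chance a tree species with a congener shares its chloroplast
    sequences with that congener (half of those pairs also share ITS2,
    i.e. form a full species complex).
    """

    n_tree_species: int = 30
    n_sampled_species: int = 20
    n_nontree_taxa: int = 8
    plot_width_m: float = 1000.0
    plot_height_m: float = 500.0
    stems_per_species: float = 150.0
    n_insect_species: int = 40
    n_larvae: int = 800
    diet_breadth_distribution: tuple = ("geometric", 0.35)
    p_stay_on_host: float = 0.60
    p_near_drop: float = 0.10
    p_far_disperse: float = 0.20
    p_nontree_diet: float = 0.10
    marker_amplify_prob: dict = field(
        default_factory=lambda: {"rbcLa": 0.30, "trnL": 0.20, "ITS2": 0.10})
    p_lowquality: float = 0.10
    p_species_indistinguishable: float = 0.25
    p_morph_family_known: float = 0.5
    near_radius_m: float = 2.0
    point_process: str = "poisson"       # poisson | thomas
    thomas_sigma_m: float = 20.0
    thomas_mean_per_parent: float = 25.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.p_stay_on_host, self.p_near_drop, self.p_far_disperse,
                 self.p_nontree_diet]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("diet-location probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("diet-location probabilities must sum to 1")
        if not 0 <= self.n_sampled_species <= self.n_tree_species:
            raise ValueError("n_sampled_species must be <= n_tree_species")
        if self.n_nontree_taxa == 0 and self.p_nontree_diet > 0:
            raise ValueError("p_nontree_diet > 0 requires nontree taxa")
        if isinstance(self.marker_amplify_prob, (int, float)):
            self.marker_amplify_prob = {m: float(self.marker_amplify_prob)
                                        for m in PLANT_MARKERS}
        for m, p in self.marker_amplify_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"amplification probability for {m} outside [0, 1]")
        if self.point_process not in ("poisson", "thomas"):
            raise ValueError(f"unknown point process: {self.point_process!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CommunityParams":
        with open(path) as fh:
            data = json.load(fh)
        if "diet_breadth_distribution" in data:
            data["diet_breadth_distribution"] = tuple(data["diet_breadth_distribution"])
        return cls(**data)


@dataclass
class LarvaRecord:
    """One collected larva; hidden truths live in the GroundTruth table."""

    larva_id: str
    insect_species: str | None
    morph_family: str | None
    collection_stem: str
    collection_species: str
    x_m: float
    y_m: float
    body_size_mm: float


@dataclass
class SequenceBundle:
    """Generated sequences: plant references live on the ReferenceLibrary."""

    insect_ref: dict[str, str]                 # insect species -> COI reference
    larva_coi: dict[str, str]                  # larva -> COI read
    gut: dict[str, dict[str, str]]             # larva -> marker -> gut sequence


# -- community ---------------------------------------------------------


def _taxonomy_tables(params: CommunityParams, rng: np.random.Generator) -> pd.DataFrame:
    """Plant taxa with genus/family structure; genera hold 1-3 species."""
    rows = []
    genus_no = family_no = 0
    remaining = params.n_tree_species
    sp_no = 0
    genera_in_family = 0
    family_size = int(rng.integers(2, 4))
    while remaining > 0:
        genus_no += 1
        if genera_in_family >= family_size:
            genera_in_family = 0
            family_size = int(rng.integers(2, 4))
        if genera_in_family == 0:
            family_no += 1
        genera_in_family += 1
        size = min(int(rng.integers(1, 4)), remaining)
        for _ in range(size):
            sp_no += 1
            rows.append({
                "taxon_id": f"Plant_{sp_no:03d}",
                "species": f"Plant_{sp_no:03d}",
                "genus": f"Genus_{genus_no:02d}",
                "family": f"Family_{family_no:02d}",
                "growth_form": "tree",
                "sampled": False,
            })
        remaining -= size
    for k in range(params.n_nontree_taxa):
        rows.append({
            "taxon_id": f"Nontree_{k + 1:02d}",
            "species": f"Nontree_{k + 1:02d}",
            "genus": f"NtGenus_{k + 1:02d}",
            "family": f"NtFamily_{k // 2 + 1:02d}",
            "growth_form": "nontree",
            "sampled": False,
        })
    return pd.DataFrame(rows)


def _mark_indistinguishable(taxa: pd.DataFrame, p: float,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Plant cpDNA sharing between congener pairs; half also share ITS2."""
    taxa = taxa.copy()
    taxa["shares_cpdna_with"] = ""
    taxa["shares_its2_with"] = ""
    trees = taxa[taxa["growth_form"] == "tree"]
    for _, group in trees.groupby("genus", sort=True):
        ids = list(group["taxon_id"])
        for a, b in zip(ids[::2], ids[1::2]):
            if rng.random() < p:
                taxa.loc[taxa["taxon_id"] == b, "shares_cpdna_with"] = a
                if rng.random() < 0.5:
                    taxa.loc[taxa["taxon_id"] == b, "shares_its2_with"] = a
    return taxa


def _place_stems(params: CommunityParams, tree_ids: list[str],
                 rng: np.random.Generator) -> pd.DataFrame:
    W, H = params.plot_width_m, params.plot_height_m
    rows = []
    stem_no = 0
    for sp in tree_ids:
        n = max(1, int(rng.poisson(params.stems_per_species)))
        if params.point_process == "poisson":
            xs = rng.uniform(0, W, n)
            ys = rng.uniform(0, H, n)
        else:  # Thomas cluster process, wrapped on the torus to keep bounds
            n_parents = max(1, int(round(n / params.thomas_mean_per_parent)))
            px = rng.uniform(0, W, n_parents)
            py = rng.uniform(0, H, n_parents)
            parent = rng.integers(0, n_parents, n)
            xs = (px[parent] + rng.normal(0, params.thomas_sigma_m, n)) % W
            ys = (py[parent] + rng.normal(0, params.thomas_sigma_m, n)) % H
        for x, y in zip(xs, ys):
            stem_no += 1
            rows.append({"stem_id": f"stem_{stem_no:05d}", "species_id": sp,
                         "x_m": float(x), "y_m": float(y)})
    return pd.DataFrame(rows)


def generate_community(params: CommunityParams) -> tuple[ReferenceLibrary, StemMap]:
    """Plant taxa (trees + nontree), sampled flags and mapped stems."""
    rng = np.random.default_rng([params.rng_seed, 0])
    taxa = _taxonomy_tables(params, rng)
    taxa = _mark_indistinguishable(taxa, params.p_species_indistinguishable, rng)
    tree_ids = list(taxa.loc[taxa["growth_form"] == "tree", "taxon_id"])
    sampled = sorted(rng.choice(tree_ids, size=params.n_sampled_species,
                                replace=False))
    taxa.loc[taxa["taxon_id"].isin(sampled), "sampled"] = True
    stems = _place_stems(params, tree_ids, rng)
    return (ReferenceLibrary(taxa),
            StemMap(stems, params.plot_width_m, params.plot_height_m))


def insect_taxa(params: CommunityParams) -> pd.DataFrame:
    """Deterministic insect species table: species, family, order."""
    n_families = max(1, params.n_insect_species // 5)
    rows = [
        {"species": f"Lep_{i + 1:03d}",
         "family": f"LepFamily_{i % n_families + 1:02d}",
         "order": "Lepidoptera"}
        for i in range(params.n_insect_species)
    ]
    return pd.DataFrame(rows)


# -- larvae ------------------------------------------------------------


def _diet_breadth(params: CommunityParams, rng: np.random.Generator) -> int:
    name, *args = params.diet_breadth_distribution
    if name == "geometric":
        k = int(rng.geometric(args[0]))
    elif name == "poisson":
        k = 1 + int(rng.poisson(args[0]))
    elif name == "fixed":
        k = int(args[0])
    else:
        raise ValueError(f"unknown diet breadth distribution: {name!r}")
    return max(1, min(k, params.n_sampled_species))


def _fogged_stems(params: CommunityParams, stems: StemMap, sampled: list[str],
                  rng: np.random.Generator) -> dict[str, str]:
    """One fogged stem per sampled species, preferring stems with a
    heterospecific tree neighbor inside the drop-sheet radius."""
    all_pts = stems.stems[["x_m", "y_m"]].to_numpy()
    all_sp = stems.stems["species_id"].to_numpy()
    tree = cKDTree(all_pts)
    chosen = {}
    for sp in sampled:
        idx = np.flatnonzero(all_sp == sp)
        with_near = []
        for i in idx:
            nbrs = tree.query_ball_point(all_pts[i], params.near_radius_m)
            if any(all_sp[j] != sp for j in nbrs):
                with_near.append(i)
        pool = with_near if with_near else list(idx)
        pick = int(pool[rng.integers(0, len(pool))])
        chosen[sp] = stems.stems.iloc[pick]["stem_id"]
    return chosen


def generate_larvae(params: CommunityParams, reflib: ReferenceLibrary,
                    stems: StemMap) -> tuple[list[LarvaRecord], pd.DataFrame]:
    """Larvae with collection trees plus a separate ground-truth table.

    Ground-truth columns: ``larva_id``, ``true_diet``, ``true_class``
    (focal/near/far/nontree) and one outcome column per plant marker
    (``none`` / ``lowquality`` / ``ok``).
    """
    rng = np.random.default_rng([params.rng_seed, 1])
    insects = insect_taxa(params)
    sampled = reflib.sampled_ids
    if not sampled:
        raise ValueError("community has no sampled species")
    fogged = _fogged_stems(params, stems, sampled, rng)

    # per-species herbivore load and insect abundances
    load = rng.dirichlet(np.ones(len(sampled)))
    insect_weights = rng.dirichlet(np.full(params.n_insect_species, 0.5))
    host_sets = {}
    for sp_row in insects.itertuples():
        k = _diet_breadth(params, rng)
        host_sets[sp_row.species] = list(
            rng.choice(sampled, size=k, replace=False))

    tree_ids = reflib.tree_ids
    nontree_ids = reflib.nontree_ids
    near_candidates = {}
    for sp, stem_id in fogged.items():
        x, y = stems.coords_of(stem_id)
        near = [s for s in stems.species_within(x, y, params.near_radius_m,
                                                exclude=sp)]
        near_candidates[sp] = near

    class_probs = np.array([params.p_stay_on_host, params.p_near_drop,
                            params.p_far_disperse, params.p_nontree_diet])
    class_names = np.array(["focal", "near", "far", "nontree"])

    larvae, truth_rows = [], []
    for n in range(params.n_larvae):
        larva_id = f"larva_{n + 1:05d}"
        insect = insects.iloc[
            rng.choice(params.n_insect_species, p=insect_weights)]
        hosts = host_sets[insect.species]
        weights = np.array([load[sampled.index(h)] for h in hosts])
        host = hosts[int(rng.choice(len(hosts), p=weights / weights.sum()))]
        stem_id = fogged[host]
        x, y = stems.coords_of(stem_id)

        cls = str(rng.choice(class_names, p=class_probs))
        if cls == "near" and not near_candidates[host]:
            cls = "far"  # no heterospecific stem inside the sheet radius
        if cls == "focal":
            diet = host
        elif cls == "near":
            cand = near_candidates[host]
            diet = cand[int(rng.integers(0, len(cand)))]
        elif cls == "far":
            far = [s for s in tree_ids
                   if s != host and s not in near_candidates[host]]
            diet = far[int(rng.integers(0, len(far)))]
        else:
            diet = nontree_ids[int(rng.integers(0, len(nontree_ids)))]

        outcomes = {}
        for marker in PLANT_MARKERS:
            if rng.random() < params.marker_amplify_prob.get(marker, 0.0):
                outcomes[marker] = ("lowquality"
                                    if rng.random() < params.p_lowquality
                                    else "ok")
            else:
                outcomes[marker] = "none"

        morph = (insect.family
                 if rng.random() < params.p_morph_family_known else None)
        larvae.append(LarvaRecord(
            larva_id=larva_id, insect_species=insect.species,
            morph_family=morph, collection_stem=stem_id,
            collection_species=host, x_m=x, y_m=y,
            body_size_mm=float(rng.lognormal(math.log(8.0), 0.5)),
        ))
        truth_rows.append({"larva_id": larva_id, "true_diet": diet,
                           "true_class": cls, **outcomes})
    return larvae, pd.DataFrame(truth_rows)


# -- sequences ---------------------------------------------------------


def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return BASES[rng.integers(0, 4, length)]


def _mutate(seq: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    n_mut = rng.binomial(len(seq), divergence)
    if n_mut == 0:
        return out
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = BASES[BASES != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return out


def _to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode()


def generate_sequences(reflib: ReferenceLibrary, larvae: list[LarvaRecord],
                       ground_truth: pd.DataFrame,
                       intraspecific_div: float = 0.004,
                       interspecific_div: float = 0.05,
                       seed: int = 0) -> SequenceBundle:
    """Toy barcodes: plant references, insect COI, larval reads, gut contents.

    Species sequences are i.i.d.-substitution mutants of random ancestral
    sequences (genus-level ancestors for plants, so congeners are closer
    than cross-genus pairs); individuals add intraspecific substitutions.
    Taxa flagged as sharing a marker get byte-identical reference
    sequences for it.  Amplified-but-low-quality gut sequences are
    truncated to 70% of the amplicon (failing the 80% rule); plant
    reference sequences attach to ``reflib.sequences`` in place.
    """
    if not (0 <= intraspecific_div < 1 and 0 <= interspecific_div < 1):
        raise ValueError("divergence fractions must lie in [0, 1)")
    rng = np.random.default_rng([seed, 2])

    # plant references: genus ancestors, then per-species mutants
    share_cp = dict(zip(reflib.taxa["taxon_id"],
                        reflib.taxa.get("shares_cpdna_with", "")))
    share_its = dict(zip(reflib.taxa["taxon_id"],
                         reflib.taxa.get("shares_its2_with", "")))
    arrays: dict[str, dict[str, np.ndarray]] = {m: {} for m in PLANT_MARKERS}
    for marker in PLANT_MARKERS:
        length = SEQ_LENGTHS[marker]
        genus_anc: dict[str, np.ndarray] = {}
        for row in reflib.taxa.itertuples():
            anc = genus_anc.setdefault(row.genus, _random_seq(length, rng))
            arrays[marker][row.taxon_id] = _mutate(anc, interspecific_div, rng)
        for row in reflib.taxa.itertuples():
            donor = share_cp.get(row.taxon_id, "")
            if marker in ("rbcLa", "trnL") and donor:
                arrays[marker][row.taxon_id] = arrays[marker][donor].copy()
            donor_its = share_its.get(row.taxon_id, "")
            if marker == "ITS2" and donor_its:
                arrays[marker][row.taxon_id] = arrays[marker][donor_its].copy()
    for marker in PLANT_MARKERS:
        reflib.sequences[marker] = {t: _to_str(s) for t, s in arrays[marker].items()}

    # insect COI references and per-larva reads
    insect_species = sorted({l.insect_species for l in larvae})
    coi_len = SEQ_LENGTHS["COI"]
    insect_ref_arr = {sp: _random_seq(coi_len, rng) for sp in insect_species}
    larva_coi = {
        l.larva_id: _to_str(_mutate(insect_ref_arr[l.insect_species],
                                    intraspecific_div, rng))
        for l in larvae
    }

    # gut contents according to the hidden diet and marker outcomes
    truth = ground_truth.set_index("larva_id")
    gut: dict[str, dict[str, str]] = {}
    for l in larvae:
        row = truth.loc[l.larva_id]
        seqs = {}
        for marker in PLANT_MARKERS:
            outcome = row[marker]
            if outcome == "none":
                continue
            seq = _mutate(arrays[marker][row["true_diet"]],
                          intraspecific_div, rng)
            if outcome == "lowquality":
                seq = seq[: int(0.7 * len(seq))]
            seqs[marker] = _to_str(seq)
        if seqs:
            gut[l.larva_id] = seqs
    return SequenceBundle(
        insect_ref={sp: _to_str(s) for sp, s in insect_ref_arr.items()},
        larva_coi=larva_coi, gut=gut,
    )


def load_larvae(path) -> list[LarvaRecord]:
    """Read a larvae.csv written by :func:`write_outputs`."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        morph = d.get("morph_family")
        if isinstance(morph, float) and math.isnan(morph):
            morph = None
        records.append(LarvaRecord(
            larva_id=d["larva_id"], insect_species=d["insect_species"],
            morph_family=morph, collection_stem=d["collection_stem"],
            collection_species=d["collection_species"],
            x_m=float(d["x_m"]), y_m=float(d["y_m"]),
            body_size_mm=float(d["body_size_mm"]),
        ))
    return records


# -- file output -------------------------------------------------------


def write_outputs(outdir, params: CommunityParams, reflib: ReferenceLibrary,
                  stems: StemMap, larvae: list[LarvaRecord],
                  ground_truth: pd.DataFrame, bundle: SequenceBundle) -> None:
    """Write the generated data set as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params.to_json(out / "params.json")
    reflib.to_csv(out / "reflib.csv")
    stems.to_csv(out / "stems.csv")
    pd.DataFrame([asdict(l) for l in larvae]).to_csv(out / "larvae.csv", index=False)
    ground_truth.to_csv(out / "ground_truth.csv", index=False)
    for marker in PLANT_MARKERS:
        reflib.write_fasta(marker, out / f"plant_{marker}.fasta")
    with open(out / "insect_COI_ref.fasta", "w") as fh:
        for sp in sorted(bundle.insect_ref):
            fh.write(f">{sp}\n{bundle.insect_ref[sp]}\n")
    with open(out / "larva_COI.fasta", "w") as fh:
        for larva_id in sorted(bundle.larva_coi):
            fh.write(f">{larva_id}\n{bundle.larva_coi[larva_id]}\n")
    for marker in PLANT_MARKERS:
        with open(out / f"gut_{marker}.fasta", "w") as fh:
            for larva_id in sorted(bundle.gut):
                if marker in bundle.gut[larva_id]:
                    fh.write(f">{larva_id}\n{bundle.gut[larva_id][marker]}\n")
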