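"""End-to-end orchestration: synthetic data through every analysis stage.

``run_pipeline`` generates (or accepts) a community, delimits insect OTUs
from larval COI, identifies diets from gut-content barcodes, builds the
observation and molecular webs, classifies diet mismatches, fits the
detection logistic and runs the size-matched null comparison.  All
randomness descends from a single root seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from barcoweb import dietid, mismatch as mismatch_mod, webs as webs_mod
from barcoweb.detect import LogisticFit, fit_logistic, occurrence_counts, prediction_table
from barcoweb.netmetrics import MetricSet, metric_set
from barcoweb.nullcomp import NullEnvelope, null_envelope
from barcoweb.reflib import PLANT_MARKERS, ReferenceLibrary, StemMap
from barcoweb.seqqc_otu import (
    SequenceRecord,
    assign_taxonomy,
    cluster_otus,
    pairwise_distance_matrix,
    qc_filter,
    search_reference,
    write_otus_tsv,
)
from barcoweb.syndata import (
    CommunityParams,
    LarvaRecord,
    SequenceBundle,
    generate_community,
    generate_larvae,
    generate_sequences,
    insect_taxa,
    write_outputs,
)

log = logging.getLogger("barcoweb")


@dataclass
class PipelineConfig:
    """All stage parameters; the community's ``rng_seed`` is the root seed."""

    community: CommunityParams = field(default_factory=CommunityParams)
    otu_threshold: float = 0.02
    linkage: str = "average"
    min_identity: float = 0.95
    radius_m: float = 2.0
    level: str = "species"
    n_draws: int = 1000
    n_restarts: int = 10
    evenness_denominator: str = "cells"
    envelope_metrics: tuple | None = None
    intraspecific_div: float = 0.004
    interspecific_div: float = 0.05

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        community = CommunityParams(**data.pop("community", {}))
        if data.get("envelope_metrics") is not None:
            data["envelope_metrics"] = tuple(data["envelope_metrics"])
        return cls(community=community, **data)

    def to_json(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    reflib: ReferenceLibrary
    stems: StemMap
    larvae: list[LarvaRecord]
    ground_truth: pd.DataFrame
    bundle: SequenceBundle
    otu_assignments: dict[str, str]
    otu_labels: dict
    accepted_larvae: list[LarvaRecord]
    marker_results: dict[str, list]
    diet_calls: list
    matched_larvae: list[LarvaRecord]
    resolution: pd.DataFrame
    obs_web: webs_mod.BipartiteWeb
    mol_web: webs_mod.BipartiteWeb
    overlap: pd.DataFrame
    categories: dict[str, str]
    mismatch_summary: mismatch_mod.MismatchSummary
    accuracy: pd.DataFrame
    logistic_fit: LogisticFit | None
    obs_metrics: MetricSet
    mol_metrics: MetricSet
    envelope: NullEnvelope | None
    recovery_rate_pct: float


def _otu_stage(config: PipelineConfig, larvae: list[LarvaRecord],
               bundle: SequenceBundle, insects: pd.DataFrame
               ) -> tuple[dict[str, str], dict, list[LarvaRecord]]:
    """Cluster larval COI into OTUs and label them against the insect
    reference; returns (seq->OTU, OTU->assignment, accepted larvae)."""
    records = [
        SequenceRecord(l.larva_id, "COI", bundle.larva_coi[l.larva_id],
                       source_larva=l.larva_id)
        for l in larvae if l.larva_id in bundle.larva_coi
    ]
    records = [r for r in records if qc_filter(r)]
    dm = pairwise_distance_matrix(records)
    assignments = cluster_otus(dm, config.otu_threshold, config.linkage)

    reference = {
        row.species: (bundle.insect_ref[row.species], row.family, row.order)
        for row in insects.itertuples()
        if row.species in bundle.insect_ref
    }
    by_larva = {l.larva_id: l for l in larvae}
    members: dict[str, list[str]] = {}
    for seq_id, otu in assignments.items():
        members.setdefault(otu, []).append(seq_id)
    labels = {}
    for otu, seq_ids in sorted(members.items()):
        rep = min(seq_ids)
        hits = search_reference(bundle.larva_coi[rep], reference)
        morph = by_larva[rep].morph_family
        labels[otu] = assign_taxonomy(otu, hits[:5], morph_family=morph)

    accepted = []
    for l in larvae:
        otu = assignments.get(l.larva_id)
        if otu is None:
            continue
        a = labels[otu]
        if a.status == "accepted":
            l.insect_species = a.label
            accepted.append(l)
    n_dropped = len(larvae) - len(accepted)
    if n_dropped:
        log.info("OTU stage dropped %d larvae (discarded/unidentified OTUs)",
                 n_dropped)
    return assignments, labels, accepted


def _diet_stage(config: PipelineConfig, reflib: ReferenceLibrary,
                larvae: list[LarvaRecord], bundle: SequenceBundle):
    """Per-marker resolution and combined diet calls for every larva."""
    marker_results: dict[str, list] = {m: [] for m in PLANT_MARKERS}
    calls = []
    for l in larvae:
        seqs = bundle.gut.get(l.larva_id, {})
        results = []
        for marker in PLANT_MARKERS:
            if marker not in seqs:
                results.append(dietid.MarkerResult(l.larva_id, marker,
                                                   "no_amplification"))
                continue
            rec = SequenceRecord(f"{l.larva_id}_{marker}", marker,
                                 seqs[marker], source_larva=l.larva_id)
            if not qc_filter(rec):
                results.append(dietid.MarkerResult(l.larva_id, marker,
                                                   "discarded_low_quality"))
                continue
            res = dietid.resolve_marker(rec, reflib, config.min_identity)
            results.append(res)
            if res.outcome == "sequence":
                marker_results[marker].append(res)
        calls.append(dietid.combine_markers(results, reflib))
    return marker_results, calls


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None
                 ) -> PipelineResult:
    """Execute every stage on a synthetic community; optionally write files."""
    params = config.community
    log.info("generating community (seed %d)", params.rng_seed)
    reflib, stems = generate_community(params)
    larvae, truth = generate_larvae(params, reflib, stems)
    bundle = generate_sequences(reflib, larvae, truth,
                                config.intraspecific_div,
                                config.interspecific_div,
                                seed=params.rng_seed)
    insects = insect_taxa(params)

    assignments, labels, accepted = _otu_stage(config, larvae, bundle, insects)
    marker_results, calls = _diet_stage(config, reflib, accepted, bundle)

    calls_by_larva = {c.larva_id: c for c in calls}
    matched = [l for l in accepted
               if calls_by_larva.get(l.larva_id) and calls_by_larva[l.larva_id].items]
    recovery_rate = (100.0 * len(matched) / len(accepted)) if accepted else float("nan")
    log.info("diet identified for %d of %d larvae (%.1f%%)",
             len(matched), len(accepted), recovery_rate)

    calls_by_marker = {
        m: [dietid.combine_markers([r], reflib) for r in res]
        for m, res in marker_results.items()
    }
    matched_calls = [calls_by_larva[l.larva_id] for l in matched]
    resolution = dietid.resolution_summary(calls_by_marker, matched_calls, reflib)

    obs_web = webs_mod.build_observation_web(matched, config.level, reflib)
    mol_web = webs_mod.build_molecular_web(matched, matched_calls,
                                           config.level, reflib)
    overlap = webs_mod.overlap_tables(obs_web, mol_web)

    categories = {}
    for l in matched:
        try:
            categories[l.larva_id] = mismatch_mod.classify_larva(
                l, calls_by_larva[l.larva_id], stems, reflib,
                config.radius_m, config.level)
        except mismatch_mod.ClassificationError as exc:
            log.warning("larva %s not classified: %s", l.larva_id, exc)
    summary = mismatch_mod.summarize_mismatch(list(categories.values()))
    accuracy = mismatch_mod.accuracy_by_level(matched, matched_calls, reflib,
                                              marker_results)

    records = occurrence_counts(matched, categories)
    fit: LogisticFit | None
    try:
        fit = fit_logistic(records)
    except (ValueError, RuntimeError) as exc:
        log.warning("detection logistic not fitted: %s", exc)
        fit = None

    seed = params.rng_seed
    obs_metrics = metric_set(obs_web, seed=[seed, 10],
                             n_restarts=config.n_restarts,
                             evenness_denominator=config.evenness_denominator)
    mol_metrics = metric_set(mol_web, seed=[seed, 11],
                             n_restarts=config.n_restarts,
                             evenness_denominator=config.evenness_denominator)
    envelope: NullEnvelope | None
    try:
        envelope = null_envelope(obs_web, mol_web, n_draws=config.n_draws,
                                 seed=seed + 12,
                                 metrics=config.envelope_metrics,
                                 n_restarts=config.n_restarts)
    except (ValueError, RuntimeError) as exc:
        log.warning("null comparison skipped: %s", exc)
        envelope = None

    result = PipelineResult(
        reflib=reflib, stems=stems, larvae=larvae, ground_truth=truth,
        bundle=bundle, otu_assignments=assignments, otu_labels=labels,
        accepted_larvae=accepted, marker_results=marker_results,
        diet_calls=calls, matched_larvae=matched, resolution=resolution,
        obs_web=obs_web, mol_web=mol_web, overlap=overlap,
        categories=categories, mismatch_summary=summary, accuracy=accuracy,
        logistic_fit=fit, obs_metrics=obs_metrics, mol_metrics=mol_metrics,
        envelope=envelope, recovery_rate_pct=recovery_rate,
    )
    if outdir is not None:
        _write_report(Path(outdir), config, result)
    return result


def _write_report(out: Path, config: PipelineConfig, r: PipelineResult) -> None:
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    write_outputs(out / "syndata", config.community, r.reflib, r.stems,
                  r.larvae, r.ground_truth, r.bundle)
    write_otus_tsv(out / "otus.tsv", r.otu_assignments, r.otu_labels)
    dietid.write_diet_calls_tsv(out / "diet_calls.tsv",
                                [c for c in r.diet_calls if c.items], r.reflib)
    r.resolution.to_csv(out / "resolution_summary.tsv", sep="\t")
    r.obs_web.to_csv(out / "obs_web.csv")
    r.mol_web.to_csv(out / "mol_web.csv")
    r.overlap.to_csv(out / "overlap_table.tsv", sep="\t", index=False)
    mismatch_mod.write_mismatch_tsv(out / "mismatch.tsv", r.categories)
    mismatch_mod.write_summary_tsv(out / "mismatch_summary.tsv",
                                   r.mismatch_summary)
    r.accuracy.to_csv(out / "accuracy_by_level.tsv", sep="\t")
    metrics = {"observation": r.obs_metrics.to_dict(),
               "molecular": r.mol_metrics.to_dict(),
               "recovery_rate_pct": r.recovery_rate_pct}
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    if r.envelope is not None:
        r.envelope.to_json(out / "envelope.json")
        r.envelope.to_frame().to_csv(out / "envelope_table.tsv", sep="\t")
    if r.logistic_fit is not None:
        payload = r.logistic_fit.to_dict()
        payload["predictions"] = prediction_table(r.logistic_fit).to_dict("records")
        with open(out / "fit.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
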