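"""End-to-end orchestration: simulate -> preprocess -> de -> targets ->
enrich -> network, with one root seed, per-stage substreams, and a manifest
of output checksums for reproducibility.  A stage failure aborts the run
with the stage name and the offending record in the message."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as snio
from .config import RunConfig
from .de import call_de, normalize_cpm
from .enrichment import annotation_universe, fisher_enrichment, significant_terms
from .network import build_network, export_network
from .preprocess import (
    composition_report,
    count_features,
    filter_reads,
    map_reads_hierarchical,
)
from .seq import species_of, to_rna
from .simulate import (
    generate_annotation,
    generate_mirna_reference,
    generate_mrna_side,
    generate_reads,
    make_planted_truth,
)
from .targets import negative_correlation_filter, predict_targets, targets_by_mirna

log = logging.getLogger("seednet")

#: Substream indices: stage randomness is independent of which stages run.
_SUBSTREAMS = {"simulate": 0, "reads_control": 1, "reads_treated": 2, "mrna": 3,
               "annot": 4, "abundance": 5}

_ENRICH_COLUMNS = ["term_id", "label", "domain", "k", "n", "K", "N",
                   "pvalue", "fdr", "fold_enrichment", "neg_log2_p"]


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""


def stage_seed(root: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the root seed."""
    ss = np.random.SeedSequence(entropy=root, spawn_key=(_SUBSTREAMS[stage],))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def cross_species_gate(de_table: pd.DataFrame, cpm: pd.DataFrame,
                       focal: str, min_cpm: float) -> pd.DataFrame:
    """Demote cross-species features without remarkable expression.

    A "predicted" miRNA (mapped to a non-focal species) keeps a significant
    call only when its mean CPM reaches ``min_cpm``; the gate never touches
    focal-species features.
    """
    out = de_table.copy()
    mean_cpm = cpm.mean(axis=1)
    for fid in out.index:
        if species_of(fid) != focal and out.loc[fid, "significant"]:
            if mean_cpm.get(fid, 0.0) < min_cpm:
                out.loc[fid, "significant"] = False
    return out


def _stage_simulate(config: RunConfig, out: Path, emit) -> dict:
    truth = make_planted_truth(seed=config.seed)
    named = [(m, sp) for m, sp, _ in truth.de_mirnas]
    reference = generate_mirna_reference(
        config.n_per_species,
        seed=stage_seed(config.seed, "simulate"),
        species_order=config.species_order,
        named=named,
    )
    focal = config.species_order[0]
    # expressed features: the focal species' catalogue plus the planted
    # cross-species miRNAs (the ones an incomplete database would miss)
    expressed = [r.id for r in reference
                 if species_of(r.id) == focal or r.id in truth.effects]
    rng = np.random.default_rng(stage_seed(config.seed, "abundance"))
    base_cpm = np.exp(rng.uniform(np.log(50.0), np.log(2000.0), size=len(expressed)))
    effects = truth.effects
    for sample, stream in (("control", "reads_control"), ("treated", "reads_treated")):
        mult = np.array(
            [2.0 ** effects.get(f, 0.0) if sample == "treated" else 1.0 for f in expressed]
        )
        lam = base_cpm * mult
        lam = lam / lam.sum() * (1.0 - config.contaminant_fraction) * config.depth
        reads = generate_reads(
            reference,
            dict(zip(expressed, lam)),
            adapter=config.adapter,
            contaminant_fraction=config.contaminant_fraction,
            seed=stage_seed(config.seed, stream),
        )
        path = emit(snio.write_fastq(reads, out / f"reads_{sample}.fastq"))
        config.reads[sample] = str(path)
    config.reference_fasta = str(emit(snio.write_fasta(reference, out / "reference.fasta")))
    mrna_de, utrs, _decoys = generate_mrna_side(
        truth, reference, n_genes=config.n_genes, utr_length=config.utr_length,
        seed=stage_seed(config.seed, "mrna"), decoys_per_mirna=config.decoys_per_mirna,
    )
    config.mrna_de_table = str(emit(snio.write_table(mrna_de, out / "mrna_de.tsv", index=False)))
    config.utr_fasta = str(emit(snio.write_fasta(utrs, out / "utrs.fasta")))
    annotation = generate_annotation(
        truth, background_genes=list(mrna_de["gene_id"]), n_terms=config.n_terms,
        seed=stage_seed(config.seed, "annot"),
    )
    config.annotation_gmt = str(emit(snio.write_gmt(annotation, out / "annotation.gmt")))
    emit(snio.write_annotation_tsv(annotation, out / "annotation.tsv"))
    (out / "truth.json").write_text(truth.to_json())
    emit(out / "truth.json")
    log.info("simulate: %d reference miRNAs, %d genes, %d terms",
             len(reference), len(mrna_de), len(annotation))
    return {"reference": len(reference), "genes": len(mrna_de), "terms": len(annotation)}


def _stage_preprocess(config: RunConfig, out: Path, emit) -> dict:
    focal = config.species_order[0]
    reference = snio.read_fasta(config.reference_fasta)
    by_species: dict[str, list] = {sp: [] for sp in config.species_order}
    for rec in reference:
        sp = species_of(rec.id)
        if sp in by_species:
            by_species[sp].append(rec)
    refs = [(sp, by_species[sp]) for sp in config.species_order]
    columns, qcs = [], {}
    cross_tags: dict[str, bool] = {}
    for sample, fastq in sorted(config.reads.items()):
        reads = snio.read_fastq_reads(fastq)
        kept, qc = filter_reads(
            reads, adapter=config.adapter, q_threshold=config.q_threshold,
            q_fraction=config.q_fraction, min_len=config.min_len,
        )
        qc.sample = sample
        assignments, unmapped = map_reads_hierarchical(
            kept, refs, min_overlap=config.min_len, max_mismatches=config.max_mismatches,
        )
        qc.mapped_focal = sum(1 for a in assignments if not a.cross_species)
        qc.mapped_cross = sum(1 for a in assignments if a.cross_species)
        qc.unmapped = len(unmapped)
        qcs[sample] = qc
        for a in assignments:
            cross_tags[a.mirna_id] = a.cross_species
        columns.append(count_features(assignments, sample))
        log.info("preprocess[%s]: %d raw, %d kept, %d assigned",
                 sample, qc.total_raw, qc.kept, len(assignments))
    counts = pd.concat(columns, axis=1).fillna(0).astype(int).sort_index()
    counts.index.name = "feature_id"
    meta = pd.DataFrame({
        "species_tag": [species_of(f) for f in counts.index],
        "cross_species": [cross_tags.get(f, species_of(f) != focal) for f in counts.index],
    }, index=counts.index)
    emit(snio.write_table(pd.concat([meta, counts], axis=1), out / "counts.tsv"))
    qc_df = pd.DataFrame([vars(q) for q in qcs.values()]).set_index("sample")
    emit(snio.write_table(qc_df, out / "qc.tsv"))
    emit(snio.write_table(composition_report(qcs), out / "composition.tsv"))
    return {s: {"raw": q.total_raw, "kept": q.kept} for s, q in qcs.items()}


def _stage_de(config: RunConfig, out: Path, emit) -> dict:
    focal = config.species_order[0]
    table = snio.read_table(out / "counts.tsv", index_col="feature_id")
    counts = table[[config.control, config.treated]]
    de_table = call_de(
        counts, treated=config.treated, control=config.control,
        fc_min=config.fc_min, alpha=config.alpha, fdr_alpha=config.fdr,
    )
    de_table = cross_species_gate(de_table, normalize_cpm(counts), focal, config.min_cpm)
    emit(snio.write_table(de_table, out / "mirna_de.tsv"))
    log.info("de: %d tested, %d significant",
             de_table["tested"].sum(), de_table["significant"].sum())
    return {"tested": int(de_table["tested"].sum()),
            "significant": int(de_table["significant"].sum())}


def _stage_targets(config: RunConfig, out: Path, emit) -> dict:
    de_table = snio.read_table(out / "mirna_de.tsv", index_col="feature_id")
    reference = {r.id: to_rna(str(r.seq)) for r in snio.read_fasta(config.reference_fasta)}
    utrs = {r.id: to_rna(str(r.seq)) for r in snio.read_fasta(config.utr_fasta)}
    sig = [m for m in de_table.index[de_table["significant"]] if m in reference]
    predictions = predict_targets(
        {m: reference[m] for m in sig}, utrs, min_score=config.min_score,
    )
    mrna_de = snio.read_table(config.mrna_de_table)
    filtered = negative_correlation_filter(
        predictions, de_table, mrna_de, alpha=config.alpha, fdr=config.fdr,
    )
    emit(snio.write_table(predictions, out / "predictions.tsv", index=False))
    emit(snio.write_table(filtered, out / "filtered_targets.tsv", index=False))
    log.info("targets: %d predicted, %d after anti-correlation",
             len(predictions), len(filtered))
    return {"predicted_pairs": len(predictions), "filtered_pairs": len(filtered)}


def _stage_enrich(config: RunConfig, out: Path, emit) -> dict:
    annotation = snio.read_gmt(config.annotation_gmt)
    universe = annotation_universe(annotation)
    de_table = snio.read_table(out / "mirna_de.tsv", index_col="feature_id")
    filtered = snio.read_table(out / "filtered_targets.tsv")
    by_mirna = targets_by_mirna(filtered)
    n_sig_terms = {}
    for direction in ("down", "up"):
        mirnas = de_table.index[
            (de_table["significant"]) & (de_table["direction"] == direction)
        ]
        fg: set[str] = set()
        for m in mirnas:
            fg |= by_mirna.get(m, frozenset())
        fg &= set(universe)
        if fg:
            results = fisher_enrichment(fg, annotation, universe)
            sig = significant_terms(results, alpha=config.alpha, fdr=config.fdr)
        else:
            results = sig = pd.DataFrame(columns=_ENRICH_COLUMNS)
        emit(snio.write_table(results, out / f"enrichment_{direction}.tsv", index=False))
        emit(snio.write_table(sig, out / f"enrichment_{direction}_significant.tsv",
                              index=False))
        n_sig_terms[direction] = len(sig)
        log.info("enrich[%s]: %d genes, %d tested terms, %d significant",
                 direction, len(fg), len(results), len(sig))
    return n_sig_terms


def _stage_network(config: RunConfig, out: Path, emit) -> dict:
    annotation = snio.read_gmt(config.annotation_gmt)
    de_table = snio.read_table(out / "mirna_de.tsv", index_col="feature_id")
    filtered = snio.read_table(out / "filtered_targets.tsv")
    by_mirna = targets_by_mirna(filtered)
    stats = {}
    for direction in ("down", "up"):
        sig = snio.read_table(out / f"enrichment_{direction}_significant.tsv")
        for domain in ("BP", "MF", "CC", "pathway"):
            g = build_network(direction, de_table, by_mirna, sig, annotation, domain)
            stem = out / f"network_{direction}_{domain}"
            emit(export_network(g, stem.with_suffix(".graphml"), "graphml"))
            emit(export_network(g, stem.with_suffix(".tsv"), "tsv"))
            stats[f"{direction}/{domain}"] = {
                "nodes": g.number_of_nodes(), "edges": g.number_of_edges(),
            }
    return stats


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "de": _stage_de,
    "targets": _stage_targets,
    "enrich": _stage_enrich,
    "network": _stage_network,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    The manifest records the seed, per-stage row counts, and a sha256
    checksum of every output file; identical configurations reproduce
    identical checksums.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    written: list[Path] = []

    def emit(path: Path) -> Path:
        written.append(Path(path))
        return Path(path)

    for name in _STAGE_FUNCS:
        if name not in config.stages:
            continue
        try:
            manifest["stages"][name] = _STAGE_FUNCS[name](config, out, emit)
        except Exception as exc:
            raise StageError(f"pipeline stage '{name}' failed: {exc}") from exc

    for path in written:
        manifest["outputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
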