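"""End-to-end workflow: filtering -> constraint -> selection -> controls -> GWAS.

Glues the per-stage modules into the full validation pipeline. All stages
operate on in-memory objects; the CLI and the synthetic-bundle loader adapt
files to these inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import (
    conservation_and_selection as cons,
    constraint_model as cm,
    frame_control as fc,
    gwas_enrichment as ge,
    smorf_catalog as cat,
    variant_effects as ve,
)
from ._seq import Genome
from .errors import DataError


def prediction_to_model(pred: cat.OrfPrediction) -> ve.OrfModel:
    return ve.OrfModel(pred.id, pred.chrom, pred.strand, pred.exons,
                       source={"dataset": pred.source})


def is_valid_orf(model: ve.OrfModel, genome: Genome) -> bool:
    """Complete ORF check: starts ATG, single terminal stop, length % 3 == 0."""
    if model.total_length % 3 != 0 or model.total_length < 9:
        return False
    try:
        aa = ve.spliced_sequence(model, genome)
    except Exception:
        return False
    from ._seq import translate

    try:
        prot = translate(aa)
    except DataError:
        return False
    return aa.startswith("ATG") and prot.endswith("*") and "*" not in prot[:-1]


def filter_prediction_set(
    preds: list[cat.OrfPrediction],
    annotation: cat.AnnotationSet,
    category_whitelist=None,
    min_codons: int = 10,
    max_codons: int = 150,
) -> tuple[list[cat.OrfPrediction], pd.DataFrame]:
    """Category -> length -> longest-isoform -> annotation-overlap filtering."""
    if category_whitelist is not None:
        preds = [p for p in preds if p.category in category_whitelist]
    preds = cat.filter_by_length(preds, min_codons, max_codons)
    preds = cat.select_longest_isoform(preds)
    return cat.exclude_annotation_overlaps(preds, annotation)


@dataclass
class PipelineResult:
    survivors_a: list[cat.OrfPrediction]
    survivors_b: list[cat.OrfPrediction]
    exclusion_log: pd.DataFrame
    intersection: cat.IntersectionReport
    smorf_models: list[ve.OrfModel]
    gene_models: list[ve.OrfModel]
    calibration: cm.Calibration
    constraint: pd.DataFrame
    conservation: pd.DataFrame
    selection: pd.DataFrame
    high_confidence: set[str] = field(default_factory=set)
    capture: pd.DataFrame | None = None
    frame_table: pd.DataFrame | None = None
    frame_tests_moeuf: pd.DataFrame | None = None
    frame_tests_ns: pd.DataFrame | None = None
    enrichment: ge.EnrichmentResult | None = None
    gwas_hits: pd.DataFrame | None = None


def intersection_class_groups(report: cat.IntersectionReport) -> dict[str, list[str]]:
    """smORF benchmark groups from the cross-dataset intersection."""
    part = report.entity_partition()
    return {
        "smorf_exact_both": sorted(part["exact_a"]),
        "smorf_imperfect_both": sorted(part["imperfect_a"] | part["imperfect_b"]),
        "smorf_unique_a": sorted(part["unique_a"]),
        "smorf_unique_b": sorted(part["unique_b"]),
    }


def gene_benchmark_groups(
    genes: list[cat.AnnotationGene], scored_ids: set[str]
) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {
        "refseq_lowpLI": [],
        "refseq_modpLI": [],
        "refseq_highpLI": [],
        "refseq_short": [],
    }
    for g in genes:
        if g.id not in scored_ids:
            continue
        if g.aa_length is not None and g.aa_length < 150:
            groups["refseq_short"].append(g.id)
        tier = cons.pli_group(g.pli)
        if tier == "low":
            groups["refseq_lowpLI"].append(g.id)
        elif tier == "moderate":
            groups["refseq_modpLI"].append(g.id)
        elif tier == "high":
            groups["refseq_highpLI"].append(g.id)
    return groups


def run_pipeline(
    genome: Genome,
    preds_a: list[cat.OrfPrediction],
    preds_b: list[cat.OrfPrediction],
    annotation: cat.AnnotationSet,
    variants: pd.DataFrame,
    rate_table: cm.MutationRateTable,
    conservation_track: cons.ConservationTrack,
    catalog: pd.DataFrame | None = None,
    arrays: pd.DataFrame | None = None,
    ld_pairs: pd.DataFrame | None = None,
    methylation=None,
    category_whitelist_a=cat.CHEN_CATEGORY_WHITELIST,
    maf_max: float = 0.001,
    moeuf_max: float = cons.MOEUF_MAX_DEFAULT,
    gerp_min: float = cons.GERP_MIN_DEFAULT,
    n_perm: int = 10_000,
    seed: int = 0,
    with_frames: bool = True,
) -> PipelineResult:
    """The full smORF-validation workflow on in-memory inputs.

    The category whitelist applies to set A only (the dataset that carries
    free-text ORF labels). Calibration is fit on synonymous variation across
    annotated genes and smORF candidates jointly.
    """
    surv_a, log_a = filter_prediction_set(preds_a, annotation, category_whitelist_a)
    surv_b, log_b = filter_prediction_set(preds_b, annotation, None)
    exclusion_log = pd.concat([log_a, log_b], ignore_index=True)
    report = cat.intersect_datasets(surv_a, surv_b)

    # union of surviving smORFs; exact duplicates keep the set-A record
    dup_b = {b for _, b in report.exact_pairs}
    smorf_models = [prediction_to_model(p) for p in surv_a]
    smorf_models += [prediction_to_model(p) for p in surv_b if p.id not in dup_b]

    gene_models = []
    for g in annotation.genes:
        model = ve.OrfModel(g.id, g.chrom, "+", g.exons)
        for strand in "+-":
            m = ve.OrfModel(g.id, g.chrom, strand, g.exons)
            if is_valid_orf(m, genome):
                model = m
                break
        else:
            continue
        gene_models.append(model)

    all_models = gene_models + smorf_models
    calibration = cm.fit_calibration(
        all_models, genome, variants, rate_table, methylation, maf_max
    )
    constraint = cm.score_entities(
        all_models, genome, variants, rate_table, calibration, methylation, maf_max
    )
    conservation = cons.summarize_conservation(all_models, conservation_track)
    scores = constraint.merge(conservation, on="id", how="left")
    selection = cons.select_high_confidence(scores, moeuf_max, gerp_min)
    gene_ids = {m.id for m in gene_models}
    hc_all = cons.selected_ids(selection)
    high_confidence = {i for i in hc_all if i not in gene_ids}

    groups = intersection_class_groups(report)
    groups.update(gene_benchmark_groups(annotation.genes, gene_ids))
    capture = cons.capture_report(groups, hc_all)

    result = PipelineResult(
        survivors_a=surv_a,
        survivors_b=surv_b,
        exclusion_log=exclusion_log,
        intersection=report,
        smorf_models=smorf_models,
        gene_models=gene_models,
        calibration=calibration,
        constraint=constraint,
        conservation=conservation,
        selection=selection,
        high_confidence=high_confidence,
        capture=capture,
    )

    if with_frames:
        hc_smorfs = [m for m in smorf_models if m.id in high_confidence]
        if hc_smorfs:
            frame_table = fc.run_frame_analysis(
                hc_smorfs, genome, variants, rate_table, calibration, methylation, maf_max
            )
            result.frame_table = frame_table
            try:
                result.frame_tests_moeuf = fc.paired_frame_test(frame_table, "moeuf")
                result.frame_tests_ns = fc.paired_frame_test(frame_table, "ns_ratio")
            except DataError:
                pass

    if catalog is not None and arrays is not None and ld_pairs is not None:
        cat_clean = ge.filter_catalog(catalog)
        universe = ge.ld_expand(arrays, ld_pairs)
        hc_exons = [
            (m.chrom, s, e)
            for m in smorf_models
            if m.id in high_confidence
            for s, e in m.exons
        ]
        if hc_exons:
            index = ge.ExonIndex(hc_exons)
            common = cat_clean[
                (ve.folded_maf(cat_clean["maf"]) >= ge.COMMON_MAF_MIN)
            ].copy()
            common["maf"] = ve.folded_maf(common["maf"].to_numpy())
            result.enrichment = ge.run_enrichment(
                common, universe, index, n_perm=n_perm,
                rng=np.random.default_rng(seed),
            )
            _, hits = ge.overlap_count(common, index)
            result.gwas_hits = _annotate_hits(hits, smorf_models, high_confidence, genome)
    return result


def _annotate_hits(
    hits: pd.DataFrame,
    smorf_models: list[ve.OrfModel],
    high_confidence: set[str],
    genome: Genome,
) -> pd.DataFrame:
    """Attach the containing smORF and codon consequence to each GWAS hit."""
    rows = []
    hc_models = [m for m in smorf_models if m.id in high_confidence]
    for rec in hits.itertuples(index=False):
        for m in hc_models:
            if m.chrom != rec.chrom:
                continue
            if not any(s <= rec.pos < e for s, e in m.exons):
                continue
            try:
                csq = ve.classify_consequence(m, genome, int(rec.pos), rec.ref, rec.alt)
            except Exception:
                csq = "unknown"
            rows.append(
                {
                    "rsid": rec.rsid,
                    "smorf_id": m.id,
                    "pos": int(rec.pos),
                    "consequence": csq,
                    "trait": getattr(rec, "trait", ""),
                }
            )
            break
    return pd.DataFrame(rows, columns=["rsid", "smorf_id", "pos", "consequence", "trait"])
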