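"""End-to-end orchestration of the analysis stages.

Each ``run_*`` function consumes in-memory objects and returns a dict of
result objects; :func:`run_all` wires them together over a directory of
input files (typically one produced by ``saltomics simulate``) and writes
every stage's TSV outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, integration, metabolome, pairs, proteome, transcriptome
from .config import PipelineConfig
from .errors import ValidationError
from .expression import MEAN, ExperimentDesign, ExpressionTable, read_expression, write_expression
from .features import FeatureSet, read_annotation
from .io import read_ko_annotation, read_table, write_table

logger = logging.getLogger(__name__)


def run_transcriptome(
    signals: ExpressionTable,
    design: ExperimentDesign,
    probe_map: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    config = config or PipelineConfig()
    if probe_map is not None:
        signals = transcriptome.aggregate_probes(signals, probe_map)
    mean_fc, per_rep_fc = transcriptome.compute_fold_changes(signals, design)
    de = transcriptome.call_differential(mean_fc, signals, design, config)
    return dict(signals=signals, mean_fc=mean_fc, per_replicate_fc=per_rep_fc, de_records=de)


def run_clustering(
    mean_fc: ExpressionTable,
    design: ExperimentDesign,
    config: PipelineConfig | None = None,
    seed: int = 0,
    c: int | None = None,
    m: float | None = None,
) -> dict:
    """Prefilter, standardize 4-point profiles, select c, fit FCM, assign.

    The clustered profile is the log2 fold-change vector over all time
    points with the reference pinned at 0; after row standardization this
    is identical to clustering the 4-point signal profiles, and keeps the
    dimension D = 4 used by the fuzzifier estimate.
    """
    config = config or PipelineConfig()
    filtered = transcriptome.prefilter_for_clustering(mean_fc, config.prefilter_log2fc_min)
    profile = filtered.data.copy()
    profile.insert(0, (design.reference, MEAN), 0.0)
    profile.columns = [tp for tp, _rep in profile.columns]
    X = clustering.standardize_profiles(profile)
    m = m if m is not None else clustering.estimate_fuzzifier(len(X), X.shape[1])
    curve = None
    if c is None:
        c, curve = clustering.select_cluster_count(
            X, m, range(config.c_min, config.c_max + 1), seed=seed)
    model = clustering.fuzzy_cmeans(
        X, c, m, seed=seed, tol=config.fcm_tol,
        max_iter=config.fcm_max_iter, n_init=config.fcm_restarts)
    assignments = clustering.assign_clusters(
        model, config.membership_min, config.combined_membership_min)
    return dict(model=model, assignments=assignments, elbow_curve=curve,
                standardized=X, m=m, c=c)


def run_pairs(
    features: FeatureSet,
    per_replicate_fc: ExpressionTable,
    assignments: pd.Series,
    directions: tuple[str, ...],
    de_records: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict:
    config = config or PipelineConfig()
    duos = pairs.find_antisense_pairs(features)
    records = pairs.classify_pairs(
        duos, per_replicate_fc, assignments, directions, de_records, config.r_min)
    return dict(pairs=duos, pair_records=records, pair_summary=pairs.pair_summary(records))


def run_proteome(quants: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    config = config or PipelineConfig()
    filtered = proteome.filter_identifications(
        quants, config.min_peptides, config.single_peptide_allow_list)
    fcs = proteome.protein_fold_changes(filtered, config)
    return dict(filtered=filtered, protein_fc=fcs)


def run_integration(
    de_records: pd.DataFrame,
    protein_fc: pd.DataFrame,
    design: ExperimentDesign,
    extra_transcriptomes: list[pd.Series] | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    config = config or PipelineConfig()
    final_tp = design.timepoints[-1]
    t24 = (
        de_records[de_records.timepoint == final_tp]
        .set_index("feature_id")["log2fc"]
    )
    matches, unmatched = integration.match_transcript_protein(
        t24, protein_fc, similar_log2_max=config.similar_log2_max)
    r = integration.cross_omics_correlation(matches) if len(matches) >= 3 else np.nan
    out = dict(matches=matches, unmatched=unmatched, correlation=r, consensus=None)
    if extra_transcriptomes:
        if len(extra_transcriptomes) != 2:
            raise ValidationError("expected 2 extra transcriptome datasets (3 total)")
        prot_log2 = pd.Series(
            np.log2(protein_fc.set_index("protein_id")["fc_combined"]))
        out["consensus"] = integration.consensus_filter(
            [t24] + list(extra_transcriptomes), prot_log2,
            t_thresh=config.consensus_transcript_log2_min,
            p_thresh=config.consensus_protein_log2_min,
            protein_identified=set(protein_fc.protein_id),
        )
    return out


def run_metabolome(measurements: pd.DataFrame) -> dict:
    normalized = metabolome.normalize_to_standard(measurements)
    return dict(normalized=normalized,
                fold_changes=metabolome.metabolite_fold_changes(normalized))


def run_all(
    in_dir,
    out_dir,
    design: ExperimentDesign | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> dict:
    """Run every stage over a directory of input files and write reports.

    Expects the file layout produced by ``saltomics simulate``; external
    data prepared in the same formats works identically.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    design = design or ExperimentDesign()

    features = read_annotation(in_dir / "annotation.gff3")
    signals = read_expression(in_dir / "transcriptome_signals.tsv", design)
    tr = run_transcriptome(signals, design, config=config)
    write_expression(tr["mean_fc"], out_dir / "fold_changes.tsv")
    write_expression(tr["per_replicate_fc"], out_dir / "per_replicate_fc.tsv")
    write_table(tr["de_records"], out_dir / "de_records.tsv")

    cl = run_clustering(tr["mean_fc"], design, config=config, seed=seed)
    model = cl["model"]
    memberships = model.memberships.copy()
    memberships["assignment"] = cl["assignments"].astype("object")
    memberships.rename_axis("feature_id").reset_index().pipe(
        write_table, out_dir / "cluster_memberships.tsv")
    centroids = pd.DataFrame(model.centroids,
                             columns=[f"{tp:g}h" for tp in design.timepoints])
    centroids.insert(0, "cluster", np.arange(1, model.c + 1))
    centroids.insert(1, "direction", list(model.direction))
    write_table(centroids, out_dir / "centroids.tsv")
    if cl["elbow_curve"] is not None:
        write_table(cl["elbow_curve"], out_dir / "elbow_curve.tsv")

    pr = run_pairs(features, tr["per_replicate_fc"], cl["assignments"],
                   model.direction, tr["de_records"], config=config)
    write_table(pr["pair_records"], out_dir / "pair_records.tsv")
    write_table(pr["pair_summary"], out_dir / "pair_summary.tsv")

    quants = read_table(in_dir / "proteome_quants.tsv")
    pt = run_proteome(quants, config=config)
    write_table(pt["protein_fc"], out_dir / "protein_fold_changes.tsv")

    extras = []
    for k in (1, 2):
        path = in_dir / f"extra_transcriptome_{k}.tsv"
        if path.exists():
            extras.append(read_table(path).set_index("gene_id")["log2fc"])
    ig = run_integration(tr["de_records"], pt["protein_fc"], design,
                         extra_transcriptomes=extras or None, config=config)
    write_table(ig["matches"], out_dir / "omics_matches.tsv")
    write_table(pd.DataFrame([dict(n_matches=len(ig["matches"]),
                                   pearson_r=ig["correlation"])]),
                out_dir / "correlation_summary.tsv")
    if ig["consensus"] is not None:
        write_table(ig["consensus"], out_dir / "consensus_genes.tsv")

    ko_path = in_dir / "ko_annotation.tsv"
    enrichment = None
    if ko_path.exists():
        ko = read_ko_annotation(ko_path)
        mrna_ids = {f.feature_id for f in features if f.feature_type.value == "mRNA"}
        mrna_assign = cl["assignments"][cl["assignments"].index.isin(mrna_ids)]
        enrichment = integration.ko_enrichment(mrna_assign, ko)
        write_table(enrichment, out_dir / "enrichment.tsv")

    met_path = in_dir / "metabolome.tsv"
    met = None
    if met_path.exists():
        met = run_metabolome(read_table(met_path))
        write_table(met["fold_changes"], out_dir / "metabolite_fold_changes.tsv")

    return dict(transcriptome=tr, clustering=cl, pairs=pr, proteome=pt,
                integration=ig, enrichment=enrichment, metabolome=met)
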