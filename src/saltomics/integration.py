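"""Cross-omics integration: transcript/protein matching, correlation,
consensus filtering across datasets, and KO-term enrichment per cluster.

Transcript (24 h) and protein (7 d) log2 fold changes are joined by locus
tag; a match is "similar" when the two log2 fold changes differ by less
than log2(1.5).  The consensus filter keeps genes increased in three
transcriptome datasets (log2 > 0.58, i.e. > 1.5-fold) and in the proteome
(log2 > 0.38, i.e. > 1.3-fold), both strict.  Functional enrichment per
expression cluster uses the one-sided hypergeometric upper tail over KEGG
Orthology terms with Benjamini-Hochberg adjustment within each cluster.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .errors import ValidationError

logger = logging.getLogger(__name__)


def match_transcript_protein(
    transcript_log2fc: pd.Series,
    protein_fc: pd.DataFrame,
    id_map: pd.Series | None = None,
    similar_log2_max: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join transcript and protein fold changes by locus tag.

    Parameters
    ----------
    transcript_log2fc : Series of 24 h log2 fold changes indexed by feature id.
    protein_fc : DataFrame with ``protein_id`` and linear ``fc_combined``.
    id_map : optional Series mapping transcript feature id -> locus tag; by
        default the feature id is the locus tag.

    Returns ``(matches, unmatched)``: matches carry gene_id, both log2 fold
    changes and the similar flag; unmatched lists genes present in only one
    omics layer with a ``side`` column.
    """
    similar_log2_max = (
        PipelineConfig().similar_log2_max if similar_log2_max is None else similar_log2_max
    )
    t = transcript_log2fc.copy()
    if id_map is not None:
        t.index = t.index.map(id_map.to_dict())
        t = t[t.index.notna()]
    if t.index.has_duplicates:
        logger.warning("match_transcript_protein: duplicate locus tags on transcript side; "
                       "first kept")
        t = t[~t.index.duplicated()]
    p = protein_fc.set_index("protein_id")["fc_combined"]
    if p.index.has_duplicates:
        logger.warning("match_transcript_protein: duplicate locus tags on protein side; "
                       "first kept")
        p = p[~p.index.duplicated()]
    p = p[p > 0]
    common = t.index.intersection(p.index)
    matches = pd.DataFrame(
        {
            "gene_id": common,
            "transcript_log2fc": t.loc[common].to_numpy(dtype=float),
            "protein_log2fc": np.log2(p.loc[common].to_numpy(dtype=float)),
        }
    )
    matches["similar"] = (
        (matches.transcript_log2fc - matches.protein_log2fc).abs() < similar_log2_max
    )
    unmatched = pd.concat(
        [
            pd.DataFrame({"gene_id": t.index.difference(p.index), "side": "transcript_only"}),
            pd.DataFrame({"gene_id": p.index.difference(t.index), "side": "protein_only"}),
        ],
        ignore_index=True,
    )
    matches = matches.dropna(subset=["transcript_log2fc", "protein_log2fc"]).reset_index(drop=True)
    logger.info("match_transcript_protein: %d pairs matched", len(matches))
    return matches, unmatched


def cross_omics_correlation(matches: pd.DataFrame) -> float:
    """Pearson r between transcript and protein log2 fold changes."""
    sub = matches.dropna(subset=["transcript_log2fc", "protein_log2fc"])
    if len(sub) < 3:
        raise ValidationError("cross-omics correlation needs >= 3 matches")
    x = sub.transcript_log2fc.to_numpy()
    y = sub.protein_log2fc.to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def consensus_filter(
    transcriptomes: list[pd.Series],
    proteome: pd.Series,
    t_thresh: float = 0.58,
    p_thresh: float = 0.38,
    protein_identified: set[str] | None = None,
) -> pd.DataFrame:
    """Consensus of three transcriptome datasets and one proteome dataset.

    Gene universe is the intersection of genes present (non-NaN) in all four
    tables; a gene passes iff every transcriptome log2 FC is strictly above
    *t_thresh* and the proteome log2 FC strictly above *p_thresh*.
    """
    if len(transcriptomes) != 3:
        raise ValidationError("consensus filter needs exactly 3 transcriptome datasets")
    tables = [t.dropna() for t in transcriptomes] + [proteome.dropna()]
    universe = tables[0].index
    for t in tables[1:]:
        universe = universe.intersection(t.index)
    records = []
    for gene in universe:
        tvals = [float(t.loc[gene]) for t in tables[:3]]
        pval = float(tables[3].loc[gene])
        passes = all(v > t_thresh for v in tvals) and pval > p_thresh
        records.append(
            dict(
                gene_id=gene,
                transcriptome_1=tvals[0],
                transcriptome_2=tvals[1],
                transcriptome_3=tvals[2],
                proteome=pval,
                passes=passes,
                protein_identified=(
                    gene in protein_identified if protein_identified is not None else pd.NA
                ),
            )
        )
    out = pd.DataFrame(
        records,
        columns=["gene_id", "transcriptome_1", "transcriptome_2", "transcriptome_3",
                 "proteome", "passes", "protein_identified"],
    )
    logger.info("consensus_filter: %d of %d genes pass", int(out.passes.sum()), len(out))
    return out


def hypergeometric_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p = P(X >= k) for k term members in a
    cluster of size n, with K term members in a universe of N genes."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValidationError(f"invalid enrichment counts k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ko_enrichment(
    assignments: pd.Series,
    ko_annotation: pd.DataFrame,
    universe: pd.Index | None = None,
) -> pd.DataFrame:
    """KO-term over-representation per cluster.

    *assignments* maps gene -> cluster (NA = unassigned); *ko_annotation*
    has one (gene_id, ko_term) row per annotation.  The universe defaults to
    all assigned genes.  Terms absent from a cluster (k = 0) are skipped;
    BH adjustment runs across terms within each cluster.
    """
    assigned = assignments.dropna()
    if universe is None:
        universe = assigned.index
    universe = pd.Index(universe)
    N = len(universe)
    anno = ko_annotation[ko_annotation.gene_id.isin(universe)]
    term_members = anno.groupby("ko_term")["gene_id"].apply(set)
    records = []
    for cluster, members in assigned.groupby(assigned):
        cluster_genes = set(members.index) & set(universe)
        n = len(cluster_genes)
        if n == 0:
            logger.warning("ko_enrichment: cluster %s empty in universe; skipped", cluster)
            continue
        cluster_rows = []
        for term, genes in term_members.items():
            K = len(genes)
            k = len(genes & cluster_genes)
            if k == 0:
                continue
            cluster_rows.append(
                dict(cluster_id=cluster, ko_term=term, k=k, n=n, K=K, N=N,
                     p_value=hypergeometric_p(k, n, K, N))
            )
        if cluster_rows:
            pvals = [r["p_value"] for r in cluster_rows]
            padj = multipletests(pvals, method="fdr_bh")[1]
            for r, q in zip(cluster_rows, padj):
                r["p_adjusted"] = float(q)
            records.extend(cluster_rows)
    return pd.DataFrame(
        records,
        columns=["cluster_id", "ko_term", "k", "n", "K", "N", "p_value", "p_adjusted"],
    )
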