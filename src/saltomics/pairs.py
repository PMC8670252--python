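"""Antisense-RNA / mRNA pair detection and quadrant classification.

An asRNA is paired with every mRNA it overlaps on the opposite strand of
the same replicon (half-open intervals, >= 1 bp).  Each pair is then
classified by the Pearson correlation of the two per-replicate fold-change
profiles and the direction (induced/repressed) of the members' expression
clusters into four quadrants: asRNA-up/mRNA-down, asRNA-down/mRNA-up,
both-up and both-down.  Classification requires |r| >= 0.65, a cluster
assignment for both members, and significant differential expression of
each member at >= 1 time point.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .clustering import DIRECTION_INDUCED
from .errors import ValidationError
from .expression import ExpressionTable
from .features import FeatureSet, FeatureType
from .transcriptome import STATUS_UNCHANGED

logger = logging.getLogger(__name__)

CATEGORY_AS_UP_M_DOWN = "as_up_m_down"
CATEGORY_AS_DOWN_M_UP = "as_down_m_up"
CATEGORY_BOTH_UP = "both_up"
CATEGORY_BOTH_DOWN = "both_down"
CATEGORY_UNCLASSIFIED = "unclassified"

CATEGORIES = (
    CATEGORY_AS_UP_M_DOWN,
    CATEGORY_AS_DOWN_M_UP,
    CATEGORY_BOTH_UP,
    CATEGORY_BOTH_DOWN,
)


def find_antisense_pairs(features: FeatureSet) -> pd.DataFrame:
    """All (asRNA, mRNA) duos overlapping on opposite strands.

    Returns a DataFrame with columns asrna_id, mrna_id, overlap_bp.  An
    asRNA overlapping several mRNAs yields one row per mRNA.
    """
    rows = []
    for asrna in features.by_type(FeatureType.asRNA):
        opposite = "+" if asrna.strand == "-" else "-"
        for mrna in features.overlapping(asrna.replicon, asrna.start, asrna.end, opposite):
            if mrna.feature_type is not FeatureType.mRNA:
                continue
            rows.append(
                dict(
                    asrna_id=asrna.feature_id,
                    mrna_id=mrna.feature_id,
                    overlap_bp=asrna.overlap_bp(mrna),
                )
            )
    return pd.DataFrame(rows, columns=["asrna_id", "mrna_id", "overlap_bp"])


def pair_correlation(asrna_profile, mrna_profile) -> float:
    """Pearson r of two same-length expression profiles.

    NaN if either vector has zero variance or contains missing values.
    """
    a = np.asarray(asrna_profile, dtype=float)
    b = np.asarray(mrna_profile, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"profile length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValidationError("pair correlation needs >= 3 points")
    if np.isnan(a).any() or np.isnan(b).any():
        return np.nan
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def classify_pairs(
    pairs: pd.DataFrame,
    per_replicate_fc: ExpressionTable,
    assignments: pd.Series,
    directions: tuple[str, ...],
    de_records: pd.DataFrame,
    r_min: float = 0.65,
) -> pd.DataFrame:
    """Classify each antisense pair into a regulation quadrant.

    A pair is *eligible* when both members carry a cluster assignment and
    each is significantly differentially expressed at >= 1 time point.
    Eligible pairs with |r| >= r_min whose correlation sign agrees with the
    members' cluster directions get a quadrant; everything else is
    ``unclassified``.  Pairs missing from the expression table are dropped
    (logged).
    """
    fc = per_replicate_fc.data
    de_hit = (
        de_records[de_records.status != STATUS_UNCHANGED]
        .groupby("feature_id")
        .size()
        .to_dict()
    )
    records = []
    n_dropped = 0
    for row in pairs.itertuples(index=False):
        if row.asrna_id not in fc.index or row.mrna_id not in fc.index:
            n_dropped += 1
            continue
        r = pair_correlation(fc.loc[row.asrna_id].to_numpy(), fc.loc[row.mrna_id].to_numpy())
        as_cluster = assignments.get(row.asrna_id, pd.NA)
        m_cluster = assignments.get(row.mrna_id, pd.NA)
        eligible = (
            as_cluster is not pd.NA
            and m_cluster is not pd.NA
            and row.asrna_id in de_hit
            and row.mrna_id in de_hit
        )
        category = CATEGORY_UNCLASSIFIED
        if eligible and not np.isnan(r) and abs(r) >= r_min:
            as_dir = directions[int(as_cluster)]
            m_dir = directions[int(m_cluster)]
            if as_dir != m_dir and r <= -r_min:
                category = (
                    CATEGORY_AS_UP_M_DOWN if as_dir == DIRECTION_INDUCED else CATEGORY_AS_DOWN_M_UP
                )
            elif as_dir == m_dir and r >= r_min:
                category = (
                    CATEGORY_BOTH_UP if as_dir == DIRECTION_INDUCED else CATEGORY_BOTH_DOWN
                )
        records.append(
            dict(
                asrna_id=row.asrna_id,
                mrna_id=row.mrna_id,
                overlap_bp=row.overlap_bp,
                r=r,
                asrna_cluster=as_cluster,
                mrna_cluster=m_cluster,
                category=category,
                eligible=eligible,
            )
        )
    if n_dropped:
        logger.warning("classify_pairs: %d pairs dropped (missing expression)", n_dropped)
    out = pd.DataFrame(
        records,
        columns=["asrna_id", "mrna_id", "overlap_bp", "r",
                 "asrna_cluster", "mrna_cluster", "category", "eligible"],
    )
    counts = out[out.category != CATEGORY_UNCLASSIFIED].category.value_counts()
    logger.info("pair quadrants: %s", counts.to_dict())
    return out


def pair_summary(pair_records: pd.DataFrame) -> pd.DataFrame:
    """Quadrant counts (the four-panel summary for these inputs)."""
    rows = [
        dict(category=cat, n=int((pair_records.category == cat).sum()))
        for cat in CATEGORIES + (CATEGORY_UNCLASSIFIED,)
    ]
    return pd.DataFrame(rows)
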