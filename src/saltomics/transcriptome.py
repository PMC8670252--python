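"""Transcriptome stage: probe aggregation, fold changes, differential calls.

Inputs are normalized log2 signal intensities from duplicate hybridizations
at 0, 0.5, 2 and 24 h after salt shock.  Differential expression uses the
conventional microarray cut-offs |log2 FC| >= 1 and raw p < 0.05.  The
default p-value shares one pooled within-group variance across all features
(the only test with usable power at n = 2 per group); a per-feature Welch
t-test is available via ``de_test: welch``.  Benjamini-Hochberg adjusted
values are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .errors import ValidationError
from .expression import MEAN, ExperimentDesign, ExpressionTable

logger = logging.getLogger(__name__)

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_UNCHANGED = "unchanged"


@dataclass(frozen=True)
class DERecord:
    feature_id: str
    timepoint: float
    log2fc: float
    p_value: float
    p_adjusted: float
    status: str


def aggregate_probes(probe_table: ExpressionTable, probe_map: pd.DataFrame) -> ExpressionTable:
    """Average all probes of a feature into one row per feature.

    NaN probe values are ignored in the mean; a feature whose probes are all
    missing in any column is dropped (logged).  Probes absent from the map
    are dropped with a count logged.
    """
    if probe_table.value_kind != "signal":
        raise ValidationError("probe aggregation expects a signal table")
    pmap = probe_map.set_index("probe_id")["feature_id"]
    present = probe_table.data.index.intersection(pmap.index)
    if len(present) == 0:
        raise ValidationError("no probe ids shared between table and probe map")
    dropped = len(probe_table.data.index) - len(present)
    if dropped:
        logger.info("aggregate_probes: %d unmapped probes dropped", dropped)
    sub = probe_table.data.loc[present]
    grouped = sub.groupby(pmap.loc[present].values).mean()  # NaN-aware mean
    incomplete = grouped.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "aggregate_probes: %d features dropped (all probes missing in >=1 column)",
            int(incomplete.sum()),
        )
        grouped = grouped.loc[~incomplete]
    grouped.index.name = "feature_id"
    return ExpressionTable(grouped, value_kind="signal")


def compute_fold_changes(
    table: ExpressionTable, design: ExperimentDesign
) -> tuple[ExpressionTable, ExpressionTable]:
    """Log2 fold changes versus the reference time point.

    Returns ``(mean_fc, per_replicate_fc)``: the replicate-mean log2 fold
    change per treated time point, and per-replicate log2 fold changes
    (replicate i at a treated time point minus the reference replicate mean),
    retained for correlation analyses.
    """
    if table.value_kind != "signal":
        raise ValidationError("compute_fold_changes expects a signal table")
    table.validate_against(design)
    ref = design.reference
    ref_mean = table.data.xs(ref, axis=1, level="timepoint").mean(axis=1)
    treated = [tp for tp in table.timepoints if tp != ref]
    mean_cols, rep_cols = {}, {}
    for tp in treated:
        block = table.data.xs(tp, axis=1, level="timepoint")
        mean_cols[(tp, MEAN)] = block.mean(axis=1) - ref_mean
        for rep in block.columns:
            rep_cols[(tp, rep)] = block[rep] - ref_mean
    mean_fc = pd.DataFrame(mean_cols)
    mean_fc.columns = pd.MultiIndex.from_tuples(mean_fc.columns, names=["timepoint", "replicate"])
    per_rep = pd.DataFrame(rep_cols)
    per_rep.columns = pd.MultiIndex.from_tuples(per_rep.columns, names=["timepoint", "replicate"])
    return (
        ExpressionTable(mean_fc, value_kind="log2fc"),
        ExpressionTable(per_rep, value_kind="log2fc"),
    )


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p.

    Both groups constant: p = 1 when the means tie, 0 when they differ
    (the noise-free limit must still call planted changes).
    """
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return np.nan
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


def _pooled_p(treat: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Per-feature two-sided t-test with a common variance shared across features.

    With duplicate hybridizations a per-feature variance estimate has one
    degree of freedom and next to no power; sharing one pooled within-group
    variance across all features (the limiting case of moderated-t variance
    shrinkage, appropriate here because the platform noise is approximately
    homoscedastic on the log2 scale) restores it.  Degrees of freedom are
    summed over features.
    """
    n_feat = treat.shape[0]
    out = np.full(n_feat, np.nan)
    na = (~np.isnan(treat)).sum(axis=1)
    nb = (~np.isnan(ref)).sum(axis=1)
    ok = (na >= 2) & (nb >= 2)
    if not ok.any():
        return out
    with np.errstate(invalid="ignore"):
        va = np.nanvar(treat, axis=1, ddof=1)
        vb = np.nanvar(ref, axis=1, ddof=1)
    ss = (va * (na - 1) + vb * (nb - 1))[ok]
    dfs = (na + nb - 2)[ok]
    df_total = float(dfs.sum())
    s2 = float(ss.sum() / df_total) if df_total > 0 else 0.0
    diff = np.nanmean(treat, axis=1)[ok] - np.nanmean(ref, axis=1)[ok]
    if s2 == 0.0:
        p = np.where(diff == 0.0, 1.0, 0.0)
    else:
        se = np.sqrt(s2 * (1.0 / na[ok] + 1.0 / nb[ok]))
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out[ok] = p
    return out


def call_differential(
    fc_table: ExpressionTable,
    signal_table: ExpressionTable,
    design: ExperimentDesign,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Differential-expression calls per feature per treated time point.

    Status gates on the raw p-value (as conventional for these arrays);
    BH-adjusted p-values across features within a time point are emitted in
    ``p_adjusted``.  Features with < 2 replicates in either group get a
    missing p-value and status ``unchanged``.
    """
    config = config or PipelineConfig()
    if fc_table.value_kind != "log2fc":
        raise ValidationError("call_differential expects a log2fc table")
    common = fc_table.data.index.intersection(signal_table.data.index)
    if len(common) == 0:
        raise ValidationError("fold-change and signal tables share no features")
    ref = design.reference
    ref_block = signal_table.data.loc[common].xs(ref, axis=1, level="timepoint").to_numpy()
    records: list[dict] = []
    warned = False
    for tp in design.treated_timepoints:
        if (tp, MEAN) not in fc_table.data.columns:
            continue
        fc = fc_table.data.loc[common, (tp, MEAN)].to_numpy()
        treat_block = signal_table.data.loc[common].xs(tp, axis=1, level="timepoint").to_numpy()
        if config.de_test == "pooled":
            pvals = _pooled_p(treat_block, ref_block)
        else:
            pvals = np.array(
                [_welch_p(treat_block[i], ref_block[i]) for i in range(len(common))]
            )
        if np.isnan(pvals).any() and not warned:
            logger.warning("call_differential: < 2 replicates for some features; p missing")
            warned = True
        padj = np.full_like(pvals, np.nan)
        ok = ~np.isnan(pvals)
        if ok.any():
            padj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        for i, fid in enumerate(common):
            status = STATUS_UNCHANGED
            if not np.isnan(pvals[i]) and pvals[i] < config.de_alpha and not np.isnan(fc[i]):
                if fc[i] >= config.de_log2fc_min:
                    status = STATUS_UP
                elif fc[i] <= -config.de_log2fc_min:
                    status = STATUS_DOWN
            records.append(
                dict(feature_id=fid, timepoint=tp, log2fc=fc[i],
                     p_value=pvals[i], p_adjusted=padj[i], status=status)
            )
    out = pd.DataFrame(records)
    for tp in design.treated_timepoints:
        sub = out[out.timepoint == tp]
        logger.info(
            "DE at %gh: %d up / %d down of %d features",
            tp, (sub.status == STATUS_UP).sum(), (sub.status == STATUS_DOWN).sum(), len(sub),
        )
    return out


def prefilter_for_clustering(
    fc_table: ExpressionTable, threshold: float = 1.0
) -> ExpressionTable:
    """Keep features whose max |log2 FC| over time points is >= threshold."""
    if fc_table.value_kind != "log2fc":
        raise ValidationError("prefilter expects a log2fc table")
    keep = fc_table.data.abs().max(axis=1) >= threshold
    logger.info("prefilter_for_clustering: %d of %d features retained",
                int(keep.sum()), len(keep))
    return ExpressionTable(fc_table.data.loc[keep], value_kind="log2fc")
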