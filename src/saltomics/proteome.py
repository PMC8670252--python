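"""Proteome stage: Hi3 absolute quantification, identification filtering,
fraction-weighted fold changes and differential-abundance calls.

Protein amounts are fmol on column, measured in a total extract plus three
subcellular fractions (soluble, membrane-enriched, debris) for control and
salt-acclimated cultures.  The fraction-weighted fold change sums soluble +
membrane + debris/10 amounts per condition before forming the salt/control
ratio, which buffers proteins that merely redistribute between fractions;
the final combined fold change averages the weighted and the total-extract
ratios (falling back to whichever is available).  Significance requires a
combined fold change of >= 1.5 (either direction) and ANOVA p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .errors import QuantificationError, ValidationError

logger = logging.getLogger(__name__)

FRACTIONS = ("total", "soluble", "membrane", "debris")
WEIGHTED_FRACTIONS = ("soluble", "membrane", "debris")
CONDITIONS = ("control", "salt")


def hi3_quantify(
    peptides: pd.DataFrame,
    standard_protein_id: str,
    standard_fmol: float = 40.0,
) -> pd.DataFrame:
    """Hi3 absolute quantification from peptide intensities.

    Per protein (and per any extra grouping columns such as condition /
    replicate), the signal is the mean of its three most intense peptides;
    the amount is ``signal / standard_signal * standard_fmol`` where the
    standard is the spiked protein of known amount.  Proteins with < 3
    peptides use all available and are flagged.

    Parameters
    ----------
    peptides : DataFrame with columns ``protein_id``, ``intensity`` and
        optionally ``condition`` / ``replicate`` grouping columns.
    """
    required = {"protein_id", "intensity"}
    if not required <= set(peptides.columns):
        raise ValidationError(f"peptide table needs columns {sorted(required)}")
    group_cols = [c for c in ("condition", "replicate") if c in peptides.columns]

    def top3_mean(g: pd.DataFrame) -> pd.Series:
        vals = np.sort(g["intensity"].to_numpy())[::-1]
        return pd.Series(
            {"signal": float(vals[: min(3, len(vals))].mean()),
             "n_peptides": len(vals)}
        )

    grouped = (
        peptides.groupby(["protein_id"] + group_cols, sort=True)
        .apply(top3_mean, include_groups=False)
        .reset_index()
    )
    out_rows = []
    sample_groups = [((), grouped)] if not group_cols else list(grouped.groupby(group_cols))
    for key, sub in sample_groups:
        std = sub[sub.protein_id == standard_protein_id]
        if std.empty:
            raise QuantificationError(
                f"standard protein {standard_protein_id!r} absent from sample {key}"
            )
        if int(std.n_peptides.iloc[0]) < 3:
            raise QuantificationError(
                f"standard protein {standard_protein_id!r} has < 3 peptides in sample {key}"
            )
        std_signal = float(std.signal.iloc[0])
        sub = sub.copy()
        sub["amount_fmol"] = sub.signal / std_signal * standard_fmol
        sub["low_peptide_flag"] = sub.n_peptides < 3
        out_rows.append(sub)
    out = pd.concat(out_rows, ignore_index=True)
    return out[["protein_id"] + group_cols + ["amount_fmol", "n_peptides", "low_peptide_flag"]]


def filter_identifications(
    quants: pd.DataFrame,
    min_peptides: int = 2,
    allow_list: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Keep proteins identified by >= 2 unique peptides in a fraction.

    The filter applies per fraction: a protein may survive in one fraction
    and be dropped in another.  Named single-peptide proteins on the
    allow-list are re-admitted with ``allow_listed=True``.
    """
    if "n_unique_peptides" not in quants.columns:
        raise ValidationError("quant table lacks n_unique_peptides")
    ok = quants.n_unique_peptides >= min_peptides
    allowed = quants.protein_id.isin(allow_list)
    out = quants[ok | allowed].copy()
    out["allow_listed"] = (~ok & allowed)[ok | allowed]
    n_removed = len(quants) - len(out)
    if n_removed:
        logger.info("filter_identifications: %d records removed", n_removed)
    return out


def weighted_fraction_fc(
    salt: dict[str, float], control: dict[str, float], debris_divisor: float = 10.0
) -> float:
    """Fraction-weighted fold change for one protein.

    ``S_cond = soluble + membrane + debris / 10``; a fraction missing in a
    condition contributes 0 (the protein was not detected there).  Returns
    NaN when the control sum is zero/undefined.
    """

    def weighted_sum(amounts: dict[str, float]) -> float:
        total = 0.0
        for frac in WEIGHTED_FRACTIONS:
            v = amounts.get(frac)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            total += v / debris_divisor if frac == "debris" else v
        return total

    s_salt, s_control = weighted_sum(salt), weighted_sum(control)
    if s_control == 0:
        return np.nan
    return s_salt / s_control


def combined_fold_change(fc_weighted: float, fc_total: float,
                         geometric: bool = False) -> float:
    """Final combined fold change: mean of the weighted and total-extract
    ratios, or whichever is available alone."""
    w_ok = fc_weighted is not None and not np.isnan(fc_weighted)
    t_ok = fc_total is not None and not np.isnan(fc_total)
    if w_ok and t_ok:
        if geometric:
            return float(np.sqrt(fc_weighted * fc_total))
        return (fc_weighted + fc_total) / 2.0
    if w_ok:
        return float(fc_weighted)
    if t_ok:
        return float(fc_total)
    return np.nan


def replicate_means(quants: pd.DataFrame) -> pd.DataFrame:
    """Mean amount per (protein, fraction, condition) over replicates."""
    return (
        quants.groupby(["protein_id", "fraction", "condition"], sort=True)["amount_fmol"]
        .mean()
        .reset_index()
    )


def _anova_p(a: np.ndarray, b: np.ndarray, log_scale: bool) -> float:
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return np.nan
    if log_scale:
        if (a <= 0).any() or (b <= 0).any():
            return np.nan
        a, b = np.log2(a), np.log2(b)
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0
    p = stats.f_oneway(a, b).pvalue
    return 1.0 if np.isnan(p) else float(p)


def protein_fold_changes(
    quants: pd.DataFrame, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Full fold-change table from a long-format quant table.

    *quants* columns: protein_id, fraction, condition, replicate,
    amount_fmol, n_unique_peptides.  Returns one row per protein with
    fc_total, fc_weighted, fc_combined, p_value, significant.
    """
    config = config or PipelineConfig()
    means = replicate_means(quants)
    pivot = means.pivot_table(
        index="protein_id", columns=["fraction", "condition"],
        values="amount_fmol", aggfunc="first",
    )
    records = []
    n_excluded = 0
    for pid in pivot.index:
        row = pivot.loc[pid]

        def amount(frac: str, cond: str) -> float:
            return float(row.get((frac, cond), np.nan))

        t_c, t_s = amount("total", "control"), amount("total", "salt")
        fc_total = t_s / t_c if t_c and not np.isnan(t_c) and not np.isnan(t_s) else np.nan
        fc_weighted = weighted_fraction_fc(
            {f: amount(f, "salt") for f in WEIGHTED_FRACTIONS},
            {f: amount(f, "control") for f in WEIGHTED_FRACTIONS},
            debris_divisor=config.debris_divisor,
        )
        fc_combined = combined_fold_change(
            fc_weighted, fc_total, geometric=config.combined_fc_geometric
        )
        if np.isnan(fc_combined):
            n_excluded += 1
            continue
        test = quants[(quants.protein_id == pid) & (quants.fraction == config.protein_test_fraction)]
        p = _anova_p(
            test[test.condition == "salt"].amount_fmol.to_numpy(dtype=float),
            test[test.condition == "control"].amount_fmol.to_numpy(dtype=float),
            log_scale=config.protein_test_log_scale,
        )
        significant = bool(
            not np.isnan(p)
            and p < config.protein_alpha
            and (fc_combined >= config.protein_fc_min or fc_combined <= 1.0 / config.protein_fc_min)
        )
        records.append(
            dict(protein_id=pid, fc_total=fc_total, fc_weighted=fc_weighted,
                 fc_combined=fc_combined, p_value=p, significant=significant)
        )
    if n_excluded:
        logger.info("protein_fold_changes: %d proteins excluded (no fold change defined)",
                    n_excluded)
    out = pd.DataFrame(records)
    if len(out):
        up = int(((out.fc_combined >= config.protein_fc_min) & out.significant).sum())
        down = int(((out.fc_combined <= 1 / config.protein_fc_min) & out.significant).sum())
        logger.info("proteome DE: %d up / %d down of %d quantified", up, down, len(out))
    return out


def call_differential_proteins(
    quants: pd.DataFrame, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Alias for :func:`protein_fold_changes` emphasizing the DE-calling role."""
    return protein_fold_changes(quants, config=config)
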