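"""Metabolome stage: internal-standard normalization and fold changes.

Every LC-MS/MS sample carries a spiked carnitine internal standard; dividing
each metabolite intensity by the standard intensity of the same sample
cancels per-sample injection/ionization factors.  Fold changes are ratios
of replicate means, salt over control, with the control defined as 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("metabolite_id", "condition", "replicate", "intensity",
                    "standard_intensity")


def normalize_to_standard(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-sample normalization: intensity / internal-standard intensity.

    Samples with a zero or missing standard intensity are excluded with a
    warning; a metabolite with no valid sample left is dropped (logged).
    """
    missing = set(REQUIRED_COLUMNS) - set(measurements.columns)
    if missing:
        raise ValidationError(f"metabolite table lacks columns {sorted(missing)}")
    df = measurements.copy()
    valid = df.standard_intensity.notna() & (df.standard_intensity > 0)
    if (~valid).any():
        logger.warning(
            "normalize_to_standard: %d samples excluded (zero/missing internal standard)",
            int((~valid).sum()),
        )
    df = df[valid].copy()
    df["normalized"] = df.intensity / df.standard_intensity
    lost = set(measurements.metabolite_id) - set(df.metabolite_id)
    if lost:
        logger.warning("normalize_to_standard: metabolites dropped entirely: %s",
                       sorted(lost))
    return df


def metabolite_fold_changes(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-metabolite fold change = mean(salt) / mean(control) of the
    normalized abundances; the control level is reported as exactly 1."""
    if "normalized" not in normalized.columns:
        raise ValidationError("input lacks a 'normalized' column; run normalize_to_standard")
    records = []
    for mid, sub in normalized.groupby("metabolite_id", sort=True):
        control = sub[sub.condition == "control"].normalized.to_numpy(dtype=float)
        salt = sub[sub.condition == "salt"].normalized.to_numpy(dtype=float)
        if len(control) == 0 or len(salt) == 0:
            logger.warning("metabolite %s: missing condition; skipped", mid)
            continue
        c_mean = control.mean()
        fc = salt.mean() / c_mean if c_mean != 0 else np.nan
        records.append(
            dict(
                metabolite_id=mid,
                control_level=1.0,
                fold_change=fc,
                control_sd=float(np.std(control / c_mean, ddof=1)) if len(control) > 1 and c_mean else np.nan,
                salt_sd=float(np.std(salt / c_mean, ddof=1)) if len(salt) > 1 and c_mean else np.nan,
                n_control=len(control),
                n_salt=len(salt),
            )
        )
    return pd.DataFrame(records)
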