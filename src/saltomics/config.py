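"""Flat key/value pipeline configuration.

Every default equals the published analysis choice (cut-offs, correlation
threshold, membership gates, fraction weighting, spiked-standard amount), so
a run with no config file reproduces the published decision rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import yaml

from .errors import ConfigurationError


@dataclass(frozen=True)
class PipelineConfig:
    # transcriptome differential expression
    de_log2fc_min: float = 1.0       # |log2 FC| cut-off
    de_alpha: float = 0.05           # raw p-value cut-off
    de_test: str = "pooled"          # "pooled" (variance shared across features) | "welch"
    # clustering
    prefilter_log2fc_min: float = 1.0
    membership_min: float = 0.5
    combined_membership_min: float = 0.6
    c_min: int = 2
    c_max: int = 12
    fcm_tol: float = 1e-9
    fcm_max_iter: int = 1000
    fcm_restarts: int = 10
    # asRNA:mRNA pairs
    r_min: float = 0.65
    # proteome
    min_peptides: int = 2
    hi3_standard_fmol: float = 40.0
    debris_divisor: float = 10.0
    protein_fc_min: float = 1.5
    protein_alpha: float = 0.05
    protein_test_fraction: str = "total"
    protein_test_log_scale: bool = True
    combined_fc_geometric: bool = False  # published rule: arithmetic mean of linear ratios
    single_peptide_allow_list: tuple[str, ...] = ()
    # integration
    similar_log2_max: float = math.log2(1.5)
    consensus_transcript_log2_min: float = 0.58   # strict >, 1.5-fold
    consensus_protein_log2_min: float = 0.38      # strict >, 1.3-fold
    # pair correlation source: per-replicate fold changes (6 points)
    pair_corr_per_replicate: bool = True

    def validate(self) -> None:
        if not (0 < self.de_alpha < 1) or not (0 < self.protein_alpha < 1):
            raise ConfigurationError("alpha thresholds must lie in (0, 1)")
        if self.r_min < 0 or self.r_min > 1:
            raise ConfigurationError("r_min must lie in [0, 1]")
        if self.c_min < 2 or self.c_max < self.c_min:
            raise ConfigurationError("cluster-count range invalid")
        if self.protein_fc_min <= 1:
            raise ConfigurationError("protein_fc_min must exceed 1")
        if self.de_test not in ("pooled", "welch"):
            raise ConfigurationError("de_test must be 'pooled' or 'welch'")


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a config from defaults, an optional flat YAML file, and overrides."""
    values: dict = {}
    if path is not None:
        with open(path, "rt", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigurationError(f"config {path} is not a flat key/value document")
        values.update(doc)
    values.update(overrides)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "single_peptide_allow_list" in values and values["single_peptide_allow_list"] is not None:
        values["single_peptide_allow_list"] = tuple(values["single_peptide_allow_list"])
    cfg = PipelineConfig(**values)
    cfg.validate()
    return cfg
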