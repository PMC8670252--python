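"""Synthetic multi-omics data with known ground truth.

The generator emulates the structure of the salt-shock study inputs so every
downstream stage has a recovery test without downloading the deposited
datasets: a single pseudo-replicon annotated with mRNAs, overlapping
antisense RNAs and trans-encoded sRNAs; a duplicate-hybridization 4-point
transcriptome built from four temporal archetypes (transient up/down peaking
at 0.5 h or 2 h) plus flat profiles; a four-fraction proteome (total,
soluble, membrane, debris) with 4 biological replicates (3 for pooled
debris), lognormal noise and planted fold changes; and an LC-MS metabolome
whose per-sample injection factor is carried by a carnitine-like internal
standard so that normalization cancels it.

All randomness flows from a single integer seed; identical configurations
produce bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression import ExperimentDesign, ExpressionTable, write_expression
from .features import FeatureSet, FeatureType, GenomicFeature, write_annotation
from .io import write_table

logger = logging.getLogger(__name__)

ARCHETYPES = ("cluster1", "cluster2", "cluster3", "cluster4")
FLAT = "flat"

#: mirror partner of each archetype under sign flip
_MIRROR = {"cluster1": "cluster3", "cluster3": "cluster1",
           "cluster2": "cluster4", "cluster4": "cluster2"}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the stated synthetic world.

    Transcriptome defaults mirror the study design (duplicate hybridizations
    at 0, 0.5, 2, 24 h); the proteome uses four biological replicates per
    condition (three for the pooled debris fraction); archetype amplitude
    and noise levels are chosen for testability, not biological fidelity.
    """

    # annotation
    n_mrna: int = 600
    n_asrna: int = 200
    n_srna: int = 60
    n_pairs_inverse: int = 50
    n_pairs_coregulated: int = 50
    replicon: str = "chr_sim"
    replicon_length: int = 200_000
    # transcriptome
    timepoints: tuple[float, ...] = (0.0, 0.5, 2.0, 24.0)
    transcriptome_replicates: int = 2
    amplitude: float = 2.0          # log2 units
    baseline: float = 10.0          # log2 signal floor
    noise_sd: float = 0.3           # additive Gaussian, log2 scale
    flat_fraction: float = 0.2
    archetype_assignment: dict | None = None
    # proteome
    n_proteins: int = 500
    proteome_replicates: int = 4
    debris_replicates: int = 3
    proteome_cv: float = 0.1        # lognormal, linear fmol scale
    protein_up_fraction: float = 0.1
    protein_down_fraction: float = 0.1
    protein_fc_up: float = 2.0
    protein_fc_down: float = 0.5
    fraction_shares: tuple[float, float, float] = (0.5, 0.4, 0.1)  # soluble, membrane, debris
    redistributed_fraction: float = 0.1  # proteins swapping soluble<->membrane at constant total
    emit_peptides: bool = True
    hi3_standard_id: str = "HI3_STD"
    hi3_standard_fmol: float = 40.0
    # metabolome
    n_metabolites: int = 12
    metabolite_fc: dict = field(
        default_factory=lambda: {"met_gg": 20.0, "met_glutamate": 2.0,
                                 "met_3pga": 0.33, "met_2og": 0.5}
    )
    metabolome_replicates: int = 3
    metabolite_cv: float = 0.1
    injection_sigma: float = 0.3    # lognormal sigma of per-sample injection factor
    # misc
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_mrna, self.n_asrna, self.n_srna,
                  self.n_pairs_inverse, self.n_pairs_coregulated,
                  self.n_proteins, self.n_metabolites)
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be >= 0")
        if self.noise_sd < 0 or self.proteome_cv < 0 or self.metabolite_cv < 0:
            raise ConfigurationError("noise parameters must be >= 0")
        if self.n_pairs_inverse + self.n_pairs_coregulated > self.n_asrna:
            raise ConfigurationError("more planted pairs than asRNAs")
        if self.n_pairs_inverse + self.n_pairs_coregulated > self.n_mrna:
            raise ConfigurationError("more planted pairs than mRNAs")
        if self.n_proteins > self.n_mrna:
            raise ConfigurationError("n_proteins cannot exceed n_mrna (proteins map to genes)")
        if abs(sum(self.fraction_shares) - 1.0) > 1e-9:
            raise ConfigurationError("fraction shares must sum to 1")

    def design(self) -> ExperimentDesign:
        return ExperimentDesign(self.timepoints, self.transcriptome_replicates)


@dataclass
class GroundTruth:
    """Planted truth for recovery tests."""

    cluster_labels: pd.Series | None = None          # feature_id -> archetype label
    pairs: pd.DataFrame | None = None                # asrna_id, mrna_id, category
    protein_fc: pd.Series | None = None              # protein_id -> linear fold change
    metabolite_fc: pd.Series | None = None           # metabolite_id -> linear fold change


def archetype_profile(label: str, timepoints: tuple[float, ...],
                      amplitude: float = 2.0) -> np.ndarray:
    """Piecewise temporal archetype over (0, 0.5, 2, 24) h in log2 units."""
    shapes = {
        "cluster1": np.array([0.0, 1.0, 0.5, 0.0]),    # transient up, peak 0.5 h
        "cluster2": np.array([0.0, 0.5, 1.0, 0.25]),   # up, peak 2 h
        FLAT: np.zeros(4),
    }
    shapes["cluster3"] = -shapes["cluster1"]
    shapes["cluster4"] = -shapes["cluster2"]
    if label not in shapes:
        raise ConfigurationError(f"unknown archetype {label!r}")
    if len(timepoints) != 4:
        raise ConfigurationError("archetypes are defined over exactly 4 timepoints")
    return amplitude * shapes[label]


def _mrna_id(i: int) -> str:
    return f"sml{i:04d}"


def simulate_annotation(config: SimulationConfig) -> FeatureSet:
    """Deterministic feature layout on one pseudo-replicon.

    The replicon is divided into equal slots; slot i hosts mRNA i on the +
    strand, the paired asRNA (slots 0..n_pairs-1) inside the mRNA on the -
    strand, and non-pair asRNAs / sRNAs in the inter-genic part of the slot
    so they never overlap an opposite-strand mRNA.
    """
    config.validate()
    n_pairs = config.n_pairs_inverse + config.n_pairs_coregulated
    n_free_asrna = config.n_asrna - n_pairs
    n_slots = max(config.n_mrna, n_free_asrna, config.n_srna, 1)
    slot = config.replicon_length // n_slots
    if slot < 200:
        raise ConfigurationError(
            f"infeasible packing: {n_slots} slots on a {config.replicon_length} bp "
            f"replicon leaves only {slot} bp per slot (need >= 200)"
        )
    features: list[GenomicFeature] = []
    for i in range(config.n_mrna):
        base = i * slot
        features.append(
            GenomicFeature(_mrna_id(i), FeatureType.mRNA, config.replicon,
                           base, base + int(slot * 0.45), "+", gene_id=_mrna_id(i))
        )
    for p in range(n_pairs):
        base = p * slot
        features.append(
            GenomicFeature(f"as_{_mrna_id(p)}", FeatureType.asRNA, config.replicon,
                           base + int(slot * 0.10), base + int(slot * 0.35), "-",
                           gene_id=_mrna_id(p))
        )
    for j in range(n_free_asrna):
        base = j * slot
        features.append(
            GenomicFeature(f"asna{j:04d}", FeatureType.asRNA, config.replicon,
                           base + int(slot * 0.55), base + int(slot * 0.70), "-")
        )
    for k in range(config.n_srna):
        base = k * slot
        features.append(
            GenomicFeature(f"ncr{k:04d}", FeatureType.sRNA, config.replicon,
                           base + int(slot * 0.75), base + int(slot * 0.85), "+")
        )
    return FeatureSet(features)


def _assign_archetypes(features: FeatureSet, config: SimulationConfig,
                       rng: np.random.Generator) -> tuple[pd.Series, pd.DataFrame]:
    """Archetype label per feature plus the planted pair table.

    Inverse pairs get mirrored mRNA/asRNA archetypes, co-regulated pairs
    share the archetype; everything else follows the configured assignment
    or a random draw with the configured flat fraction.
    """
    labels: dict[str, str] = {}
    pair_rows = []
    n_inv = config.n_pairs_inverse
    for p in range(n_inv + config.n_pairs_coregulated):
        mrna = _mrna_id(p)
        asrna = f"as_{mrna}"
        m_label = ARCHETYPES[int(rng.integers(len(ARCHETYPES)))]
        inverse = p < n_inv
        labels[mrna] = m_label
        labels[asrna] = _MIRROR[m_label] if inverse else m_label
        pair_rows.append(dict(asrna_id=asrna, mrna_id=mrna,
                              category="inverse" if inverse else "coregulated"))
    manual = config.archetype_assignment or {}
    for f in features:
        if f.feature_id in labels:
            continue
        if f.feature_id in manual:
            labels[f.feature_id] = manual[f.feature_id]
        elif rng.random() < config.flat_fraction:
            labels[f.feature_id] = FLAT
        else:
            labels[f.feature_id] = ARCHETYPES[int(rng.integers(len(ARCHETYPES)))]
    series = pd.Series({f.feature_id: labels[f.feature_id] for f in features},
                       name="archetype")
    pairs = pd.DataFrame(pair_rows, columns=["asrna_id", "mrna_id", "category"])
    return series, pairs


def simulate_transcriptome(
    features: FeatureSet, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionTable, GroundTruth]:
    """Replicated log2 signal table: baseline + archetype profile + noise."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    labels, pairs = _assign_archetypes(features, config, rng)
    design = config.design()
    ids = list(labels.index)
    profiles = np.stack(
        [archetype_profile(labels[fid], config.timepoints, config.amplitude) for fid in ids]
    )
    n_rep = config.transcriptome_replicates
    expected = np.repeat(profiles, n_rep, axis=1) + config.baseline
    if config.noise_sd > 0:
        expected = expected + rng.normal(0.0, config.noise_sd, size=expected.shape)
    table = pd.DataFrame(expected, index=pd.Index(ids, name="feature_id"),
                         columns=design.columns())
    truth = GroundTruth(cluster_labels=labels, pairs=pairs)
    return ExpressionTable(table, value_kind="signal"), truth


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_proteome(
    config: SimulationConfig, rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Long-format fmol quant table over four fractions and two conditions.

    Salt amounts are control x planted fold change; a configured subset of
    proteins additionally swaps abundance between the soluble and membrane
    fractions at constant total, emulating complexes that pellet differently
    under salt.  Returns ``(quants, truth)``; ``quants`` also carries a
    peptide attribute when ``emit_peptides`` is set (see
    :func:`simulate_peptides`).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    ids = [_mrna_id(i) for i in range(config.n_proteins)]
    n = config.n_proteins
    fc = np.ones(n)
    n_up = int(round(config.protein_up_fraction * n))
    n_down = int(round(config.protein_down_fraction * n))
    fc[:n_up] = config.protein_fc_up
    fc[n_up:n_up + n_down] = config.protein_fc_down
    totals = rng.lognormal(mean=np.log(50.0), sigma=0.5, size=n)
    sol, mem, deb = config.fraction_shares
    shares_control = np.tile(np.array([sol, mem, deb]), (n, 1))
    shares_salt = shares_control.copy()
    n_redist = int(round(config.redistributed_fraction * n))
    # redistributed proteins move half their soluble share into the membrane
    redist_idx = np.arange(n - n_redist, n)
    shares_salt[redist_idx, 0] = shares_control[redist_idx, 0] * 0.5
    shares_salt[redist_idx, 1] = (
        shares_control[redist_idx, 1] + shares_control[redist_idx, 0] * 0.5
    )
    rows = []
    for cond, cond_fc, shares in (("control", 1.0, shares_control),
                                  ("salt", fc, shares_salt)):
        cond_total = totals * cond_fc
        for fi, fraction in enumerate(("soluble", "membrane", "debris")):
            n_rep = config.debris_replicates if fraction == "debris" else config.proteome_replicates
            expected = cond_total * shares[:, fi]
            noise = _lognormal_noise(rng, config.proteome_cv, (n, n_rep))
            for rep in range(1, n_rep + 1):
                rows.append(pd.DataFrame(dict(
                    protein_id=ids, fraction=fraction, condition=cond, replicate=rep,
                    amount_fmol=expected * noise[:, rep - 1],
                )))
        noise = _lognormal_noise(rng, config.proteome_cv, (n, config.proteome_replicates))
        for rep in range(1, config.proteome_replicates + 1):
            rows.append(pd.DataFrame(dict(
                protein_id=ids, fraction="total", condition=cond, replicate=rep,
                amount_fmol=cond_total * noise[:, rep - 1],
            )))
    quants = pd.concat(rows, ignore_index=True)
    n_pep = rng.integers(2, 30, size=n)
    pep_map = dict(zip(ids, n_pep))
    quants["n_unique_peptides"] = quants.protein_id.map(pep_map)
    truth = GroundTruth(
        protein_fc=pd.Series(fc, index=pd.Index(ids, name="protein_id"), name="fold_change")
    )
    return quants, truth


#: per-protein relative peptide intensities; the top-3 mean is exactly 1 so
#: Hi3 recovers planted fmol without bias
_PEPTIDE_WEIGHTS = np.array([1.2, 1.0, 0.8, 0.5, 0.3])


def simulate_peptides(
    quants: pd.DataFrame, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Peptide intensity table for the total extract, with a spiked standard.

    Each protein yields five peptides whose intensities are proportional to
    its amount; the spiked standard appears at the configured fmol in every
    sample.  The proportionality constant per sample is arbitrary (Hi3 is
    scale-invariant).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    total = quants[quants.fraction == "total"]
    rows = []
    for (cond, rep), sub in total.groupby(["condition", "replicate"], sort=True):
        scale = float(rng.uniform(50.0, 150.0))  # per-sample instrument response
        amounts = np.concatenate([sub.amount_fmol.to_numpy(), [config.hi3_standard_fmol]])
        pids = list(sub.protein_id) + [config.hi3_standard_id]
        intens = np.outer(amounts, _PEPTIDE_WEIGHTS) * scale
        for i, pid in enumerate(pids):
            for j in range(len(_PEPTIDE_WEIGHTS)):
                rows.append((pid, cond, rep, f"pep{j + 1}", intens[i, j]))
    return pd.DataFrame(rows, columns=["protein_id", "condition", "replicate",
                                       "peptide_id", "intensity"])


def simulate_metabolome(
    config: SimulationConfig, rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Metabolite intensities with a per-sample internal-standard channel.

    Raw intensities carry a per-sample injection factor; the internal
    standard of the same sample carries the identical factor so that
    normalization cancels it exactly.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    planted = dict(config.metabolite_fc)
    ids = list(planted)
    for i in range(len(ids), config.n_metabolites):
        mid = f"met_flat{i:02d}"
        ids.append(mid)
        planted[mid] = 1.0
    abundance = {mid: float(rng.uniform(100.0, 1000.0)) for mid in ids}
    standard_base = 500.0
    rows = []
    for cond in ("control", "salt"):
        for rep in range(1, config.metabolome_replicates + 1):
            injection = float(rng.lognormal(0.0, config.injection_sigma)) \
                if config.injection_sigma > 0 else 1.0
            noise = _lognormal_noise(rng, config.metabolite_cv, len(ids))
            for i, mid in enumerate(ids):
                level = abundance[mid] * (planted[mid] if cond == "salt" else 1.0)
                rows.append(dict(
                    metabolite_id=mid, condition=cond, replicate=rep,
                    intensity=level * injection * noise[i],
                    standard_intensity=standard_base * injection,
                ))
    truth = GroundTruth(metabolite_fc=pd.Series(planted, name="fold_change"))
    return pd.DataFrame(rows), truth


def simulate_ko_annotation(
    truth_labels: pd.Series, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """KO-term table with one planted enriched term per archetype cluster.

    All mRNAs of archetype k (and only those) share the term ``KO:Ck``;
    every gene additionally draws two background terms, so the planted term
    dominates its cluster's enrichment ranking by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    genes = [g for g in truth_labels.index if g.startswith("sml")]
    background = [f"KO:B{i:02d}" for i in range(1, 16)]
    rows = []
    for g in genes:
        label = truth_labels[g]
        if label in ARCHETYPES:
            rows.append(dict(gene_id=g, ko_term=f"KO:C{label[-1]}"))
        for term in rng.choice(background, size=2, replace=False):
            rows.append(dict(gene_id=g, ko_term=str(term)))
    return pd.DataFrame(rows, columns=["gene_id", "ko_term"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_all(config: SimulationConfig, out_dir) -> pd.DataFrame:
    """Write every synthetic input plus ground truth; return the manifest.

    Files: annotation.gff3, transcriptome_signals.tsv, proteome_quants.tsv,
    peptides.tsv (optional), metabolome.tsv, ko_annotation.tsv, two extra
    transcriptome log2fc tables for the consensus filter, and the truth
    tables.  The manifest is a TSV of (role, path, sha256).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    features = simulate_annotation(config)
    expr, truth_t = simulate_transcriptome(features, config, rng)
    quants, truth_p = simulate_proteome(config, rng)
    metab, truth_m = simulate_metabolome(config, rng)
    ko = simulate_ko_annotation(truth_t.cluster_labels, config, rng)

    written: dict[str, Path] = {}

    def emit(role: str, name: str, writer) -> None:
        path = out / name
        writer(path)
        written[role] = path

    emit("annotation", "annotation.gff3", lambda p: write_annotation(features, p))
    emit("transcriptome", "transcriptome_signals.tsv", lambda p: write_expression(expr, p))
    emit("proteome", "proteome_quants.tsv", lambda p: write_table(quants, p, float_digits=10))
    if config.emit_peptides:
        peptides = simulate_peptides(quants, config, rng)
        emit("peptides", "peptides.tsv", lambda p: write_table(peptides, p, float_digits=10))
    emit("metabolome", "metabolome.tsv", lambda p: write_table(metab, p, float_digits=10))
    emit("ko_annotation", "ko_annotation.tsv", lambda p: write_table(ko, p))

    # external-style transcriptome datasets: true 24 h log2 FC + small noise
    labels = truth_t.cluster_labels
    genes = [g for g in labels.index if g.startswith("sml")]
    true_24h = pd.Series(
        {g: archetype_profile(labels[g], config.timepoints, config.amplitude)[-1]
         for g in genes}
    )
    for k in (1, 2):
        noisy = true_24h + rng.normal(0.0, 0.2, size=len(true_24h))
        df = pd.DataFrame({"gene_id": true_24h.index, "log2fc": noisy.to_numpy()})
        emit(f"extra_transcriptome_{k}", f"extra_transcriptome_{k}.tsv",
             lambda p, df=df: write_table(df, p, float_digits=10))

    emit("truth_clusters", "truth_clusters.tsv",
         lambda p: truth_t.cluster_labels.rename_axis("feature_id").reset_index()
         .to_csv(p, sep="\t", index=False))
    emit("truth_pairs", "truth_pairs.tsv", lambda p: write_table(truth_t.pairs, p))
    emit("truth_proteins", "truth_proteins.tsv",
         lambda p: truth_p.protein_fc.rename_axis("protein_id").reset_index()
         .to_csv(p, sep="\t", index=False))
    emit("truth_metabolites", "truth_metabolites.tsv",
         lambda p: truth_m.metabolite_fc.rename_axis("metabolite_id").reset_index()
         .to_csv(p, sep="\t", index=False))

    manifest = pd.DataFrame(
        [dict(role=role, path=path.name, sha256=_sha256(path))
         for role, path in written.items()]
    )
    manifest_path = out / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    logger.info("simulate_all: wrote %d files to %s", len(written) + 1, out)
    return manifest
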