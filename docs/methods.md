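# Methods

This note documents the models, decision rules, defaults and numerical
choices implemented in `saltomics`, what the synthetic-data generator does
and does not emulate, and the known limitations. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Experiment model

The pipeline assumes the salt-shock design: log2 signal intensities for
every transcript feature (mRNA, cis-antisense RNA, trans-encoded sRNA,
5'UTR, internal-TSS transcript) at 0 (reference), 0.5, 2 and 24 h, with
two hybridizations per time point; protein amounts in fmol on column for a
total extract plus soluble, membrane-enriched and debris fractions
(control vs salt-acclimated, 4 biological replicates, 3 for the pooled
debris); and metabolite intensities with a per-sample internal-standard
channel (3 replicates per condition). Coordinates are 0-based half-open
internally; GFF3 conversion happens only at the I/O boundary. Missing
values stay missing — no statistic imputes silently.

## Transcriptome

Probe-level tables are averaged to one row per feature (NaN-aware mean; a
feature is dropped if all probes are missing in any column). Log2 fold
changes are treated-replicate means minus the reference-replicate mean;
per-replicate fold changes (each treated replicate minus the reference
mean) are retained because the pair correlation uses the individual
measurements.

Differential expression gates on |log2 FC| ≥ 1 and raw p < 0.05
(BH-adjusted values are always emitted alongside). The default test shares
one pooled within-group variance across all features within a time point
and sums the degrees of freedom. Rationale: with two replicates a
per-feature variance estimate has ~1 df and essentially no power at the
stated 0.05 level; sharing variance across features is the limiting case
of moderated-t shrinkage and is appropriate because microarray noise is
approximately homoscedastic on the log2 scale. A per-feature Welch t-test
is available via `de_test: welch` for data where that assumption fails.
Groups that are exactly constant yield p = 1 on a tie and p = 0 on a
non-zero difference, so the noise-free limit still calls planted changes.

## Clustering

Only features with max |log2 FC| ≥ 1 over the time course enter
clustering. The clustered vector is the fold-change profile over all four
time points with the reference pinned at 0; after row standardization
(mean 0, population sd 1) this is identical to standardizing the 4-point
signal profile, and keeps D = 4 for the fuzzifier estimate
m(N, D) = 1 + (1418/N + 22.05)·D⁻² + (12.33/N + 0.243)·D^(−0.0406·ln N − 0.1134)
(m(3831, 4) = 2.53). Constant and incomplete rows are excluded with a
warning.

Fuzzy c-means uses Euclidean distance, random-row centroid initialization,
10 restarts keeping the best objective, convergence at max |Δu| < 1e-9 or
1000 iterations, and the singularity rule that a point coinciding with a
centroid takes membership 1 there. A cluster is labelled *induced* when
its centroid entry of largest magnitude is positive, else *repressed*.

Cluster-count selection records the minimum pairwise centroid distance for
each candidate c in 2..12. The curve stays high while c does not exceed
the number of genuine groups and collapses once a group is split, so the
elbow is the left endpoint of the largest relative drop
(argmax of log d(c) − log d(c+1), ties toward smaller c). The relative
form matters: with four temporal archetypes the two induced and two
repressed shapes form close pairs, so absolute drops peak spuriously at
the first step. If no step at least halves the distance the data show no
elbow and the smallest candidate is returned with a warning.

Assignment: argmax cluster at membership ≥ 0.5; otherwise a feature is
rescued into the same-direction cluster group (induced pair vs repressed
pair) when that group's summed membership exceeds 0.6; otherwise it stays
unassigned. "Similar clusters" are operationalized as same direction
label, matching the induced 1+2 / repressed 3+4 pairing.

## Antisense pairs

Pairs are all (asRNA, mRNA) duos on one replicon overlapping on opposite
strands by ≥ 1 bp (half-open arithmetic; an asRNA covering only a gene's
3' end still pairs, and one asRNA may pair with several mRNAs).
Correlation is Pearson r over the six per-replicate post-shock fold
changes (2 replicates × 3 time points); three replicate means would make
r nearly degenerate. Eligibility requires a cluster assignment for both
members and significant differential expression of each member at ≥ 1
time point (the stricter each-member reading). Quadrants require
|r| ≥ 0.65 with sign consistency: opposite cluster directions need
r ≤ −0.65, same directions r ≥ +0.65; everything else is `unclassified`.

## Proteome

Hi3: per protein the signal is the mean of its three most intense
peptides (fewer peptides → all available, flagged), scaled to the spiked
40-fmol standard, making amounts invariant to global intensity scaling.
Identification filtering keeps proteins with ≥ 2 unique peptides per
fraction; a configurable allow-list re-admits named single-peptide
proteins with a flag.

Weighted fold change: S = soluble + membrane + debris/10 per condition
(debris carries ~10% of total protein, hence the divisor); a fraction not
detected in a condition contributes 0 and is flagged. fc_combined is the
arithmetic mean of the weighted and total-extract ratios — the literal
combination rule; a geometric (log-scale) mean is available via
`combined_fc_geometric`. The ANOVA (two groups, equivalent to a pooled-
variance t) runs on log2-transformed total-extract amounts by default for
variance stabilization; which fraction feeds the test is configurable.
Significance: fc_combined ≥ 1.5 or ≤ 1/1.5 and p < 0.05.

## Integration and enrichment

Transcript 24-h and protein log2 fold changes are inner-joined by locus
tag (duplicates: first kept, logged); |Δlog2| < log2(1.5) marks a similar
pair; the overall Pearson r is reported with the scatter data. The
consensus filter intersects the gene universes of three transcriptome
log2 FC tables and one proteome table and keeps genes strictly above 0.58
(transcriptomes) and 0.38 (proteome) — strict inequalities, since the
thresholds are defined as exceedances ("log2 > …"), so a gene exactly at a
threshold fails. Enrichment per (cluster, KO term) is the one-sided
hypergeometric upper tail P(X ≥ k) on the clustered-mRNA universe, BH
adjusted within a cluster; k = 0 terms are skipped.

## Metabolome

Normalized abundance = intensity / internal-standard intensity of the same
sample, which cancels per-sample injection and ionization factors exactly
by construction; samples with a zero or missing standard are excluded with
a warning. The fold change is the ratio of replicate means (not the mean
of per-replicate ratios), salt over control, control reported as 1, with
relative replicate standard deviations alongside.

## Synthetic data

The generator plants known structure so that recovery, not plausibility,
is tested:

- **Annotation** — one pseudo-replicon (200 kb default) divided into equal
  slots; each slot hosts an mRNA (+ strand), optionally its planted asRNA
  inside it (− strand), and non-pair asRNAs/sRNAs in the intergenic part
  so they never overlap an opposite-strand mRNA. Feature lengths scale
  with slot width and are not biologically realistic; only the overlap
  topology matters to the algorithms.
- **Transcriptome** — four archetypes over (0, 0.5, 2, 24) h with
  amplitude 2 log2 units: transient up peaking at 0.5 h (0, A, A/2, 0), up
  peaking at 2 h (0, A/2, A, A/4), and their mirrored negatives, plus flat
  profiles (default 20%). Inverse pairs mirror the mRNA archetype,
  co-regulated pairs share it. Noise is additive Gaussian on log2 signals
  (default sd 0.3); the study-scale defaults (600 mRNA / 200 asRNA /
  60 sRNA, duplicate replicates) keep the full pipeline under 10 s.
- **Proteome** — 500 proteins mapped to the first mRNA locus tags, default
  fraction shares (0.5, 0.4, 0.1), 10% planted at fold change 2 and 10%
  at 0.5, mean-preserving lognormal noise at CV 0.1, and a 10% subset that
  moves half its soluble share into the membrane at constant total (the
  redistribution scenario the weighted fold change is designed for).
  Peptide tables use fixed relative intensities whose top-3 mean is 1, so
  Hi3 recovers planted fmol exactly at CV 0.
- **Metabolome** — per-sample lognormal injection factors (σ 0.3) carried
  identically by the internal-standard channel; planted fold changes
  default to a strongly accumulating osmolyte-like compound (20×), a
  depleted glycolytic intermediate (0.33×), and flats.
- **KO annotation** — every mRNA of archetype k carries term `KO:Ck`
  (nowhere else) plus two random background terms, so the planted term
  ranks first by construction.

All randomness flows from one integer seed; identical configurations give
bit-identical files. What a green recovery test does **not** establish:
robustness to probe-level artifacts, heteroscedastic or correlated noise,
batch effects, unbalanced designs, or annotation ambiguity — none of which
the generator emulates.

## Numerical choices and degenerate inputs

- Pearson r is missing (never 0) for zero-variance or incomplete vectors.
- Fold changes with a zero/missing denominator are missing, with a reason
  logged; proteins with neither weighted nor total ratio are excluded.
- Membership rows sum to 1 within 1e-9 at every iteration; the objective
  is non-increasing by construction of the alternating minimization.
- TSV reports render floats at 6 significant digits; expression matrices
  round-trip at full precision.

## Limitations

- Headline counts of the original study (pair quadrant totals, numbers of
  regulated proteins, the cross-omics r, consensus-list size) depend on
  the deposited datasets and are out of scope here; the pipeline
  reproduces the *rules*, verified against planted ground truth.
- The probe-to-feature map must be supplied explicitly; no disambiguation
  of probes hitting several overlapping features is attempted.
- With duplicate arrays the default variance-sharing test trades
  per-feature specificity for power; use `de_test: welch` when replicate
  counts allow.
- No raw-signal processing (array images, spectra, peak integration):
  inputs begin at normalized log2 signals, fmol amounts or peptide
  intensities, and metabolite intensities.
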