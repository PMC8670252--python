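# saltomics

Integrative multi-omics analysis of the cyanobacterial salt-acclimation
response. The package re-implements, as a tested pipeline, the analysis
chain used to characterize how a euryhaline cyanobacterium
(*Synechocystis*-like) reorganizes its transcriptome, proteome and
metabolome after a sudden shift to high salinity: soft clustering of a
4-time-point microarray time course, strand-aware antisense-RNA/mRNA pair
classification, fraction-weighted label-free proteome fold changes,
transcriptome–proteome correlation and consensus filtering, KO-term
enrichment, and internal-standard metabolite normalization.

It is written for computational biologists who want to run the same
decision rules on their own expression/proteome tables, or to study the
behaviour of those rules on synthetic data with known ground truth — the
bundled generator emulates the study design (duplicate hybridizations at
0, 0.5, 2 and 24 h; four proteome fractions with four biological
replicates; planted temporal archetypes, antisense pairs, protein and
metabolite fold changes), so every stage has a recovery test without any
download.

## Methods at the core

**Fuzzy c-means time-course clustering.** Standardized 4-point log2
profiles x_i are soft-clustered by minimizing

    J = Σ_i Σ_k u_ik^m ‖x_i − v_k‖²,   Σ_k u_ik = 1,

with the alternating updates
v_k = Σ_i u_ik^m x_i / Σ_i u_ik^m and
u_ik = 1 / Σ_j (‖x_i−v_k‖/‖x_i−v_j‖)^(2/(m−1)).
The fuzzifier is estimated from the data dimensions as

    m(N, D) = 1 + (1418/N + 22.05)·D⁻² + (12.33/N + 0.243)·D^(−0.0406·ln N − 0.1134),

which gives m = 2.53 for N = 3831 profiles over D = 4 time points. The
cluster count is the elbow of the minimum-centroid-distance curve;
transcripts join their argmax cluster at membership ≥ 0.5, or the
same-direction cluster pair when the combined membership exceeds 0.6.

**Antisense pair classification.** Each asRNA is paired with every mRNA it
overlaps on the opposite strand (half-open intervals, ≥ 1 bp). Pairs where
both members are clustered and differentially expressed (|log2 FC| ≥ 1,
p < 0.05) are placed into four quadrants — asRNA-up/mRNA-down,
asRNA-down/mRNA-up, both-up, both-down — by the Pearson correlation r of
their per-replicate fold-change profiles at |r| ≥ 0.65, with direction
taken from the induced/repressed cluster labels.

**Fraction-weighted proteome fold change.** Per protein,
S = soluble + membrane + debris/10 (fmol on column) is formed per
condition; fc_weighted = S_salt/S_control buffers proteins that merely
redistribute between fractions. The final fc_combined averages
fc_weighted with the total-extract ratio (falling back to whichever
exists); significance needs fc ≥ 1.5 (either direction) and ANOVA
p < 0.05. Hi3 absolute amounts are mean(top-3 peptide intensities) scaled
to a 40-fmol spiked standard.

**Integration.** Transcript (24 h) and protein log2 fold changes are
joined by locus tag; |Δlog2| < log2(1.5) marks a similar pair. A consensus
filter keeps genes with log2 FC > 0.58 in three transcriptome datasets and
> 0.38 in the proteome. Per-cluster KO-term enrichment uses the one-sided
hypergeometric upper tail with Benjamini–Hochberg adjustment.

**Metabolome.** Intensities are divided by the per-sample carnitine
internal-standard signal (cancelling injection factors exactly), and fold
changes are ratios of replicate means with the control defined as 1.

## Worked example

```sh
saltomics --seed 42 --out-dir sim  simulate
saltomics --seed 42 --out-dir out  run-all --in-dir sim
```

prints (numbers from this exact run):

```
Fuzzy c-means: c=4, m=2.657, J=61.1306, converged=True
  cluster 1:   induced, peak +1.496, 191 assigned
  cluster 2: repressed, peak -1.484, 183 assigned
  cluster 3:   induced, peak +1.476, 155 assigned
  cluster 4: repressed, peak -1.482, 182 assigned
```

The elbow found the four planted temporal archetypes; m = 2.657 is the
closed-form estimate for the 732 profiles that survived the |log2 FC| ≥ 1
prefilter. `out/pair_summary.tsv` for the same run counts the recovered
antisense quadrants (50 inverse and 50 co-regulated pairs were planted):

```
    category  n
as_up_m_down 28
as_down_m_up 18
     both_up 26
   both_down 23
unclassified  5
```

and `out/protein_fold_changes.tsv` flags 100 of 500 proteins as
significant — exactly the 10% planted at fold change 2 and 10% at 0.5.
Each stage can also be run individually (`saltomics transcriptome`,
`cluster`, `pairs`, `proteome`, `integrate`, `enrich`, `metabolome`); see
`--help` for the file interfaces, and `docs/methods.md` for the model
details, defaults and limitations.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's analytic reference quantity from scratch — the
closed-form fuzzifier estimate for a clustering input of 3831 transcript
profiles over the four sampling time points — and writes it as JSON. It
also runs the full synthetic pipeline end to end under the given seed as a
self-check before reporting.
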