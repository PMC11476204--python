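# Methods

`cardiosplice` implements a tissue-aware discovery framework for
splice-disrupting DNA variants: candidate variants from genome sequencing
are screened by in-silico splice Δ scores, confirmed against outlier
splicing events in myocardial RNA-Seq from the same patient, used to
train random-forest classifiers, and finally carried into gene-tier
prioritization and case-control carrier burden analyses.  This note
records the model, the defaults, the numerical choices, and what the
synthetic cohorts do and do not establish.

## Splice metrics and the outlier model

For a junction *j* with donor *D*, ψ5(*j*) is the fraction of split reads
at *D* assigned to *j* among all junctions sharing *D*; ψ3 is the
symmetric quantity over shared acceptors; θ(site) = split/(split +
non-split) measures splicing efficiency (intron retention lowers it).
Junctions and sites require a read count of at least 15 in at least one
sample; a zero denominator leaves ψ undefined rather than zero.

Each retained site is modeled across the cohort as beta-binomial.  The
per-sample null is fitted **leave-one-out** by method of moments on the
other samples' (k, n) pairs: with ratio mean *m*, ratio variance *v* and
mean denominator n̄, the intraclass correlation is
ρ = (v/(m(1−m)) − 1/n̄)/(1 − 1/n̄); ρ ≤ 0 falls back to a plain binomial.
Leaving the tested sample out of its own null matters for single
outliers: a sample with an extreme ψ would otherwise inflate the
overdispersion of the very null used to test it and mask itself.  The
expected ψ reported per sample is the leave-one-out count-weighted
cohort mean, and the effect size is Δψ = ψ_obs − ψ_expected.

The decision rule for a significant event is fixed by four thresholds:
FDR < 0.2 (Benjamini–Hochberg within each sample across its tested
sites), |Z| ≥ 1, |Δψ| ≥ 0.2, and expected ψ ≤ 0.1 or ≥ 0.9 (only sites
that are nearly constitutively spliced, or nearly never spliced, are
interpretable as outliers).  The p-value is two-sided by doubling the
smaller beta-binomial tail (capped at 1).  The Z-score is computed on
logit ψ with pseudocounts (+1 numerator, +2 denominator) standardized by
the full-cohort mean/SD at the site — the logit stabilizes boundary ψ
values, and the |Z| ≥ 1 cut needs a declared scale since none is
canonical.  Events mapping to zero or multiple genes are dropped.  Ties
in p are ordered by site coordinate so output is deterministic.  A
latent-confounder correction (autoencoder-style denoising) is
intentionally out of scope: the decision rule is threshold-based and the
cohort null suffices at this scale.

## Expression Z-scores and the NMD check

Genes are retained when at least 10 reads are seen in **more than** half
the samples (strict).  Size factors are median-of-ratios with
zero-count genes excluded from the geometric-mean reference; Z-scores
standardize log2(normalized count + 1) per gene (constant genes get
Z = 0).  The nonsense-mediated-decay check compares the Z values at
(carrier sample, gene) pairs between model-selected and model-rejected
variants with a Welch two-sided t-test; variants in unretained genes are
skipped and tallied, and groups smaller than two leave the p-value
undefined rather than fabricated.

## Screening, labeling and features

A variant enters the candidate pool when it is PASS, its maximum Δ score
(over acceptor/donor gain/loss) is ≥ 0.2 (inclusive), and it is carried
by at most one sample — the carrier-count form covers the internal-MAF
phrasing at any cohort size.  Population rarity (gnomAD v2 AF < 1e-4 and
v3 PopMax AF < 1e-4) is applied separately when selecting
high-confidence variants; missing population frequencies are treated as
absence from controls and tallied for audit.

A screened variant is **confirmed** when a significant event exists in
the same gene and the same carrier sample within ±100 bp (inclusive at
exactly 100) of the event boundaries — the junction's donor/acceptor
coordinates, or the site position for θ events.  A variant whose
gene/carrier shows an event only beyond the window is **indeterminate**
and excluded from training and evaluation; everything else is
**unconfirmed**.  The model features are: maximum Δ score, distance to
the nearest annotated junction endpoint (leftmost reference position for
indels; single-exon genes leave it missing), SNV/indel status, the three
region flags (branchpoint, low complexity, repeat), and the gene's
median TPM.  Missing features are never imputed; rows with missing
values in a model's feature set are omitted and counted.

## Models

Four feature sets (Δ only; DNA features without Δ; DNA features + TPM;
everything) are fitted as random forests (500 trees, √p feature
subsampling, scikit-learn defaults otherwise).  The score is the mean
tree probability, thresholded at 0.5 by default — the operating point is
configurable because none is canonical.  Class imbalance (~1:80) is
handled either by class weights ∝ 1/class-count or by SMOTE: each
synthetic minority row is x + λ(x′ − x) for a uniformly chosen one of
x's k = 5 nearest minority neighbors (Euclidean on unit-variance-scaled
continuous features), λ ~ U(0,1); binary features are copied from the
nearer parent since interpolation has no meaning for them.  Evaluation
uses stratified 5-fold cross-validation with weights/SMOTE applied
strictly inside the training folds (leakage-free is the defensible
choice where folding details are open), pooled metrics on concatenated
out-of-fold scores, and a final refit on all data before application to
new cohorts.  Odds ratios add 0.5 to each confusion cell
(Haldane–Anscombe), keeping every table finite; Fisher's exact p uses
the raw table.  The bias-variance decomposition refits on bootstrap
resamples and scores out-of-bag points; per point, MSE = bias² +
variance holds exactly by construction (no covariance term — single
ensembles, not committee members).

## Prioritization and burden

Positions inside a gene are bucketed by offset from the nearest annotated
junction using the standard consequence convention: intronic 1–2
canonical splice site, intronic 3–8 or exonic 1–3 splice region, exonic
beyond 3 exonic, intronic 9–10 proximal intronic, deeper deep intronic
(the ">10 bp" cut is exactly representable).  The predicted mechanism
reuses the 0.2 screen: loss (donor/acceptor loss ≥ 0.2), gain, or both —
a deterministic stand-in where "most probable effect" is otherwise
ambiguous.  Reportability: Tier 1 genes under their inheritance mode
(dominant, or homozygous in recessive genes; a Tier 1 gene without an
inheritance annotation is an error, not a silent pass), and Tier 2 genes
with pLI ≥ 0.9.

Burden is carrier-based: a sample carries the stratum when it harbors at
least one qualifying variant.  Fisher's exact test runs on the raw 2×2
counts; the odds ratio and Wald 95% CI
(exp(log OR ± 1.96·√Σ 1/(cell+0.5))) use HA-corrected cells — the
correction is for estimation, not testing.  The synonymous-variant
control compares per-sample counts of rare synonymous variants between
cohorts with a two-sided Mann–Whitney U test before any splice burden is
interpreted.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes,
not sequence content (no reads, no FASTQ/BAM, no Δ-score network).
Defaults: 100 RNA+DNA case samples, 250 DNA-only controls, 300 genes
(10% Tier 1, 20% Tier 2) with 4–8 exons on 22 synthetic chromosomes,
~80 screened candidate variants per sample, mean junction depth 60,
log-TPM ~ per-gene Normal(1.0, 1.2²) means with within-gene σ = 0.5 and
10% of genes forced below TPM 1 to exercise the expression filter.
These sizes keep the full pipeline to a few minutes on one CPU.

Latent causality is logistic in exactly (max Δ, log median TPM, repeat
flag) with coefficients (−9.8, +8, +1, −1.5) — the minimal model that
reproduces the three univariable enrichments the labeling stage should
find (higher Δ scores, higher expression, repeat depletion), with the
intercept set so that confirmed:unconfirmed lands near 1:80, the class
structure the model-training stage is designed around.  Each causal
variant perturbs the nearest junction of its gene in the carrier sample
only: split reads are re-allocated from the canonical junction to a
cryptic junction sharing the donor by Δψ = 0.4 of the donor total
(per-donor totals conserved; shifts that would cross zero are clipped
and recorded).  NMD is emulated by scaling the carrier's gene count by
2^(shift · sd_g), sd_g the gene's SD of log2(count+1), which moves the
expression Z by ≈ the configured shift (−0.2 by default) before
Z-scoring.  Cases optionally receive extra causal variants in Tier 1/2
genes (0.3 per case by default), planting a carrier-burden excess.  The
marginal Δ-score distribution among screened candidates is a free
choice (0.2 + 0.8·Beta, with a dominant gain/loss channel and occasional
dual patterns); nothing downstream depends on its exact shape.

What passing tests show — and what they do not.  The synthetic cohorts
have independent genes, no alignment artifacts, no homologous-gene
read-misassignment (the kind that forces manual event exclusions in real
myocardium), no ancestry structure, and a causal model that is exactly
the logistic the features can represent.  Recovery results on them
demonstrate internal correctness of the machinery (metrics, nulls,
matching, model ordering, calibration), not field performance on
patient data.

## Problem sizes in the checks

The repeated-cohort checks use the default cohort over 10 seeds for the
model-ordering and sensitivity comparisons; 80-sample single-arm cohorts
for the NMD direction; 100 reduced replicates for NMD null uniformity;
and carrier-status simulation at 947 cases / 2570 controls for burden
calibration (500 null replicates) and recovery of a planted OR of 1.3
(100 replicates, control carrier rate 0.3).  Burden replicates simulate
carrier indicators directly rather than full variant tables: the carrier
2×2 is a sufficient statistic for the burden test, so nothing is lost
and five hundred replicates stay cheap.

## Known limitations

* The cohort beta-binomial null does not absorb latent confounders
  (batch, cell-type composition); on real data a denoising step would
  precede it.
* ψ3 events are only informative when acceptors are genuinely shared;
  the generator's cryptic junctions share donors, so its planted events
  surface through ψ5 (and θ stays null), which is a modeling choice, not
  a constraint of the caller.
* The burden CI is Wald-on-corrected-cells; exact intervals would be
  wider for very sparse strata.
* Genotype phasing, compound heterozygosity and segregation are out of
  scope; the recessive rule uses the single-variant genotype only.
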