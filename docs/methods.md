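# Methods

## Data model

Three linked tables drive every analysis. The **ESV table** holds
integer read counts per denoised exact sequence variant per sample,
with each ESV pointing at its parent MOTU and optionally carrying its
nucleotide sequence. The **MOTU table** holds per-sample read counts,
a ranked taxonomy (semicolon-delimited, absent ranks empty), an
optional nominal species, and a dataset label (NIS / NAT / COMM_other).
The **sample frame** maps samples to locality, time point, replicate
and type (true sample, blank, PCR negative). Invariants enforced at
construction and re-validated after every stage: unique ids,
nonnegative integer reads, and MOTU reads equal to the per-sample sums
of member ESVs. Sample columns are recognised by membership in the
sample frame — an unknown column is an error, which prevents a blank
from being silently analysed as a sample. Reads are stored as
integers; relative abundances are derived on demand and never stored.

## Curation cascade

Order: blank filter → dual abundance filter → pseudogene filter →
sample depth filter. All thresholds are strict inequalities.

* **Blank filter** (threshold 0.10): an ESV is a contaminant when its
  summed reads in blanks and negatives are *more than* 10% of its
  summed reads in true samples. The denominator uses true samples
  only; a switch (`blank_denominator_true_samples_only=False`) includes
  controls for sensitivity analyses. ESVs seen only in controls are
  removed. Control columns are dropped from analysis immediately after
  this filter, so later per-sample totals are unaffected by them.
* **Dual abundance filter** (0.005% of the sample total, then 5 reads):
  step (ii) is evaluated on post-step-(i) values; the order is
  enforced because a cell can pass the relative cutoff and still fall
  to the count cutoff. Sample totals are taken at entry to the filter
  (after contaminant removal).
* **Pseudogene filter**: a sequence is deleted when its translation
  has a stop codon under *every* configured mitochondrial genetic code
  — the default set is the nine NCBI tables used by metazoan
  mitochondria (2, 4, 5, 9, 13, 14, 21, 24, 33) — or when a configured
  conserved amino-acid position deviates from its allowed residues in
  every stop-free translation. Keeping sequences that are stop-free
  under at least one code is deliberate: the producing taxon is
  unknown, so only a universally broken frame condemns a sequence.
  Note TAA is not a universal metazoan stop (it encodes tyrosine in
  tables 14 and 33); TAG is. The conserved-position list defaults to
  empty (disabled) and is supplied through `FilterConfig` when a
  reference profile for the amplified fragment is available. The
  reading frame defaults to offset 2, the customary frame of the
  ~313 bp Leray COI fragment, and is configurable. MOTUs whose ESVs
  are all deleted are removed from the MOTU table.
* **Sample depth filter** (9,500 reads): true samples below the
  threshold are removed from all tables; removing every sample is an
  error.

Every stage emits a removal log (esv_id, stage, reason, reads removed)
and the cascade records per-stage ESV/MOTU/read counts; total reads
are non-increasing along the cascade by construction.

## Dataset classification

A MOTU is **NIS** when at least one hit against the curated
invasive-species reference reaches 97% identity *and* 70% coverage
(both inclusive). The nominal species comes from the best hit; ties
are broken by identity, then coverage, then species name, making the
assignment invariant under hit order. The agreement report against a
general-database assignment classes each NIS MOTU as coincident,
higher-rank-only, different-species or same-species-low-identity.
**NAT** is the species-level-assigned non-NIS subset minus an explicit
exclusion list (species complexes, dubious matches, cryptogenic
species); an exclusion entry may be a MOTU id or a binomial, and an
entry matching nothing warns rather than fails. **COMM** — used for
the community-level analyses — is everything that is not NIS. Pooling
MOTUs to nominal species sums reads and conserves totals exactly.

## Diversity analyses

* **Richness** is rarefied analytically: E[S] = Σ_i [1 −
  C(N−N_i, d)/C(N, d)] at common depth d (log-gamma arithmetic), the
  expectation of a without-replacement subsample. The depth is the
  minimum per-sample total over retained samples, computed from the
  data, never hard-coded.
* **Shannon** (natural log) is computed on one seeded
  multivariate-hypergeometric draw at the common depth; a config
  option averages k draws. The analytic expectation is used for
  richness but not Shannon because the expected Shannon of a
  subsample has no similarly simple closed form; one seeded draw
  mirrors common practice and stays reproducible.
* Group comparisons: one-way ANOVA + Tukey HSD for Shannon;
  Kruskal–Wallis + Dunn rank post-hocs (tie-corrected, Holm-adjusted
  column included) for richness, whose distribution is typically
  skewed. Tied constant data yield statistic 0, p 1.
* **Composition summaries**: per locality, the mean over samples of
  per-sample relative read proportions by phylum; phyla under 5% pool
  into "Others", unassigned reads report as "Unidentified";
  proportions sum to 1.

## Beta diversity

Bray–Curtis is computed on per-sample relative abundances without
rarefaction. Sørensen sharing is computed at locality level (pooled
incidence over a locality's samples, one value per locality pair, mean
over the pairs); a sample-pair mode (`sorensen_between_samples`)
exists for sensitivity analysis. Membership (upset) counts are exact:
each MOTU contributes to exactly one locality-subset cell. NMDS uses
non-metric MDS with several seeded random starts, reporting Kruskal's
normalised stress-1; identical seeds give identical configurations.

**PERMANOVA** is Anderson's one-way pseudo-F computed directly from
squared distances, with p = (count of permuted F ≥ observed + 1) /
(n_perm + 1); factors (site, month) are tested separately, matching
how one-way designs are reported for this kind of survey. The
**dispersion test** embeds the distance matrix in principal-coordinate
space keeping all axes, subtracts the contribution of
negative-eigenvalue axes from squared centroid distances (clamped at
zero), and permutes the distances-to-centroid. Permuted statistics are
compared to the observed one with a 1e-12 relative tolerance so exact
ties arising from float reordering are counted as ties. Both
statistics match scikit-bio's implementations to numerical precision;
the permutation machinery is seeded and matches exhaustive enumeration
on small inputs.

**Temporal turnover** averages, per locality and consecutive
time-point pair, the Bray–Curtis values over all cross-time sample
pairs, then averages localities; a locality missing a time point is
flagged as a gap. Dataset-level mean dissimilarities are compared with
a paired t-test over matching sample pairs. A warm/cold season
labelling utility uses a 20 °C threshold.

## Metaphylogeography

ESVs serve as haplotypes within MOTUs. Per-MOTU ESV counts are
compared between NIS and NAT with two-sided Mann–Whitney tests,
overall and stratified by locality or phylum.

Because detected haplotype number grows with read number, the package
quantifies the confound (per-dataset OLS of log ESVs on log reads,
Pearson r, slope homogeneity via the dataset × log-reads interaction)
and removes it by **per-MOTU read rarefaction**: every MOTU above a
common threshold (an integer, or the mean/median of the NAT read
totals) is subsampled without replacement to exactly that total with a
single multivariate hypergeometric draw over its (ESV, sample) cells,
preserving per-sample proportions in expectation; ESVs reduced to zero
are eliminated and elimination percentages are reported per dataset.
A **randomization balance test** re-runs the rank test after repeatedly
subsampling the larger group to the smaller group's size, reporting
the fraction of significant resamples.

**Jost's D** is estimated per MOTU between each locality pair from
occurrence counts — the number of samples in the locality where the
ESV is detected — because read counts are a poor abundance proxy at
haplotype level. The estimator uses the small-sample corrections with
harmonic-mean sample size (Ĥ_S = ñ/(ñ−1)·H_S; Ĥ_T = H_T + Ĥ_S/(ñn));
an uncorrected variant sits behind a flag. Negative estimates are
clamped to zero per MOTU before averaging. Eligibility: the MOTU is
present in both localities and has at least two ESVs with nonzero
occurrence summed over the pair (a strict per-locality mode is
available); this is the weakest condition under which differentiation
is defined. Across the locality pairs, the NIS and NAT mean-D vectors
are compared with a paired t-test, and their Pearson correlation asks
whether the two groups share a spatial pattern. Degenerate cases
error explicitly: a locality with zero occurrences, a single
haplotype, or a within-locality diversity estimate of 1 (undefined D).

Small occurrence totals deserve caution: with only a handful of
detections per locality, the clamped estimator's sampling noise
inflates mean D upward even without true differentiation. Tests that
assert near-zero D under no differentiation therefore use
configurations with enough occupied samples per locality.

## Synthetic data generator

The generator is first-class, tested code; its defaults encode the
survey conditions: 4 ports × 10 sampling times × 3 replicates, 15 PCR
blanks and 12 negatives, 75 NIS + 244 NAT + 1,455 other MOTUs,
lognormal per-sample depths around 10⁶ reads, and 10 of 120 samples
made shallow (below the 9,500-read cutoff).

Model, per MOTU: a lognormal base abundance (σ = 2.5; NIS scaled ×25
so few NIS MOTUs carry a large read share); Bernoulli locality
occupancy (NIS 0.8, others 0.3); a zero-truncated negative-binomial
haplotype number whose mean scales with relative abundance to the 0.35
power within each class (larger populations carry more haplotypes;
class means 8 for NIS, 3 otherwise); haplotype base frequencies from a
symmetric Dirichlet (α = 0.3, one dominant haplotype plus a rare
tail); and locality frequencies (1−θ)·base + θ·private Dirichlet draw,
with θ the differentiation dial (defaults θ_NIS = 0.6,
θ_NAT = θ_other = 0.75). Reads per sample are one multinomial draw
over all (ESV, sample) cell weights — MOTU sums therefore equal ESV
sums exactly — with per-(MOTU, sample) lognormal wiggle (σ = 0.7,
temporal turnover) and per-(ESV, sample) patchiness (σ = 1.5,
haplotypes carried by few individuals). Contaminant ESVs (1%) leak
~30% of their true-sample reads into controls; pseudogene spike-ins
(2% of ESVs) carry an in-frame TAG in an otherwise clean 313-bp
COI-like template whose variants differ only at third codon positions.
A ground-truth ledger records classes, θ, contaminants, pseudogenes
and shallow samples.

Free parameters without a stated value were fixed once so the
generator sits in the survey's qualitative regime — NIS median ESVs
per MOTU ≈ 7 vs NAT ≈ 2, a strong log-log reads–richness correlation
in both datasets, NIS read share far above their MOTU share, and mean
D ≈ 0.2 (NIS) vs ≈ 0.3–0.4 (NAT).

What the generator does *not* emulate: PCR/sequencing error and
chimeras (denoising is upstream of this package), phylogenetic
structure among MOTUs, true seasonal cycles (temporal variation is
exchangeable noise, so month effects are null by construction), and
taxonomy-dependent primer bias. Passing tests on synthetic data
therefore demonstrate correctness of the statistical machinery and
recoverability of planted effects, not field realism.

## Numerical choices and limitations

* Seeds: every stochastic operation takes an explicit seed; the
  pipeline derives per-stage seeds from one master seed via
  `SeedSequence`, so identical manifests reproduce outputs
  bit-for-bit.
* Rarefaction uses `Generator.multivariate_hypergeometric`; expected
  richness uses log-gamma arithmetic (stable for large counts).
* Mann–Whitney tests use the normal approximation with tie
  correction, adequate at the group sizes involved.
* Problem sizes in the test and acceptance suites are scaled-down
  versions of the default conditions (fewer MOTUs/time points,
  shallower depths), chosen to keep the checks sharp at small cost;
  the study-scale defaults are exercised directly where group-size
  defaults matter (richness-ordering recovery, the acceptance script).
* The log-log regressions apply no outlier deletion by default; an
  outlier rule can be applied by filtering the summaries table before
  the regression.
* PERMANOVA is one-way only (no crossed/nested designs); Sørensen
  locality pooling assumes each locality has at least one occupied
  sample; Jost's D is the only differentiation statistic provided (no
  F_ST family), and occurrence counts cap at the number of samples per
  locality, which compresses D when sampling is sparse.
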