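# Methods

`phosdyn` reimplements, against synthetic data with known ground
truth, the computational analysis of a time-resolved phosphoproteomics
experiment: cells treated with a WEE1 inhibitor are sampled at 0, 20,
40, 60 and 90 minutes in three biological replicates; phosphopeptide
and protein abundances are quantified per sample with no missing
values. Releasing WEE1's inhibitory phosphorylation activates
CDK1/CDK2, so CDK substrates phosphorylate over the time course while
most sites stay flat.

## Synthetic data

The generator is first-class code: every downstream stage is tested
against what was planted.

**Proteome.** Random sequences (default 300 proteins, 300–800
residues) drawn from approximate human amino-acid frequencies. Each
protein carries a per-residue disorder track from a two-state
segmental model: ordered and disordered segments alternate with
geometric lengths (means 30 and 20 residues, giving ~40% disordered
occupancy); ordered segments score uniform on [0, 0.45], disordered on
[0.35, 1.0]. Disorder is segmental rather than i.i.d. so the
conventional "disorder > 0.4" background filter selects structured
runs, as it does on real tracks.

**Kinase motifs.** Substrate sites are planted by rewriting flanking
residues around a random S/T acceptor according to a positional
preference table: the CDK-like consensus writes P at +1 with
probability 0.95 and K/R at +3 (0.55/0.2); a basophilic control kinase
writes R at −3/−2. Planted sites enter the kinase–substrate annotation
table with curation effort 3. Placements that cannot host the motif
are re-drawn and, if exhausted, reported by warning — flanks are never
silently truncated. Flanks are the ±10 window, padded with `_` at
termini so they are always 21 characters; pads are excluded from every
count and score.

**Time courses.** The noise-free log2 signal of an activated site
follows the saturation curve `y = Vm·t/(K + t)` with plateau Vm ~
N(2.0, 0.3) log2 units and half-time K lognormal around 10 min
("fast") or 60 min ("slow", CV 20%); "decreasing" sites fall linearly
(total drop uniform 0.5–1.5 log2 at 90 min); "flat" sites are
constant. The default composition is 200 CDK substrates (split
fast/slow), 60 flat control-kinase substrates, 1,700 flat and 300
decreasing decoys. Abundances are `baseline · 2^signal` (baseline
log2 ~ N(20, 1.5)) multiplied by a per-sample loading factor
(lognormal, σ = 0.2), a per-(site, replicate) batch offset (lognormal,
σ = 0.15) and log-normal measurement noise (σ = 0.1 log2 units,
~7% CV) — multiplicative noise because MS reporter intensities are
positive and right-skewed. The protein matrix is flat per protein
(5% of proteins drift linearly up to ±0.5 log2 over the course) with
its own loading factors and noise. The single-time-point companion
design (0/90 min × 4 replicates) is available via configuration but
off by default. The real data's noise structure is unknown; these
parameters are plausible study conditions, not estimates of it.

What the generator does not emulate: missing values, peptide-level
effects (missed cleavages, co-isolation), correlated noise between
sites on one protein, phosphatase kinetics, and kinase
cross-talk. Passing tests therefore demonstrate correctness of the
computations and calibration of the statistics under a clean
generative model, not performance on real spectra.

## Normalization

Two steps. (1) *Sample loading*: each column is scaled by
`SF_i = mean column sum / column sum_i`, after which all column sums
are equal (checked to relative 1e-9). (2) *Artificial internal
reference standards* (ARS): for feature j and biological replicate i,
`ARS_{i,j}` is the feature's total over the replicate's conditions;
the correction factor is `reference_j / ARS_{i,j}`, which equalizes
each feature's within-replicate totals across replicates and removes
per-(feature, replicate) batch effects exactly. The cross-replicate
reference is the **mean** of the per-replicate ARS values: a literal
sum would scale every factor uniformly by the replicate count and
change only the global scale; the sum reading is available via
`reference="sum"`. Rescaling one input sample changes the output only
through the global reference, so relative abundances are invariant.

*Protein correction* divides each matched phosphosite profile by its
protein's mean-centered profile in log2 space (centering keeps the
phospho scale); unmatched sites pass through flagged. *Adjusted
z-scores* for display either anchor the first time point at zero or
shift the minimum to zero.

## Differential testing

Each post-treatment time point is contrasted with t = 0 on log2
abundances with an empirical-Bayes moderated t: per-feature pooled
variances (d residual df) are shrunk toward a prior s0² with d0 df,
`s̃² = (d0·s0² + d·s²)/(d0 + d)`, t referred to d + d0 df. The prior
is fitted by the method of moments on log sample variances (inverting
the trigamma function), which reproduces the standard moderated-t
implementation exactly — one test validates t and p against R limma
to 1e-9. d0 → 0 recovers the ordinary t; d0 → ∞ uses s0² everywhere.
BH step-up FDR (via statsmodels) is applied per contrast; sites with
FDR < 0.05 are "significant", optionally filtered by sign.

Because both normalization steps equalize sums, strong genuine
up-regulation depresses flat sites slightly (a compositional effect
inherent to sum-based scaling); it inflates "down" calls among flat
sites but does not affect the up-regulated calls the CDK prediction
uses.

## Kinase activity

Sites are scaled peptide-wise (row z-score across samples, sample SD)
so abundant sites cannot dominate. For kinase k with n ≥ 5 annotated
sites, the per-sample activity is the Stouffer combination
`RKA_k = Σ S_i / √n`; under the null of standard-normal scaled
abundances this is standard normal, so the 1% significance threshold
is the upper normal quantile 2.3263 (one-sided, activation being the
question; a two-sided option exists). The `/n` plain-mean variant is
exposed as a switch. Per-condition mean activities are the OLS
coefficients of a condition-indicator model with SE from pooled
residual variance; shifts vs t = 0 propagate SEs in quadrature;
activity correlation is the Pearson correlation of per-kinase
condition-mean profiles.

## Dynamics

Scaled time profiles (replicate-averaged per time point) of the
*regulated* sites (FDR < 0.05 at any time point) are clustered with
fuzzy c-means, 8 clusters, fuzzifier m = 2, Euclidean distance,
tolerance 1e-6, max 200 iterations. Clustering only regulated sites is
deliberate: the z-scored profiles of thousands of flat sites are pure
noise spread over a sphere, and at 8 clusters the objective prefers
partitioning that cloud to separating the two activated classes.
Initialization is k-means++-style seeding with 10 deterministic
restarts (lowest final objective wins); memberships for a profile
coinciding with a centroid collapse to that cluster. The objective is
asserted non-increasing on every run.

Each increasing cluster (positive net centroid change) is fitted,
pooled over its member profiles (min-shifted), with
`y = Vm·x/(K + x)` by nonlinear least squares from multiple K starts
(5, 20, 60, 200 min) to avoid single-start non-convergence;
non-convergent or constant cases fall back to a flagged straight
line. "Fast" is the increasing cluster with the smallest fitted K,
"slow" the largest; ties break toward larger Vm. Note that K is only
weakly identified from five time points per series (CRLB ≥ 35% of K
per series at 5% noise), so cluster-level pooled fits are the
meaningful quantity; centroid-only fitting is available via a flag.

## PSSMs

Background amino-acid frequencies `F_i = A_i/T` are counted over
residues with disorder > 0.4 only (phosphosites live in disordered
sequence whose composition differs from the folded proteome), with
one pseudocount per residue class. For each kinase with ≥ 20 sites of
curation effort strictly above 2, a 21 × 20 matrix of residue scores

    RS = −log10[ P(k ≥ K_a | N, p_a) / P(k ≤ K_a | N, p_a) ]

is built from binomial tail sums (K_a observed count at a position, N
non-pad residues there, p_a background frequency); positive means
enrichment. The lower tail includes K_a itself; an exclusive variant
(stopping at K_a − 1) is behind a compatibility flag. Site scores sum
matrix entries over the flank; pads contribute zero.

Raw scores are calibrated per kinase by logistic regression
`P(S) = 1/(1 + e^−(β0+β1·S))` against the decoy pool: stratified
80/20 split, training majority class down-sampled to balance, small
L2 penalty (C = 100) so separable fits stay finite. The split is
site-level disjoint — held-out metrics are honest, unlike a test set
overlapping PSSM training. The probability cutoff maximizes Youden's
J on the held-out ROC curve (ties toward higher specificity); AUC is
the rank-based area, validated against a pair-counting oracle.

## CDK prediction and motif comparisons

A site is a *theoretical* CDK substrate if its calibrated CDK1 or
CDK2 probability reaches that kinase's cutoff, and an *empirical*
prediction if additionally its cluster is fast or slow and it is
significantly up-regulated; CDK1/CDK2 calls merge keeping the larger
probability. The output equals a brute-force conjunction by
construction and is tested as such.

Flank composition of fast vs slow empirical substrates is compared by
bootstrap: each group resampled with replacement at its own size 100
times; the fast − slow frequency difference per (position −7..+7,
residue) is summarized by its mean and SD, and a two-sided p value is
taken from N(0, SD) — under the null the observed difference divided
by its bootstrap SD is approximately standard normal. Cells with zero
SD report p = NA. Cy motifs are all (possibly overlapping) matches of
[R/K]-x-[L/V/I] where x is any of the 20 residues; nearest-match
distances on each side of the phosphosite are compared between groups
with the two-sample KS test. The 20–80-residue window in which Cy
motifs act is a reporting band, not a filter. Gene-set
over-representation uses the upper-tail hypergeometric test against
the detected-phosphoprotein background with BH correction across
sets.

## Orchestration and problem sizes

`run_pipeline` executes the stages in order, writes all outputs as
TSV/JSON into a run directory, and records a manifest (parameter
hash, seed, library versions, per-stage counts). One root seed is
forked into independent per-stage streams, so reruns with the same
configuration and seed are byte-identical. Defaults: FDR 0.05,
min 5 substrate sites, α = 0.01, 8 clusters, fuzzifier 2.0, disorder
cutoff 0.4, ≥ 20 training sites, curation > 2, 100 resamples.

The default scenario (2,260 sites × 15 samples, 300 proteins) runs
end-to-end in well under a minute; the test suite uses this size and
a reduced variant (450 sites) so that statistical checks (10,000-kinase
null calibration, 1,000-profile clustering, 1,000-triple oracle
comparisons) remain quick and reproducible.

## Known limitations

- Sum-based normalization is compositional (see above).
- Real-dataset-scale analyses (tens of thousands of sites,
  database-derived kinase annotations, external inhibitor datasets)
  are out of scope; recovery statistics here quantify the method on
  planted truth, not on real biology.
- No phosphatase or inhibitory-site modeling: activity scores treat
  all annotated substrates as activation readouts.
- Cy-motif matching is linear sequence only; no structural check.
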