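# Methods

This package re-implements, as a tested pipeline over synthetic data, the
analysis chain used to characterise mito-nuclear discordance across an avian
secondary-contact zone: restriction typing of a maternally inherited marker,
microsatellite quality control, Bayesian admixture scoring, geographic cline
fitting with information-criterion model selection, neutral-diffusion dating
of the contact, and phenotype–ancestry regression. This note records the
models, the defaults and why they were chosen, and what the synthetic data
do and do not establish.

## The cline model family

A geographic cline describes the change of a frequency (here: interior mtDNA
haplotype frequency, or mean interior ancestry Q per site) along a
one-dimensional transect. The shape is the standard sigmoid with optional
exponential tails:

- central sigmoid `f(x) = 1 / (1 + exp(-4 (x - c) / w))`, with centre `c`
  (km, where the unscaled cline crosses 0.5) and width `w` (km, the inverse
  of the maximum slope);
- an optional left tail replacing the sigmoid for `x < c - delta_L`:
  `f(x) = f(c - delta_L) * exp(theta_L (x - c + delta_L))` with
  `theta_L = (4 tau_L / w) / (1 + exp(-4 delta_L / w))`, so that the tail
  matches the sigmoid's value at the junction and has `tau_L` times its
  slope there (the right tail is the mirror image);
- scaling `p(x) = p_min + (p_max - p_min) f(x)`.

The composite is continuous everywhere and continuously differentiable at
the junctions exactly when `tau = 1` (verified by finite differences in the
tests). Tails are applied to the unscaled shape and the composite is then
scaled; the alternative composition order (scale before tails) is
observationally equivalent for the no-tail models used by the headline
analysis.

Fifteen models are formed by crossing five tail configurations (none, left,
right, mirror, both) with three scaling sets: set 1 fixes `p_min = 0,
p_max = 1`; set 2 fixes them at the observed extreme frequencies; set 3
frees them. A sixteenth, null, model is a constant frequency with its
closed-form maximum-likelihood fit.

## Likelihood

Site data enter through a binomial likelihood: at site `i` with `n_i`
individuals, `k_i` interior haplotypes, the log-likelihood sums
`log Binomial(k_i | n_i, p(x_i))` with `p` clamped to `[1e-9, 1 - 1e-9]` to
keep mismatches at fixed bounds finite. Mean Q-scores are fitted with the
same machinery through an effective success count `k_eff = round(n_i *
mean_q_i)`; this mirrors treating per-site average ancestry as a frequency.
A Gaussian alternative using the per-site Q variance was considered and not
implemented in v1 — the binomial route is the one the emulated analysis
used, and it is deliberately conservative (it overstates the noise of a
13-locus average, widening the nuclear CIs).

## Fitting, model selection, and intervals

Each cline model is fitted by random-walk Metropolis–Hastings under flat
priors on hard bounds (with `span` the transect extent: `c` in
`[min - span/2, max + span/2]`, `w` in `(0, 2 span]`, `delta` in `[0,
span]`, `tau` in `[0, 1]`, `p_min <= p_max` in `[0, 1]` by rejection). A
pilot run with a diagonal proposal (scale steered toward ~25% acceptance)
estimates the proposal covariance, which is scaled by `2.38^2 / d` for the
main phase: by default three chains from overdispersed starts, the first
20% of each discarded, the rest pooled. Split-R̂ and effective sample size
are computed per parameter (via ArviZ) and a warning is raised when R̂ >
1.05 or ESS < 200. Everything is deterministic given the seed.

Model selection uses AICc = `-2 ln L + 2k + 2k(k+1)/(n - k - 1)` with `n`
the number of sites (localities, not individuals; switchable). Because the
Monte-Carlo maximum log-likelihood carries sampling noise of order 0.1,
near-identical models (e.g. set 2 reduces to set 1 whenever the observed
extremes are 0 and 1) would otherwise be ranked by that noise; the selection
therefore reports both the raw AICc winner and a "preferred-parsimony"
model — the simplest model (fewest parameters, then simplest scaling, then
simplest tails) within 2 AICc units of the minimum. Downstream stages use
the parsimony-preferred model.

Parameter support is summarised by two-log-likelihood intervals: the min and
max of a parameter over all pooled samples whose log-likelihood is within 2
units of the maximum (an approximate 95% region under a quadratic
likelihood). Two datasets' estimates are declared significantly different by
the reciprocal rule: each point estimate must fall outside the other's
interval. Intervals come from pooled chains; a sample-based interval can
only shrink, never widen, relative to the true 2-LL region, which makes the
significance rule slightly anticonservative at very short chain lengths —
the default chain budgets were checked for ≥ 85% coverage of the true width
in simulation.

## Neutral-diffusion dating

Under neutral diffusion after contact, cline width grows as
`w = 2.51 sigma sqrt(t)` with `sigma` the RMS parent–offspring dispersal
distance. Two inversions are provided: `formula`, the literal solution
`t = (w / (2.51 sigma))^2`, and `paper_match`, `t = (w / sigma)^2`. The
published year ranges for this system (~690–7,600 and ~12,000–440,000) are
reproduced, to two significant figures, only by the `paper_match` form; the
discrepancy factor is exactly `2.51^2 = 6.3001` and cannot be resolved from
the source text (it could be a dropped constant or an implicit ≈6.3-year
generation-time multiplier). New analyses default to `formula`; the
reproduction harness uses `paper_match`. Results are in generations and
labelled as years only under a one-year generation assumption. Maternal
markers use female dispersal (1.5–5.0 km); biparental markers use the
male/female average (0.5–3.0 km).

## Restriction typing

The wet-lab assay scores an amplicon digest on a gel: two bands (one cut) =
coastal, one band (no cut) = interior. The in-silico analogue counts
leftmost non-overlapping occurrences of the recognition motif on either
strand (a physical digest cuts each site once; `N` never matches; degenerate
IUPAC motifs are rejected rather than silently mismatched). The default
motif is the BsrDI recognition sequence GCAATG — the enzyme is what the
assay used; the motif default is a package choice and is configurable.
Amplicons are linear, so fragments = cuts + 1. More than two bands yields an
"ambiguous" call, which per-site tabulation excludes with a warning.

## Genotype QC

Both QC tests are conditional Monte-Carlo exact tests with
`p = (1 + #{permuted >= observed}) / (1 + B)`.

- **HWE**: the observed allele pool at a locus is held fixed and re-paired at
  random; the statistic is the chi-square distance of the genotype-class
  counts from their re-pairing expectation (`E[n_ab] = 2 n c_a c_b / (2n
  (2n-1))`, `E[n_aa] = n c_a (c_a - 1) / (2n (2n-1))`). For biallelic data
  this is a monotone function of the heterozygote count, and the tests
  verify the Monte-Carlo p against the exact Levene distribution; the
  chi-square form was chosen over the raw het count because its
  near-continuous support for multiallelic loci keeps the p-value calibrated
  (measured type-I error 4.2–5.0% at alpha = 5% over thousands of null
  loci), where a pure het-count statistic is one-sided and heavily tied.
- **Linkage**: the G-statistic of the two-locus genotype contingency table,
  with the null generated by permuting individuals at one locus.

Bonferroni correction treats all (population × locus) tests as one family by
default (switchable to per-locus families). A locus is dropped when its
corrected failures occur in more than `max_failing_populations` populations
(default 5 — the emulated workflow's "many populations" is not quantified in
its source, so this is a package choice, exposed in config); loci failing in
1–5 populations are reported as a borderline set for sensitivity reruns.

## Admixture model

The standard unsupervised admixture model: each allele copy of individual
`i` originates from cluster `k` with probability `q_ik`; cluster `k` carries
per-locus allele frequencies with a Dirichlet(`lambda` = 1) prior
(independent across clusters — the correlated-frequencies prior is not
implemented; the Q-score contract, not the prior, is what the cline stage
consumes); `q_i ~ Dirichlet(alpha, ..., alpha)`. Inference is Gibbs sampling
over (z, p, q), fully vectorised over allele copies; missing genotypes are
skipped. The reported Q is the posterior mean.

`alpha` is fixed, not sampled. The default is 0.1: implementations that
sample `alpha` converge to small values for strongly structured data, and
with a flat `alpha = 1` the prior alone pulls a pure individual's
posterior-mean Q about `1/(2 alpha + 2 L)` off its vertex (≈ 0.036 at L = 13
loci) before any misassignment noise, which misrepresents parental
individuals. Measured on planted zones, `alpha = 0.1` gives parental RMSE
0.02–0.04 and overall RMSE 0.05–0.07 at divergence 0.6–0.8.

The successive-splitting strategy runs K = 2 at each node, sets aside
admixed individuals (max-Q < 0.80), and recurses only when at least half of
each cluster's members are confidently assigned. The split decision itself
uses a flat ancestry prior (`alpha = 1`): a vertex-seeking small `alpha`
polarises even homogeneous groups into confident noise clusters and the
stopping rule would never fire. The stopping rule is a package stand-in —
the emulated workflow's "no further clustering" criterion was judgment by
its authors. Label switching across runs is repaired by optimal assignment
(Hungarian algorithm) on summed |ΔQ| against the first run.

## Synthetic zones

The generator imposes the study conditions directly rather than simulating
forward-time dynamics (no explicit hybrid-female sterility, no sex-biased
dispersal mechanics — marker-specific cline widths are the *premise*, and
the pipeline's job is to recover them):

- 13 sites over 0–600 km (the emulated transect's scale), 20 individuals
  per site by default; a 1–28 random site-size mode mirrors the real
  sampling design's range.
- truth clines: mtDNA width 131 km and nuclear width 331 km, both centred
  at 300 km.
- individual ancestry `q ~ Beta(m nu, (1 - m) nu)` with `m` the nuclear
  cline value and concentration `nu = 10` (a free choice: no within-site
  ancestry variance is published for this system; `nu = inf` gives the
  deterministic shortcut used by oracle tests). Expected ancestry within
  1e-3 of 0 or 1 is clamped to exactly 0/1, so far-flank sites contain
  exactly parental individuals, as reference populations outside a real
  zone do.
- parental allele pools: per locus a Dirichlet(1,...,1) base vector plus two
  private components on disjoint allele halves, mixed as `(1 - d) base + d
  private`; the total-variation distance between pools is exactly the
  divergence `d` (default 0.8; `d = 1` gives fully private alleles). Each
  allele copy is drawn from `q P_interior + (1 - q) P_coastal`.
- mtDNA class: Bernoulli(mt-cline value); amplicon sequences are random
  motif-free backbones, with exactly one motif insertion for coastal
  individuals (verified against a brute-force two-strand scan).
- phenotypes: six morphometrics (mm) and three ordinal 1–6 plumage scores,
  linear in true ancestry plus Gaussian noise, plumage discretised by
  rounding. Defaults encode the observed contrast — plumage spans its scale
  across the ancestry gradient, morphometrics are ancestry-independent — so
  the association stage has a known pattern to recover.

What passing on these data shows: the estimators recover the parameters of
the generating model at realistic sample sizes, the model-selection and
significance rules behave as intended under their own assumptions, and the
pipeline detects a planted mito-nuclear width mismatch. What it does not
show: robustness to features of real microsatellite data absent here —
null alleles, stutter, allele-size homoplasy, spatially varying sampling
effort, within-site family structure, or selection against hybrids shaping
cline tails.

## Problem sizes and numerical choices

Default desk-scale budgets (all overridable): MH pilot 10,000 iterations and
3 × 50,000 main draws for single fits (3,000/3 × 10,000 inside the
pipeline; 1,500–2,000/2 × 5,000–6,000 inside replicated model-selection
studies); Gibbs 500 burn-in + 2,000 draws for pipeline Q-scores (2,000 +
8,000 in the analysis scripts); 9,999 permutations for single QC tests, 499
inside large calibration sweeps. These budgets were chosen so the full
simulation studies (50-replicate coverage, 30 model-selection replicates,
10 pipeline replicates) complete in minutes on one core; all were checked
against their oracles (grid-search ML within 0.5 log-units in every
replicate; enumeration agreement for QC).

Degenerate inputs: monomorphic loci give p = 1 with a flag; zero-n sites are
excluded with a warning; a zero-variance trait is a named error in PCA and a
flagged "ns" in regression; empty sites are excluded with a warning.
Frequencies are oriented so the interior class increases with distance; a
direction flag flips data, never the model.

## Known limitations

- The generator's phenotype module draws morphometrics independent of
  ancestry by default; it cannot, by construction, probe environment–genotype
  confounding.
- 2-LL intervals from finite MCMC samples are conservative-length
  approximations; very short chains shrink them.
- The admixture model omits the correlated-frequencies prior and alpha
  updating; Q-scores for weakly diverged pools (divergence < ~0.3) are
  noisy and the K = 2 split rule will often (correctly) refuse to split.
- The q-mean binomial likelihood discretises `n * mean_q`; for sites with
  very few individuals this coarsens the nuclear cline likelihood.
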