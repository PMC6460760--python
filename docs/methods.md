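# Methods

This note documents the models behind `hybridzone`, the choices made where
the design was genuinely open, and what the simulation-based tests do and do
not demonstrate.

## Data model and polarization

Genotypes are stored losslessly as the dose (0/1/2) of a locus's alternate
allele, with missing as a first-class code; depth, when present, must be
positive wherever a call is present. Nothing at the I/O layer knows which
allele belongs to which taxon. Polarization — recoding each diagnostic
locus so that 2 means homozygous for the B-associated allele — happens once,
in the ancestry stage, taking the B-associated allele to be whichever allele
is the more frequent in the B parental reference panel. After δ-filtering
the two parental frequencies are far apart, so this rule is unambiguous; a
locus with exactly equal parental frequencies cannot be polarized and is an
error rather than a silent coin flip.

## Diagnostic loci

For a biallelic locus the interspecies allele-frequency differential reduces
to δ = |p_A − p_B|, where p are alternate-allele frequencies estimated by
allele counting within each parental panel only (admixed candidates never
contribute). δ = 1 ("fixed difference") is decided on the *observed allele
sets being disjoint* — one panel shows only one allele and the other panel
only the other — rather than on a floating-point comparison with 1, which
avoids tolerance artefacts and matches the counting semantics of fixation.
Consequently a δ = 1 call is conditional on sampling: a rare shared allele
unobserved in a finite panel can masquerade as fixed. The simulator-based
test quantifies exactly this: with 50 allele copies per side, the empirical
δ of a weakly-to-strongly differentiated locus is within 0.1 of truth at the
rate predicted by its binomial sampling error (≈ 84–100% depending on the
frequencies, ~93% over the default mix), and the δ = 1 set equals the
engineered fixed set when no such masking occurs.

Filters run in a fixed order — depth masking, then call rate, then MAF,
then group presence — because depth masking changes the call rate; the
filter report is therefore interpretable as sequential attrition. MAF is
computed over all non-missing calls in all groups by default
(`FilterParams.maf_scope="overall"`), with a parental-only option.

## Hybrid index and heterozygosity

The likelihood treats loci as independent. With B-polarized parental
frequencies (p_A,ℓ, p_B,ℓ) and mixing proportion h, the B-allele dose at
locus ℓ is Binomial(2, qℓ) with qℓ = h·p_B,ℓ + (1−h)·p_A,ℓ. Each
log-likelihood term is a sum of logs of functions affine in h, so the total
is strictly concave on [0, 1]. The MLE is therefore found by Brent root
finding on the score function (derivative of the log-likelihood), with the
boundary taken when the score does not change sign — no multi-start
optimization is needed, and at fully diagnostic loci (p_A = 0, p_B = 1) the
root is the allele-counting estimator B-dose/(2·L) to machine precision,
which the tests assert at 1e−9. Parental frequencies enter as point
estimates; no uncertainty is propagated, matching standard codominant
usage. The reported support interval is the set of h within 2
log-likelihood units of the maximum.

Interspecific heterozygosity is the fraction of scored diagnostic loci with
polarized dose 1. At non-fixed (δ ≥ 0.8) loci this counts heterozygosity
for the A- vs B-*associated* alleles, the natural extension when true
origin is unobservable; it inflates H for individuals backcrossed toward
the taxon whose panel still segregates at those loci, which is a property
of the locus set, not a bug.

Class assignment partitions the (h, H) unit square totally: pure at h
exactly 0 or 1; F1 when H ≥ 0.85 (flagged "boundary" if h is outside
[0.25, 0.75]); otherwise backcross A for h ≤ 0.25, backcross B for
h ≥ 0.75, multigeneration in between. The boundary h = 0.25/0.75 with low
H resolves to the backcross class. Because a first-generation backcross has
*expected* h exactly on the boundary, roughly half of realized BC1
individuals necessarily land on the multigeneration side; recovery tests
therefore score the pipeline against the class implied by each simulated
individual's realized ancestry, which is the strongest property threshold
rules of this form can have, and additionally require perfect recovery of
the unambiguous pure and F1 pedigrees.

## Genomic clines

Per locus, a three-category multinomial logistic regression of genotype on
the genome-wide hybrid index (linear predictors by default; quadratic
available via `degree=2`) is compared with the neutral-admixture model in
which individual i's genotype is Binomial(2, qᵢ(hᵢ)) — the same mixing
model as the hybrid-index likelihood, which is the only internally
consistent choice of neutral expectation. Only admixed-group individuals
enter the fit; parental panels contribute solely through allele
frequencies.

The multinomial NLL is convex, so fitting uses damped Newton iterations
(analytic gradient and Hessian) with backtracking; coefficients are clipped
at |β| ≤ 30 to handle complete separation (a clipped fit is flagged, and a
bounded L-BFGS-B fallback guards any Newton stall). Genotypes impossible
under a degenerate q use a floored probability of 1e−12 and are counted in
a warning.

Significance is by parametric bootstrap: `n_sims` (default 1000) neutral
datasets are simulated at the observed h values, each refitted, and
p = (1 + #{LR_s ≥ LR_obs}) / (n_sims + 1) — the add-one estimator, so p is
never 0 and never below 1/(n_sims+1). The identical simulations provide the
genotype deviation summary: each class's observed count against the 2.5th
and 97.5th simulated percentiles, rendered "AA Aa+ aa−" style. Two
family-wise corrections are reported side by side: the harmonic-sum
adjusted level α/Σ₁..k(1/i) (Benjamini–Yekutieli-style single threshold,
e.g. 0.013 at k = 23, 0.011 at k = 50, 0.009 at k = 152) and
Benjamini–Hochberg adjusted p-values (via statsmodels). Per-locus seeds are
spawned deterministically from the run seed, so identical configurations
give identical p-values and deviation strings.

Calibration is tested at 200 neutral loci × 50 admixed individuals ×
500 bootstrap replicates (the rejection count must fall in the 99% binomial
interval around 0.05); power is tested against simulator loci with
transmission distortion b = 0.4 and against constructed heterozygote-deficit
loci, which must be flagged with "Aa−". These sizes keep the full test
suite within a few minutes on one core while leaving the binomial interval
narrow enough to be informative.

## F_ST and PCA

Between-group differentiation uses the Weir–Cockerham (1984) θ for two
populations and two alleles, with variance components summed over loci
(ratio of sums) rather than averaged per locus; loci need at least two
called individuals per group to contribute, small negative estimates are
reported unclamped, and the estimator is invariant to polarization and
group order. No per-locus significance zeroing is applied before averaging,
so parity with pipeline tools that apply such corrections is approximate by
design. Genotype PCA mean-centres per locus, imputes missing calls to the
locus mean (which visibly pulls high-missingness individuals toward the
origin — a realistic artefact, deliberately not hidden), and uses SVD;
component signs are fixed by forcing each component's largest-magnitude
loading positive.

## Plumage

Six integer trait scores (cheek patch 0–2, the rest 0–4) become proportions
of their trait maxima; the phenotype hybrid index is their unweighted mean
over available traits, so a missing rump simply averages five traits. Both
PCA variants (drop individuals missing rump vs drop the rump trait)
standardize traits to unit variance first. The hybrid zone's geographic
extent is operationalized as: an individual is "in zone" if its index is
strictly inside (0.2, 0.8), or if its 0.25° latitude bin contains both a
< 0.1 and a > 0.9 individual (parental phenotypes co-occurring); latitude
bounds are the min/max over qualifying individuals and longitude bounds are
taken over in-band individuals inside those latitudes. The band, bin width
and thresholds are arguments.

## Simulator

The simulator is the validation instrument, and its defaults mirror the
motivating study design: 40 + 21 parental reference individuals, a
~16-bird admixed group, a locus panel with ~3% fixed differences and ~9%
at δ ≥ 0.8 among mostly weakly differentiated loci, 5% missing calls, and
plumage noise sd 0.05 with extra cheek-patch noise at low ancestry.
Individuals are built by explicit pedigree (F1; F2; BC1/BC2 to either side;
MULTIGEN_k = k successive hybrid×hybrid generations), with two tracked
haplotypes per bird carrying both allele state and parental origin, so
ground-truth h and H are the *realized* per-genome values, not pedigree
expectations — parameter-recovery tests compare like with like.
Transmission distortion (B-origin allele transmitted with probability
½ + b from origin-heterozygous parents) generates exactly the
genotype-frequency departures the cline test targets, without a viability
model. Geography places A-like birds (ancestry ≤ 0.2) north of a
configured latitude band, B-like birds south of it and intermediates inside
it, with intermediates also confined to a longitude band.

What the simulator does *not* emulate — linkage, mutation, genotyping
error beyond missingness, spatially explicit dispersal, coalescent-depth
shared polymorphism — bounds what green tests mean: they validate the
estimators and the pipeline under the models' own assumptions (unlinked,
exchangeable loci), not robustness to their violation on real data.

## Numerical conventions

Probability floor 1e−12 in neutral likelihoods; hybrid-index root found to
1e−12 in h; cline coefficients bounded at ±30; LR values in (−1e−6, 0)
from convergence tolerance clamped to 0; tiny-negative F_ST left as is.
Undefined quantities (all-missing individuals, frequency-undefined loci)
are NaN-flagged and excluded from rankings, never imputed.
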