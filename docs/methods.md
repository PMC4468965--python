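# Methods

This note records the models behind `noisereg`, the assumptions they make,
the defaults chosen where the design was genuinely open, and what the
synthetic data do and do not establish.

## Noise model

Per-cell fluorescence distributions are treated as log-normal, so a
promoter is summarised by the mean and variance of log-fluorescence; the
variance is the noise statistic throughout, equivalent to the squared
coefficient of variation when fluctuations are small relative to the mean.
Natural logarithms are used everywhere; variances are therefore
dimensionless and means are in log GFP-molecule units. An optional,
off-by-default conversion shifts raw log FACS intensity to GFP-molecule
units by the constant log(2.88).

The minimal-variance curve combines three ingredients: a background
fluorescence `n_bg` common to all cells; an intrinsic component `β/⟨n⟩`
from burst-like production, with β a renormalized burst size (in the
unrenormalized limit the variance of the molecule count is (b+1)⟨n⟩ with
b = β − 1); and an extrinsic asymptote `σ_ab²`, the relative variance of
the product of transcription, translation and decay rates across cells.
The curve is exact only in the small-fluctuation regime in which the
log-variance expansion is valid; it is monotone decreasing far above
background whenever β > 2·σ_ab²·n_bg, which holds for all parameter values
of practical interest here (β ≈ 450, σ_ab² ≈ 0.025, n_bg ≈ 100).

**Floor fitting.** How the floor is fitted to a promoter cloud is a design
choice. We bin promoters into `n_bins = 20` equal-count bins of mean
log-expression, take within each bin the promoter at the
`envelope_quantile = 5`th percentile of variance (using that promoter's own
mean avoids binning bias), and least-squares fit the closed form to those
envelope points (`scipy.optimize.curve_fit`, parameters bounded below by
zero). The 5th percentile, rather than the minimum, keeps single
low-variance outliers from dragging the floor down. `n_bg` is fixed from
configuration when background controls are available and co-fitted
(bounded above by the smallest observed mean) otherwise; co-fitting is the
less stable path and gets wider recovery tolerances in the tests.
Preconditions: at least 20 promoters spanning at least one decade of mean
expression, otherwise a two-parameter envelope is unidentifiable and the
fit refuses.

**Excess noise** is variance minus the fitted floor at the promoter's
mean. It is reported unclipped — slightly negative values carry
information about fit error — with clipping at zero available for analyses
that need non-negativity.

**Robust moments.** Per-cell samples contain debris/doublet outliers. The
default estimator fits, by EM, a two-component mixture of a Gaussian
signal and a uniform outlier component spanning 2× the observed range,
initialised from 1%-trimmed moments with outlier weight
`outlier_fraction_prior = 0.01`; the reported moments are those of the
Gaussian component. A non-iterative fallback (`method="clipped"`) takes
median/MAD pilot estimates and the bias-corrected moments of values within
4 robust SDs. A fixed symmetric trim was rejected: under one-sided
contamination it trims asymmetrically into the genuine data and moves the
variance by ~5% even when the trim fraction matches the contamination.

## FACS selection and sort-and-mutate evolution

The sorter is a Gaussian acceptance function with target μ* and width τ
(defaults from the fitted medium-expression gate: μ* = 8.1, τ = 0.03, both
in log GFP-molecule units). Integrating it over a genotype's Gaussian
expression distribution gives the closed-form genotype fitness; the
probabilistic per-cell acceptance mode realises this expectation exactly,
and a rank mode (keep the k cells nearest the target, the literal top-5%
gate) is provided — the two coincide in the regime where the Gaussian gate
was fitted.

Evolution is simulated at the phenotype level; sequences are out of scope.
Each lineage receives a Poisson number of effective mutation events per
round with zero-event probability 1 − `p_mutate` (default p = 1 − e⁻²,
i.e. Poisson mean 2, so ~95% of lineages carry 0–4 events — the
phenotype-level analogue of 0.01/bp mutagenesis of a ~200 bp promoter).
Each event perturbs the mean by N(0, `rate_mu`²) with `rate_mu` = 0.1: a
typical point mutation shifts expression by ~10%, large regulatory-site
hits being rarer.

The noise channel is deliberately multiplicative. When floor parameters
are supplied, a lineage's variance is decomposed as floor(e^μ) + excess
with heritable excess ≥ 0; each mutation event rescales existing excess by
exp(N(0, `rate_sigma`²)), `rate_sigma` = 0.3. Mutation therefore modulates
noise-generating promoter architecture where it exists but cannot push a
lineage below the physical floor, and a population initialised exactly on
the floor stays there — which is the package's modelling statement of
"low noise is the default state". The alternative, an additive kernel that
creates excess de novo, makes any floor-initialised population drift
upward at a rate set by the kernel scale; nothing in the data model
constrains that scale, and the observation the simulator is built to
reproduce (evolved synthetic promoters sit at the floor) argues it is
small. Users wanting to quantify residual selection on noise can seed the
population with excess (the σ-dependence of the genotype fitness is then
active; see the excess-seeded unit test) or drop `floor_params`, in which
case `rate_sigma` acts multiplicatively on total σ².

Selection never creates genotypes — mutation is the only source of novelty
— and trajectories are bit-reproducible given the seed. Degenerate runs in
which no cell passes the gate raise rather than silently continuing.

## Regulation theory

Environments enter only through the desired levels μ_e (optionally
weighted; uniform by default) and the shared fitness width τ; regulator
activity is Gaussian within each environment with a shared variance σ_r².
Holding τ and σ_r² constant across environments is what makes the closed
forms exact; per-environment heterogeneity can be explored through the
constructive (per-environment averaging) path, which is also the oracle
the closed forms are tested against, via Gaussian quadrature and direct
environment averaging.

Conventions and numerical choices:

- X ≥ 0 by definition; repression (c < 0) is absorbed into the sign of the
  effective correlation, since the gain depends on c only through X² and
  the product SX − RY.
- `dlogf` returns exactly 0 at X = 0. The basal-noise regime's supremum is
  a boundary limit (X → 0 jointly with S → ∞); quantities in that limit
  (e.g. the perfect-tracking gain Y²/2 at R = 1) are evaluated through the
  constructive log-fitness path, not the reduced 4-parameter form.
- S* = RY/X is undefined at X = 0 and raises; it diverges at the phase
  boundary, so the landscape's ridge output is NaN where X* = 0.
- Joint optimisation over (X, S) is nested bounded Brent (inner S, outer
  X, tolerances 1e-12) polished by Nelder–Mead; the tests require
  agreement with the closed-form optima to 1e-5.
- Log-fitness is reported up to an environment-independent additive
  constant; only differences are contract-bearing.
- The composite-regulator variance implements the stated cross term
  Σ_{i≠j} R_ij σ_i σ_j without coupling factors; because the diagonal term
  does carry c_i², a `weight_cross_by_couplings` flag provides the
  c_i c_j-weighted variant. The discrepancy is flagged, not resolved.
- In the worked three-environment scenario the unregulated promoter's
  "total noise 0.1" is interpreted as a standard deviation (σ² = 0.01);
  with τ = 0.03 and Y = 4 this fixes var(μ_e) and the environment spacing.

## Propagation regression

E_p = Σ_r M_pr V_r + noise is fitted by ridge regression (Gaussian prior
exp(−λV_r²/2)) with an unpenalized intercept absorbing the small baseline
excess of promoters with all-zero rows. λ is selected by repeated random
80/20 splits (default 50 repeats) maximising mean held-out variance
explained; ties go to the stronger prior; the winning λ is refit on all
promoters. The residual noise variance is unknown, so σ(V_r) uses the
curvature of the penalized objective with a plug-in residual variance
(effective degrees of freedom from the ridge hat matrix). V_r is
unconstrained by default — noise propagation is physically non-negative,
but the unconstrained fit is the reference formulation — with an NNLS-based
non-negative option. Significant regulators are those with V_r > σ(V_r),
ranked by V_r/σ(V_r), ties broken by regulator id.

## Association analyses

Expression plasticity of a gene is the mean of its squared log
fold-changes across conditions (nominally 240), on whatever log base the
input uses; missing conditions are dropped with counts reported. A
promoter's regulatory-input count is the mean number of distinct known
regulators over the genes of its downstream operon (duplicate interaction
rows are collapsed; promoters without an operon mapping are excluded and
logged). Cutoff curves report mean ± SE (sample SD/√n) of a covariate over
promoters with excess noise at or above each cutoff; the default grid is
the sorted unique excess values, and the comparison is inclusive (≥) so
the minimal cutoff reproduces the grand mean — a strict (>) mode is
available. High-noise enrichment between two groups is a one-sided exact
hypergeometric tail on the pooled 2×2 table at the chosen threshold
(default 0.05, in excess-noise units).

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analyses assume:
log-normal per-cell expression on a floor-plus-excess variance (excess
exponential with mean 0.08 on half the promoters — long-tailed, like
native excess distributions; the family is a fixture choice), means
uniform over log-expression 6.5–9.5 (the medium-to-high window around the
μ* ≈ 8.1 gate, spanning >1 decade so the floor is identifiable), optional
gross outliers; regulator activity profiles hitting target (R, S) exactly
by orthogonal construction; Bernoulli(0.1) incidence networks of 1000
promoters × 20 regulators with exponential(0.05) strengths and Gaussian
noise at 2× the signal SD (so the planted signal fraction is 0.2);
and plasticity matrices whose per-gene variance is 0.3 + 3·excess.

They do not emulate: non-Gaussian flow artefacts beyond point outliers,
correlated transcription-factor activity fluctuations (the attribution
model itself assumes independence), operon structures more complex than
the mappings supplied, sequence-level genetics, or measurement batch
effects. Passing tests therefore establish correctness of the methods
under their own model assumptions — parameter recovery, oracle identities,
planted-structure detection — not robustness to the full messiness of
experimental flow data.

## Problem sizes

Defaults were chosen so the full suite and the acceptance script each run
in well under a minute of compute: 480 promoters × 5000 cells for floor
fits, 2×10⁵ sorted cells × 5 rounds for the evolution runs, 100 random
draws for oracle identities, 20×20 optimisation grids, 1000×20 networks
with 20–50 cross-validation repeats. All are comfortably past the point
where the checked properties stabilise; scaling them up changes nothing
qualitative.

## Known limitations

- The closed-form theory assumes Gaussian fitness functions and expression
  distributions; truncation-style (rectangular) selection is approximated,
  not represented.
- Fitness is evaluated, not fixed: there is no population-genetic dynamics
  of regulatory alleles, and a single gene is analysed (no multi-gene
  co-evolution).
- The ridge attribution assigns one propagation strength per regulator for
  all its targets and treats regulator fluctuations as independent; it
  attributes variance on a fixed, given network and does not infer edges.
- The floor fit's envelope quantile trades robustness against a small
  downward bias when fewer than ~5% of promoters in a bin are floor-level;
  populations where nearly all promoters carry excess noise need a lower
  quantile or an explicit mixture approach.
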