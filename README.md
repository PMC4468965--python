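# noisereg

Tools for asking how natural selection shapes gene expression noise — and
for the counter-intuitive answer that noise propagated from transcription
factors to their targets can itself be a selected, rudimentary form of gene
regulation.

The package is written for systems biologists analysing flow-cytometry
promoter libraries (native or laboratory-evolved synthetic promoters in
*E. coli*) and for modellers of regulatory evolution. It implements four
connected pieces:

1. **Noise floor and excess noise** (`noisereg.noise_model`).
   Expression noise is the variance of log-fluorescence across isogenic
   cells. Intrinsic (burst) and extrinsic (global rate) fluctuations impose
   a strict lower bound as a function of mean expression ⟨n⟩ (GFP-molecule
   units, background n_bg):

       var(log n) = σ_ab²(1 − n_bg/⟨n⟩)² + (β/⟨n⟩)(1 − n_bg/⟨n⟩)

   with β a renormalized burst size and σ_ab² the relative variance of the
   product of transcription/translation/decay rates. The floor is fitted to
   the lower envelope of a promoter population; a promoter's **excess
   noise** is its variance above the floor at its mean.

2. **FACS sort-and-mutate evolution** (`noisereg.selection_sim`).
   A sorter that keeps cells with probability exp[−(x−μ*)²/(2τ²)] gives a
   promoter genotype (mean μ, variance σ²) the fitness

       f(μ,σ | μ*,τ) = √(τ²/(τ²+σ²)) · exp[−(μ−μ*)²/(2(τ²+σ²))]

   The simulator runs rounds of cell-level sorting and phenotype-level
   mutation and shows the library's defining property: mean-targeted
   selection pulls μ onto the gate while excess noise stays at its floor
   default.

3. **Fitness theory of regulatory coupling** (`noisereg.regulation_theory`).
   Across environments e with desired levels μ_e and fitness width τ,
   coupling a promoter to a regulator (correlation R with μ_e,
   signal-to-noise S, renormalized coupling X, expression mismatch
   Y² = var(μ_e)/(σ²+τ²)) changes log-fitness by the closed form

       d log f = ½ [(X²+R²)Y² − (SX−RY)²]/(1+X²) − ½ log(1+X²)

   with analytic optima S* = RY/X and X*² = max[0, (1−R²)Y²−1], and a phase
   boundary (1−R²)Y² = 1: above it regulation keeps basal noise, below it
   noise-propagation is positively selected and the optimal total noise is
   σ_tot² = (1−R²)·var(μ_e) − τ². Composite (multi-regulator) and iterated
   regulation are included.

4. **Noise-propagation attribution** (`noisereg.propagation_regression` and
   `noisereg.association_analysis`). Excess noise is modelled as
   E_p = Σ_r M_pr V_r + noise over a binary regulatory network, fitted by
   ridge regression with cross-validated prior strength; association
   analyses (cutoff running means, enrichment, CDFs) reproduce the
   descriptive links between excess noise, expression plasticity and
   regulatory inputs.

A `synthetic_data` module generates every input with known ground truth, so
the full pipeline runs and is tested without any external download.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```sh
python analysis/01_simulate_data.py --seed 0
python analysis/02_noise_floor.py
python analysis/03_selection_simulation.py --seed 0
python analysis/04_regulation_theory.py --seed 0
python analysis/05_propagation_fit.py --seed 0
python analysis/06_associations.py
```

Script 02 fits the noise floor on 480 simulated promoters (generating
parameters σ_ab² = 0.025, β = 450) and prints:

```
floor fit: sigma_ab2 = 0.0250 (generating 0.025, error 0.0%), beta = 450.0 (generating 450, error 0.0%)
excess of 238 planted-zero promoters: mean -0.0000 (5th-95th pct -0.0000..+0.0000, straddles 0)
```

Script 03 evolves a library (means uniform over μ* ± 2, noise on the floor)
through five rounds of the fitted gate (τ = 0.03, μ* = 8.1) at 2×10⁵ cells
per sort:

```
mean |mu - mu*|: 1.005 -> 0.209 over 5 rounds
max |realized - analytic| selected fraction: 0.00116
mean excess noise constant at 0: no noise selection signature
```

i.e. the realized selected fraction tracks the analytic genotype fitness to
~0.1%, the mean converges on the gate, and noise stays at the floor —
promoters are low-noise by default under mean-targeted selection.

Script 04 scores three candidate regulators for a promoter with mismatch
Y = 4 (basal σ = 0.1, three environments):

```
 regulator      R      S  gain_dlogf  X_star  sigma_tot2_at_optimum
  accurate 0.9500 5.0780      7.2777  0.7483                 0.0161
pure-noise 0.0000 0.0500      6.1125  3.8730                 0.1735
mismatched 0.6400 6.0000      4.0392  2.9063                 0.1021
```

The completely uncorrelated, noisy regulator (gain 6.11) beats the
moderately correlated one whose signal-to-noise exceeds S*(R) (gain 4.04):
pure noise-propagation acting as a bet-hedging, rudimentary regulation.

Script 05 recovers planted propagation strengths from the 1000 × 20
network with noise at twice the signal SD:

```
selected lambda = 10; variance explained = 17.4% (held-out 14.3%)
correlation of fitted V with planted V_true: 0.913
```

## Layout

```
src/noisereg/    library (all computation lives here)
analysis/        numbered narrative drivers writing results/ tables
tests/           pytest suite, including end-to-end property checks
scripts/         acceptance.py
docs/methods.md  model assumptions, parameter choices, limitations
```
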