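# Methods

## Prediction model

The predictor is an ε-insensitive support-vector regression with an RBF
kernel on two features: the adduct-form molecular polarizability (Å³) and
*m/z* (Da per unit charge, equal to the ion mass for |z| = 1). Features are
min–max scaled to [0, 1] using statistics of the training set only; the
target (CCS, Å²) is **not** scaled, so the tube half-width ε is in Å². The
grid values ε ∈ {0.01, 0.1, 1} are therefore small relative to typical CCS
values (~100–350 Å²), which makes the fit behave like a robust
least-absolute-deviation interpolant with the C term controlling
smoothness. Scaling the target instead would reinterpret the same ε values
as a few tenths of the CCS range; the unscaled-target reading is the
documented interpretation here, and the epsilon grid is exposed so either
convention can be run.

Hyperparameters are chosen by 5-fold cross-validation over the fixed grid
C ∈ {10², 10³, 10⁴, 10⁵, 10⁶}, γ ∈ {0.01, 0.1, 1}, ε ∈ {0.01, 0.1, 1}
(45 combinations, single kernel). Design choices, each genuinely open:

* **CV scoring** is the mean relative error, the same statistic used for
  reporting, so tuning optimizes what is evaluated.
* **Folds** are contiguous blocks of a seeded shuffle; the fold seed is
  recorded so any iteration can be reproduced in isolation.
* **Ties** go to the first grid point in the documented iteration order
  (kernel, C, γ, ε).
* The fold-internal scaler is re-fit on each fold's training portion; no
  statistic of a held-out block ever reaches the model.

The quadratic program is solved by libsvm (through scikit-learn).
`train_svr` solves to optimizer tolerance; inside the repeated-evaluation
protocol the SMO iteration count is capped at 50,000 per fit. The cap only
binds in the extreme-C corner of the grid (C ≥ 10⁵ with γ = 1), where the
dual refinement costs ~10⁶ iterations while changing the protocol's mean
MRE by about 0.04 percentage points (measured by running both ways); it is
a numerical throughput choice, exposed as `solver_max_iter`/`max_iter` and
set to −1 for exact solves, which the oracle-equivalence tests use.
Trained models persist as self-describing JSON (feature names, scaler
min/max, hyperparameters, support vectors, dual coefficients, bias), so
predictions survive column reordering and require no pickle.

## Evaluation protocol

One iteration = seeded random split → grid search by 5-fold CV on the
training part → train → predict the held-out part → MRE
(mean(|pred − obs|/obs) × 100). The canonical split is 70 training / 18
test records: on an 88-record ion mode this is exactly an 80/20 split, and
using the same absolute sizes in both ion modes keeps their accuracies
comparable. The full protocol default is 10,000 iterations; scaled-down
runs are first-class because per-iteration seeds derive from the master
seed by a counter scheme (`SeedSequence(master, spawn_key=(i,))`), giving
the prefix property: a 200-iteration run is bit-identical to the first 200
iterations of a 10,000-iteration run. The ± spread quoted with a mean MRE
is the standard deviation of the per-iteration MRE distribution (the result
object exposes the full distribution, so any other interval can be
formed). Learning curves hold the test size fixed at 20 records across all
training sizes; sizes below the fold count fall back to leave-one-out CV.
Cross-instrument divergence is the MRE of traveling-wave CCS against
matched drift-tube CCS with the drift-tube value as reference
(denominator), joined on (compound, adduct type).

The acceptance script runs the repeated-split protocol at 200 iterations
and the learning curve at 25 iterations per size — sizes chosen so the
protocol's sampling spread (reported alongside the mean) is small relative
to the quantities of interest.

## Association analyses

*Simple fits* are ordinary least squares with R² = 1 − SSE/SST and a
mean-response confidence band (Student-t quantile; 99% default). The
band is for the mean response, not prediction, matching the "confidence
interval" reading; per-adduct agreement is judged on the **difference** of
two fitted lines against that difference's own 99% half-width
√(h_a² + h_b²) over a probe grid — each line also carries sampling error,
so testing one noisy line against the other's band alone would reject far
too often even when the underlying lines coincide. The one-sided
containment fractions are still reported descriptively.

*Interaction regression.* CCS = μ + α·P + β·X + γ·P·X + ε with P the
adduct polarizability and X either m/z or ovality, fitted as a
Gaussian-family GLM (numerically OLS) with normal-theory Wald tests. The
default fit window keeps records with m/z in [87.04, 385.35] Da
(inclusive), the densely populated small-molecule range; rank-deficient
designs (constant or collinear covariates) raise instead of fitting
silently. p-values are reported to full precision; a display of "0.000"
means p < 0.0005.

*Conditional trends.* The heat-map analysis bins records on a property
pair (default 10×10 equal-width bins over the observed ranges), averages
CCS per cell, and masks cells with fewer than 3 members. For the trend of
CCS along one axis with the other held (binned) fixed, every transect
(row or column) with ≥ 2 unmasked cells contributes a count-weighted
least-squares slope of cell-mean CCS on bin centers; transect slopes are
pooled by inverse variance using a pooled within-cell CCS variance, and the
pooled slope gets a two-sided normal-theory p-value. This pooled-transect
scheme is this package's own definition of "varying one property at fixed
other": it uses every usable transect rather than a single visual
transect, which makes the dichotomy (mass trend real, shape trend null)
an assertable statistic. Bin counts and the mask threshold are exposed
because no canonical values exist.

## Synthetic data

The generator draws a latent size S ~ U(8, 32) Å³ per adduct and derives
polarizability = S + offset(adduct type) (offsets 0 / −1.5 / 0 Å³ for
M+H / M+Na / M−H), volume = 10·S + N(0, 6) Å³,
m/z = −173 + 32.5·polarizability + N(0, 80) Da (clipped to ≥ 1),
ovality = 1 + |N(0.15, 0.10)|, and
CCS = 70 + 5.1·polarizability + [TWIM] 0.1·m/z + N(0, 4.4) Å².
Deriving volume from S but m/z from the offset polarizability places the
sodium shift where it belongs: sodium adducts are less polarizable than
protonated adducts of equal volume, while CCS given (polarizability, m/z)
carries no adduct label. The m/z line needs an intercept because a
through-origin line cannot span ~87–868 Da over a physical polarizability
range.

The defaults are invented calibrations, not measurements. They were fixed
analytically before any test ran: the CCS noise SD (4.4 Å²) sets the
protocol's MRE floor at σ√(2/π)/mean(CCS) ≈ 1.6%, and the conditional m/z
scatter (slope 0.1 Å²/Da × 80 Da SD) then fixes the marginal CCS-on-
polarizability R² at var(signal)/(var(signal)+σ_resid²) ≈ 0.975 at the
197-record composition (52/57/88 across M+H/M+Na/M−H). Drift-tube defaults
(108 records, 31/27/50) drop the m/z term and widen the CCS noise to
13.3 Å² — multi-source compilation scatter — giving R² ≈ 0.948. Matched
instrument pairs multiply drift-tube CCS by 1 + N(0, 0.0293), i.e. a mean
absolute divergence of ≈ 2.34%.

What the generator does **not** emulate: chemical-class clustering,
heteroscedastic measurement error, adduct-specific CCS ranges, non-Gaussian
tails, calibrant drift, or any instrument physics. Passing tests therefore
demonstrate that the pipeline recovers the designed statistical structure
at realistic sample sizes — not that a particular laboratory's data will
show the same numbers.

## Thole polarizability

Molecular polarizability is computed with the interactive induced-dipole
model: each atom carries an isotropic polarizability α_i, the 3N×3N relay
matrix has α_i⁻¹·I diagonal blocks and −T_ij off-diagonal blocks with the
damped dipole interaction tensor T_ij = λ₅·3rrᵀ/r⁵ − λ₃·I/r³, and the
molecular tensor is the sum of all 3×3 blocks of the relay inverse
(isotropic value = trace/3). Supported damping forms, on the reduced
distance u = r/(α_i α_j)^{1/6}: the exponentially decaying charge-density
form (default, shipped factor 2.1304 with a published per-element
polarizability set in `data/thole_params.json`), the original
piecewise-linear form, and undamped point dipoles (for closed-form
checks). The computation runs in atomic units internally (1 Å = 1/0.52918
bohr; polarizabilities converted by 0.52918³) for relay-matrix
conditioning. A non-positive-definite relay matrix — the polarization
catastrophe of undamped dipoles at short range — is detected by Cholesky
factorization and raised with advice to enable damping. The adduct's net
charge does not enter the model (a deliberate simplification: the
calculation is on the neutral-framework geometry), and reproducing any
specific commercial implementation's numbers is out of scope since their
parameterizations are undocumented; the shipped Na⁺ and P values are
transferable estimates flagged in the parameter file.

## Limitations

* The MRE floor of the synthetic study conditions is homoscedastic; real
  CCS error grows with m/z and differs by chemical class.
* The repeated protocol re-tunes hyperparameters every iteration. That is
  the expensive, leak-free reading of the protocol; at 10,000 iterations it
  is a long run, which is why the prefix property and scaled-down defaults
  exist.
* The conditional-trend pooling assumes a common within-cell variance
  across the grid; strongly heteroscedastic data would need per-cell
  variances (stored in the grid, so the extension is local).
* Thole isotropic polarizabilities depend materially on the element set
  and damping factor; treat absolute values as parameterization-relative.
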