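# Methods

## Model

Each spectroscopic label y (R_e in Å, ω_e in cm⁻¹, or a binding-energy label
in eV-derived units) is modeled as a Gaussian process with explicit basis
functions,

    y(x) = h(x)ᵀβ + f(x) + ε,   f ~ GP(0, k),   ε ~ N(0, σ_y²).

The parametric mean h(x)ᵀβ is either a constant (intercept only) or linear
(intercept plus one slope per feature); β is estimated by generalized least
squares under the kernel covariance, i.e. the vague-prior ("ordinary/universal
kriging") treatment of the basis coefficients, and the same correction term
enters the predictive variance. Distances are Euclidean on z-scored features
(training-split statistics only), so a single isotropic length scale is
meaningful across mixed-unit feature sets. Two kernels are provided:

* exponential, k(r) = σ_f²·exp(−r/l) — rough (Ornstein–Uhlenbeck-like)
  sample paths; used with the linear basis for equilibrium distances;
* Matérn 5/2 — twice-differentiable paths; used with the constant basis for
  frequencies and the binding label.

This pairing mirrors the observation that R_e varies with a strong linear
trend in the period average while frequencies and well depths are smoother,
trendless functions of the descriptors. Both choices are estimator
parameters, not hard-coded.

### Hyperparameters

(σ_f, l, σ_y) are set by maximizing the log marginal likelihood with β
profiled out (the GLS optimum makes the envelope-theorem gradient exact), in
log-space with L-BFGS-B and analytic gradients. Defaults:

| parameter | bounds (standardized units) | start | rationale |
|---|---|---|---|
| σ_f | [1e-6·sd(y), 10·range(y)] | sd(y) | brackets any plausible signal scale |
| l | [1e-2, 1e3] | 1.0 | z-scored features put typical spacings near 1 |
| σ_y | [1e-6, range(y)] | 0.1·sd(y) | from interpolation to pure noise |

One data-driven start plus 5 random restarts (log-uniform inside the
bounds, seeded). Discrete choices — kernel kind, basis kind, feature
variant, isotope offset — are selected by stratified 5-fold cross-validation
on the training split (`nested_cv_select`), keeping the continuous ML-II
estimation inside each fold; fold RMSE is the criterion and ties resolve to
the first candidate.

### Numerical policy

The covariance Cholesky gets an initial diagonal jitter of 1e-10, escalated
×100 up to 1e-6 on factorization failure (duplicate rows from permutation
augmentation make this reachable at small σ_y); every escalation is logged.
A rank-deficient basis design falls back to a small ridge (1e-8 of the mean
diagonal) on the GLS normal matrix, logged. Predictive variances are clipped
at zero before taking square roots. Non-finite likelihood at every start is
a hard error carrying the kernel/basis/n diagnostics.

## Features

Tokens cover: per-atom group and period (g₁, g₂, p₁, p₂); isotope-aware
groups g^iso (group + δ·(mass number − 1) for hydrogen isotopes only,
δ = 0.1 by default, so H→1.0, D→1.1, T→1.2 — the smallest perturbation that
separates the isotopes without distorting group geometry; δ is
configurable); the averages ḡ, p̄ (plain groups by default, isotope-aware on
request); cross-state quantities R_e⁻¹(X), R_e⁻¹(A), ω_e(X); the
electron-transfer descriptor D(IP, EA); and transformed predictors for the
linear baselines (log Z₁Z₂, R_e⁻², √(Z₁Z₂/m)·e^(−0.97·R_e)).

D(IP, EA) defaults to the cost of moving one electron toward the more
electronegative atom: IP_donor − EA_acceptor, the acceptor being the atom
with larger Pauling χ (the average of both directions on a χ tie). The form
is symmetric in the two atoms by construction and pluggable
(`features.D_FORMS`); a χ-difference-weighted variant ships as an example.

Permutation augmentation doubles the training rows with the atom-indexed
columns exchanged (g₁↔g₂, p₁↔p₂, g^iso₁↔g^iso₂). Because the augmented set
is closed under the swap and standardization statistics are computed after
augmentation, kernel predictions for a query and its swap image are
identical to solver precision — AB and BA are the same molecule.

The predicted-distance feature R̂_e (used by the "hat" model variants) is
produced by a GP on (g₁, g₂, p₁, p₂) fitted strictly inside the current
training split, then predicted for all rows; predictions are floored at
0.5 Å before inversion (logged when active) so R̂_e⁻¹ stays finite and
positive. Fitting it per split avoids test-set leakage through the feature.

## Evaluation protocol

Labels are stably sorted and cut into 25 contiguous equal-count blocks
(quantile strata; sizes differ by ≤ 1). Quantile blocks rather than
equal-width bins keep stratification meaningful under the skewed label
distributions typical of these constants. Each Monte-Carlo repetition draws
one test molecule uniformly per stratum (round-robin allocation when the
test size and stratum count differ), giving 25-molecule test sets;
repetition i uses the seed sequence (seed, i), so the whole report is
bit-reproducible from (seed, plan). Metrics: MAE, RMSE, and
r_E = 100·RMSE/range(y) with the range fixed to the full label set of the
target view, so r_E is comparable across repetitions. Per-rep metrics are
averaged and reported mean ± sd; per-molecule as-train/as-test prediction
means, sds and mean absolute errors are aggregated alongside, and the
count-weighted per-molecule means reproduce the pooled metrics exactly.
Failed repetitions are skipped and counted; more than 5% failures aborts
the run.

Learning curves rerun the same protocol with the training split
stratified-subsampled to each size N; 500 repetitions per point by default.

## Classical baselines

Power-law rules R_e^a·ω_e^b·m^c·n^d (n = total valence electrons; group
count for s/d-block, group − 10 for p-block, 3 for the f-block under the
group-3 encoding — a convention, pluggable) are evaluated per molecule,
median-normalized, and summarized by quartiles and the coefficient of
variation. Shipped presets: Kratzer (a=2,b=2,m), Mecke–Birge (2,1), Morse
(3,1), Badger-type (3,2,m), the √m-adjusted Morse rule (3,1,m^½) and the
valence-electron rule (6,2,m,n).

Linear baselines are OLS fits on a single transformed predictor, run under
the identical split plan as the GP so comparisons are paired: R_e from
log Z₁Z₂ (slope/intercept map to the electron-density parameters
ξ̂ = 1/slope, Â = exp(−intercept·ξ̂)); ω_e from R_e⁻² or from the
transformed predictor √(Z₁Z₂/m)·e^(−ξ′R_e) with ξ′ = 0.97; and the binding
label from R_e. The binding label itself is configurable — ln(Z₁Z₂/D_e)
(default; the combination that is linear in R_e under the exponential
density model), D_e, or √D_e — with D_e = D_0 + ω_e/2 − ω_e·x_e/4 converted
at 1 cm⁻¹ = 1.239841984×10⁻⁴ eV.

## Synthetic data

The generator emulates the statistical shape of the experimental
compilations (≈250 heteronuclear molecules, R_e mostly within 1.4–3.8 Å,
partial D_0 and A-state coverage), not molecular physics. Element pairs are
drawn without replacement from a 50-element pool spanning periods 1–6
(including D). Three truth surfaces, all expressible in the baselines'
own relations so every model has a known optimum:

* `smooth_gp_surface` (default): R_e* ~ GP over (ḡ, p̄), Matérn 5/2 with
  σ_f = 0.4 Å, l = 3.0, mean 0.55·p̄ + 0.9 Å, clipped to [0.8, 4.5] Å —
  scale and spread chosen to land the bulk of R_e* in the 1.4–3.8 Å window;
* `parr_exact`: R_e* = ξ⁻¹(ln Z₁Z₂ − ln A) (defaults ξ = 2, A = 10; pairs
  whose implied R_e* leaves [0.5, 6] Å are resampled);
* `badger_exact`: the smooth mean surface plus 0.3 Å scatter.

Frequencies follow ω_e* = K/(R_e*³·√m) with K = 2×10⁴ cm⁻¹·Å³·u^½ (typical
mid-table magnitudes; exactly the √m-adjusted Morse rule), except under
`parr_exact` where ω_e* comes from the electron-density force constant.
Well depths obey D_e* = A_D·m·ω_e*²·R_e*³ with A_D = 2×10⁻⁷ (few-eV
magnitudes), ω_e x_e* = 0.01·ω_e* (typical anharmonicity scale, purely a
synthetic convention), and D_0* inverts the D_e/D_0 relation. Gaussian
noise defaults: 0.05 Å additive on R_e, 3% relative on ω_e, 5% relative on
D_0.

What passing tests on this data do **not** show: robustness to the
heteroscedastic, bond-type-dependent errors of real compilations, to
systematic disagreements between experimental sources, or to the strongly
non-smooth behavior of molecules with unusual bonding — on real data those
appear as the characteristic outliers (hydrides, van der Waals dimers)
rather than as a uniform noise floor.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the protocol at reduced
Monte-Carlo depth (tens to 200 repetitions, learning curves at 100) on
250-molecule synthetic sets; these sizes give MC standard errors well below
the effect sizes being checked while keeping the whole suite to a few
minutes. Production runs default to the full 1000/500 repetitions.

## Known limitations

* Single isotropic length scale (no ARD); deliberate, matching the kernels'
  definitions, but it makes feature scaling part of the model.
* ML-II hyperparameters are point estimates; no hyperparameter uncertainty
  is propagated, and predictive sds are used only for reporting, not
  calibrated.
* The element table is a curated snapshot (Slater radii, standard IP/EA/χ
  values, IUPAC groups with the f-block mapped to group 3); isotopes other
  than D/T are not distinguished.
* The A-state synthetic labels are a simple affine/Morse-link construction;
  they exercise the cross-state feature plumbing, not excited-state physics.
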