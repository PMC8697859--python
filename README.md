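# spectroml

Gaussian-process prediction of the spectroscopic constants of heteronuclear
diatomic molecules — the equilibrium distance R_e (Å), the harmonic
vibrational frequency ω_e (cm⁻¹) and a binding-energy label derived from
D_0 (eV) — from nothing more than the positions of the two atoms in the
periodic table.

## Who this is for

Molecular spectroscopists and ML-for-chemistry researchers who want to

* test how far periodic-table descriptors (group g, period p of each atom)
  carry in predicting R_e, ω_e and D_0 for ground (X) and first-excited (A)
  electronic states;
* benchmark such models against the classical empirical rules
  (Kratzer/Mecke/Morse/Badger-type power laws R_e^a·ω_e^b·m^c ≈ const) and the
  electron-density linear baselines (R_e linear in log Z₁Z₂);
* do all of the above under a small-dataset evaluation protocol that is
  honest about split-to-split variance.

The experimental constants compilations themselves are not bundled; any CSV
with columns `formula, state, Re, we, wexe, D0` works, and a synthetic-data
generator with known ground truth exercises every stage of the pipeline.

## The model

Labels are modeled as a Gaussian process with explicit basis functions,

y(**x**) = **h**(**x**)ᵀβ + f(**x**) + ε,  f ~ GP(0, k),  ε ~ N(0, σ_y²),

with a constant or linear basis **h** (β estimated by generalized least
squares) and an isotropic kernel on z-scored features, either

* exponential: k(r) = σ_f² exp(−r/l), or
* Matérn 5/2: k(r) = σ_f² (1 + √5·r/l + 5r²/3l²) exp(−√5·r/l),

where r is the Euclidean distance. (σ_f, l, σ_y) maximize the log marginal
likelihood (multi-start L-BFGS-B, analytic gradients); the posterior mean is
the prediction. Feature sets per target follow the named presets — e.g.
`(g₁, g₂, p₁, p₂)` for R_e, `(R_e⁻¹, g₁^iso, g₂^iso, p₁, p₂, ḡ)` for ω_e,
`(R_e, ḡ, p̄)` for the binding label — with atom-swap permutation
augmentation so that AB and BA predict identically.

Evaluation is stratified Monte-Carlo splitting: labels are sorted into 25
equal-count strata, each repetition draws 25 test molecules (one per
stratum), and MAE, RMSE and r_E = 100·RMSE/range(y) are reported as
mean ± sd over repetitions (1000 by default; 500 for learning curves), with
per-molecule as-train/as-test prediction statistics.

## Worked example

Generate a 250-molecule synthetic dataset (smooth ground-truth surface over
(ḡ, p̄), 0.05 Å noise on R_e) and evaluate the flagship R_e model:

```sh
$ spectroml synth --n 250 --seed 7 --out data
wrote 250 records to data/data.csv

$ spectroml evaluate --data data/data.csv --features preset:table1_Re_gp \
      --model GPR --n-mc 10 --seed 1 --out re_report.json
test MAE 0.06821 ± 0.011 | RMSE 0.08806 ± 0.016 | r_E 2.41 ± 0.45 %
```

The GP reaches a normalized test error r_E of ~2.4% on this data — the
prediction error is a few percent of the label range, dominated by the
injected 0.05 Å observation noise. The classical electron-density baseline
on the same data is several times worse:

```sh
$ spectroml baseline --data data/data.csv --recipe log_zz --n-mc 10 --out baseline.json
{ "recipe": "log_zz", "slope": 0.368, "intercept": 0.620,
  "xi_hat": 2.716, "A_hat": 0.186, ... }
```

(`xi_hat`, `A_hat` are the electron-density decay constant and prefactor
implied by the fitted line R_e = ξ⁻¹log Z₁Z₂ − ξ⁻¹log A; on data generated
exactly from that relation they are recovered to machine precision.)

Rule diagnostics report how constant each historical power law really is
(coefficient of variation of the median-normalized rule value; 0 = exact):

```sh
$ spectroml rules --data data/data.csv --out rules.csv
     kratzer: CV = 2.993
       mecke: CV = 1.152
       morse: CV = 0.7616
      badger: CV = 1.587
  morse_mass: CV = 0.06041
    valence6: CV = 0.4574
```

`morse_mass` (R_e³·ω_e·√m) is nearly constant here because the generator's
frequency link is built from exactly that rule; the others spread widely.

The full comparison grid (every GPR feature variant and every linear
baseline per target, paired splits) runs with:

```sh
spectroml run --data data/data.csv --grid table1 --n-mc 1000 --out results/
```

which writes `comparison.csv`/`comparison.json`, one JSON report per row and
per-row outlier listings tagged by bond type (from R_e/(R₁+R₂)).

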