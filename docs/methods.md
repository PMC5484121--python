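# Methods

## The discrimination problem

Given an experimental list of ¹H and ¹³C chemical shifts and two or more
candidate structures with computed shifts, decide which candidate the
experiment supports. Candidates are opaque named entities: they may be
constitutional isomers, protonation states (acid vs carboxylate), or
hydrogen-bonded complexes — no chemistry-aware merging is attempted, because
the question "which table of numbers matches best" is the same in every case.

## Ensemble averaging

Flexible molecules populate several conformers, so the observable shift is a
population average. Conformers enter with free energies (hartree); those
within `window_kcal` (default **3 kcal/mol**) of the global minimum are
retained — the minimum always survives, and a zero window keeps exactly the
minima — and weighted by

w_i = exp(−ΔG_i/RT) / Σ_j exp(−ΔG_j/RT),

with T = 298.15 K and R = 1.987204×10⁻³ kcal/(mol·K) by default. The
temperature is configurable; 298.15 K is the standard thermochemistry
convention of the common QM packages. When free energies are missing but
electronic energies are present, the window and weights fall back to the
latter with a logged notice. Weights are computed after subtracting the
minimum energy, so they are exactly invariant to a constant offset and never
overflow. Averaging may be applied to shieldings before scaling or shifts
after scaling; under an affine scaling the two are identical, and the
pipeline averages scaled shifts (methyl protons, for example, are reported as
the mean of the three scaled shifts via equivalence groups).

## Linear scaling

Computed isotropic shieldings relate to shifts through σ_iso = slope·δ +
intercept (slope near −1). Two entry points exist:

* **supplied models** (per element, never pooled across C and H) for
  converting raw shieldings with community reference slopes/intercepts;
* **empirical rescaling** per candidate: regress δ_calc on δ_exp and return
  (δ_calc − b)/m. This strips systematic method error (slope/offset) and is
  the standard DP4 preprocessing step. It is idempotent, leaves zero-mean
  residuals uncorrelated with δ_exp (normal equations), and makes the
  downstream statistics invariant to any affine transform of the computed
  column. A non-positive fitted slope signals an anti-correlated candidate
  and raises a warning rather than an error, since such a candidate should
  simply score terribly, not crash the run.

The bundled cereoanhydride table already contains scaled, Boltzmann-averaged
shifts; the original scaling constants behind it were never published, so
reproducing its computed columns from raw shieldings is not attempted.

## Deviation statistics

Per nucleus, |δ_calc − δ_exp| on unrounded values; MAD is the mean, MAX the
maximum. Reported numbers are rounded half-up to 1 decimal (¹³C) / 2 decimals
(¹H) — the policy matters: the acid ¹³C MAD is 1.35 ppm unrounded, which
half-up rounding reports as 1.4 while summing pre-rounded deviations would
give 1.3. Acceptability uses the community rules of thumb, <5 ppm (¹³C) and
<0.3 ppm (¹H), with strict less-than: a deviation exactly at the threshold is
unacceptable. Acceptable deviations within 0.02 ppm of the threshold are
additionally flagged "borderline" so that near-misses (e.g. a 0.29 ppm
aromatic proton) remain visible in reports.

## DP4

For candidate k with scaled errors e₁…e_n the unnormalized score is

P_k ∝ prior_k × Π_i [1 − T_ν(|e_i|/σ)],

where T_ν is the Student-t CDF. Defaults are the published DP4 parameters
σ_C = 2.306 ppm, ν_C = 11.38, σ_H = 0.185 ppm, ν_H = 14.18, with a uniform
prior; all are overridable. Carbon-only, proton-only and combined scores are
reported; the combined unnormalized score is exactly the product of the
carbon and proton scores. Numerics: scores are accumulated in log space;
any likelihood term that underflows to zero is floored at 10⁻³⁰⁰ with a
warning. Empirical rescaling precedes the error computation whenever at
least three nuclei are matched; below three points the regression is
degenerate and raw errors are used (this also makes single-nucleus toy
problems evaluate the two-term formula directly).

## Geometry and energetics

Distances are Euclidean; the NOE feasibility flag tests d ≤ 5 Å (inclusive),
the usual visibility ceiling for NOE cross-peaks; no r⁻⁶ intensity modelling
is attempted. Angles come from the clipped normalized dot product. Energy
profiles convert hartree to kcal/mol (× 627.5094741) relative to the first
species; "downhill" means every step strictly lowers the energy — ties do
not count. The bundled rearrangement profiles (anhydride → ring-opened
intermediate → acid at three DFT levels) and NOE distances are literature
fixtures: recomputing them requires DFT, which this package does not do.

## Synthetic data

The generator emulates the statistical structure of the real workflow at the
scale of the cereoanhydride problem: 16 carbons and 8 proton environments,
experimental shifts uniform over 10–180 ppm (C) and 0.5–9 ppm (H). The true
candidate's computed shifts add per-nucleus scaled Student-t noise with the
DP4 σ and ν per element (∞ df selects normal noise), so the DP4 model is
exactly matched in the well-specified regime and recovery experiments are
interpretable. Each decoy draws its own noise and is additionally perturbed
by ±5 ppm (C) / ±0.3 ppm (H) on a random half of its nuclei — the localized
few-nuclei disagreement that wrong ring systems or protonation states
actually produce. With perturbation zero, decoys are exchangeable with the
truth and recovery collapses to the symmetry baseline 1/(n_decoys+1).
Conformer ensembles draw relative free energies from an exponential with
mean `energy_spread_kcal/2` (minimum shifted to zero) and per-conformer
shieldings as a shared base pattern plus 0.3 ppm normal offsets.

What the generator does **not** emulate: correlated errors between
neighbouring nuclei, solvent/referencing offsets beyond the affine family,
exchange broadening, or any relationship between geometry and shifts
(synthetic geometries are random points). Passing recovery tests therefore
demonstrate the statistical machinery, not the accuracy of any quantum
method on real molecules.

All randomness flows through NumPy's `default_rng` (PCG64); one integer seed
reproduces every table bit-for-bit.

Monte-Carlo sizes: the recovery experiments run 200 trials per condition
(binomial s.e. ≈ 3% at p = 0.5) and the monotonicity grid 3×3 conditions at
60 trials each; both finish in seconds and give standard errors comfortably
below the margins being tested.

## Design choices made where the design was open

* **Experimental shifts are one shared column** across candidates; whether a
  study referenced each candidate's experiment separately cannot be encoded.
* **Element inference from labels** ("C11" → C, "H17-19" → H) mirrors common
  atom-numbering practice; exchangeable protons are excluded from tables by
  construction, matching how experimental lists omit OH/CO₂H signals.
* **QM-log grammar** is a minimal line-oriented pattern (`index element
  Isotropic = value`, Gaussian-style free-energy line). Restarted logs with
  several shielding blocks keep the last block, with a warning.
* **Bundled dataset with checksum**: the cereoanhydride table ships as one
  versioned CSV guarded by a SHA-256; tests and the acceptance script load
  it rather than re-typing values.
* **Indices**: the library is 0-based (Python convention); the `geom` CLI
  accepts 1-based indices as printed in QM logs.

## Known limitations

* No DP4+ (shielding-level statistics), CP3, or pKa-based population
  modelling: the carboxylate fraction in a real sample is not estimated,
  only the consistency of each protonation state with the spectrum.
* Scaled-shift inputs are trusted as given; no multi-standard absolute
  referencing is provided.
* XYZ reading goes through MDAnalysis, whose coordinates are float32
  (~10⁻⁴ Å round-trip precision) — irrelevant at the 5 Å NOE scale.
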