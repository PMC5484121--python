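# shiftsieve

Structure discrimination for natural products from computed NMR chemical
shifts.

When a candidate structure is in doubt — a misassigned ring system, an
ambiguous protonation state, a possible hydrogen-bonded complex — DFT-computed
¹H/¹³C chemical shifts can arbitrate, provided the comparison with experiment
is done carefully. `shiftsieve` packages that comparison:

* **Boltzmann ensemble averaging** over conformers within an energy window
  (default 3 kcal/mol) of the global minimum, w_i ∝ exp(−ΔG_i/RT);
* **linear scaling** of isotropic shieldings, σ_iso = slope·δ + intercept,
  with separate carbon and proton models, plus the per-candidate empirical
  rescaling of computed against experimental shifts used by DP4;
* **deviation statistics** — per-nucleus |δ_calc − δ_exp|, MAD and MAX, with
  acceptability flags at the community rules of thumb (<5 ppm ¹³C,
  <0.3 ppm ¹H);
* **DP4 probabilities** — per nucleus the likelihood term 1 − T_ν(|e|/σ)
  under a Student-t error model (defaults σ_C = 2.306 ppm, ν_C = 11.38;
  σ_H = 0.185 ppm, ν_H = 14.18), multiplied over nuclei and normalized over
  candidates to give the percent likelihood that each candidate is correct;
* **geometric feasibility** — interatomic distances against the ~5 Å NOE
  visibility cutoff, bond angles, and reaction-energy profiles in kcal/mol;
* a **synthetic-data generator** that emulates the statistics of computed
  shift errors (heavy-tailed t noise at the DP4 scales), conformer
  free-energy spreads and systematically perturbed decoy structures, so the
  whole pipeline can be exercised and power-tested without quantum chemistry.

The quantum-chemistry stage itself (geometry optimization, GIAO shieldings,
conformer searching) is deliberately out of scope: per-conformer shieldings
and free energies enter as CSV/TSV tables or plain-text QM log files.

## Worked example: the cereoanhydride structure problem

Cereoanhydride, a metabolite of the marine fungus *Coniothyrium cereale*, was
originally assigned a strained seven-membered ring anhydride structure and
later revised to a ring-contracted carboxylic acid. The bundled dataset
(`shiftsieve.datasets.load_cereoanhydride`) carries the experimental shifts
and Boltzmann-averaged, scaled DFT shifts for three candidates — the
anhydride, the acid, and the deprotonated acid (carboxylate):

```python
import shiftsieve as ss

exp, candidates = ss.datasets.load_cereoanhydride()
report = ss.build_report(candidates, exp)
print(report.to_text())
```

prints

```
Structure discrimination vs cereoanhydride (experimental, CD3OD)

candidate: anhydride
  C: n=16  MAD=3.3  MAX=9.6 (C11)  unacceptable: C11, C10, C2, C13
  H: n=8  MAD=0.11  MAX=0.26 (H17-19)
candidate: acid
  C: n=16  MAD=1.4  MAX=3.8 (C9)
  H: n=8  MAD=0.21  MAX=0.54 (H23)  unacceptable: H23, H17-19
candidate: carboxylate
  C: n=16  MAD=1.5  MAX=3.5 (C11)
  H: n=8  MAD=0.12  MAX=0.23 (H27)

DP4 (carbon): anhydride=0.0%  acid=81.2%  carboxylate=18.8%
DP4 (proton): anhydride=35.7%  acid=2.1%  carboxylate=62.2%
DP4 (combined): anhydride=0.0%  acid=12.5%  carboxylate=87.5%

verdict: carboxylate
```

Reading the output: the anhydride is ruled out by four ¹³C deviations past
the 5 ppm acceptability line (its ring carbons are simply in the wrong
places), and carbon-only DP4 favours the acid. But the acid's α proton H23 is
computed 0.54 ppm too far downfield — an unacceptable ¹H deviation — and both
proton-only and combined DP4 instead select the **carboxylate**, i.e. the
observed spectrum is most consistent with the acid being at least partly
deprotonated in the NMR sample. That protonation-state subtlety is exactly
what makes molecules with acidic protons hard cases for shift prediction.

The same run is available from the shell:

```bash
shiftsieve simulate --seed 5 --out sim/          # synthetic candidate sets
shiftsieve discriminate --exp exp.csv \
    --candidate acid=acid.csv --candidate carboxylate=carb.csv --out report/
shiftsieve geom --xyz conformer.xyz --dist 17 23 --noe-cutoff 5.0
```

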