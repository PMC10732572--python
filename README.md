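# bindfit

Forward models and fitters for the biophysical assays used to characterise
cation-regulated protein–protein interactions — built around the
Ca²⁺/Na⁺-controlled complex between the EF-hand sensor NCS-1 and the Gα
chaperone/GEF Ric-8A, but written as reusable components:

- **Sequential multi-site equilibria** (`bindfit.equilibria`): exact
  speciation of the stoichiometric ladder M + L ⇌ ML₁ ⇌ ML₂ ⇌ ML₃ with
  stepwise constants K₁…K₃, plus the 1:1 quadratic, ΔG = −RT ln(1/K_d)
  conversions, and per-step availability profiles Θᵢ along a titration.
- **ITC** (`bindfit.itc`): VP-ITC injection-heat forward model
  (perfusion dilution + displacement correction) and a nonlinear
  least-squares fitter for (K_d1–3, ΔH1–3).
- **Fluorescence titrations** (`bindfit.titration`): 1:1 saturation
  y = y_max·L/(K_d,app + L) vs linear response, with AICc model selection.
- **BLI kinetics** (`bindfit.bli`): 1:1 Langmuir sensogram simulation and a
  global two-phase fit returning k_on, k_off and K_d,app = k_off/k_on, with
  identifiability warnings in weak-binding regimes.
- **Nucleotide exchange** (`bindfit.exchange`): single/double-exponential
  progress-curve fits, matched intrinsic-rate subtraction, and the
  Ca²⁺-activation hyperbola v = v₀ + v_max[Ca²⁺]/(K_a + [Ca²⁺]).
- **Nano-DSF** (`bindfit.thermal`): two-state van 't Hoff melt curves on the
  350/330 nm ratio and first-derivative inflection-temperature (Ti)
  detection.
- **Interface analysis** (`bindfit.interface`): inter-chain contacts at a
  distance cutoff, hydrogen bonds, per-residue contact shares and
  Shrake–Rupley-style buried surface area from PDB coordinates (via gemmi).
- **Synthetic data** (`bindfit.synth`): seeded generators for every assay
  with ground-truth sidecars, so each fitter is testable offline.

See `docs/methods.md` for model details, assumptions and numerical choices.

## Worked example

Simulate a sequential Ca²⁺ ITC titration under the measured Na⁺-buffer
parameters (K_d = 265/758/379 nM, ΔH = −7.7/+3.0/−9.1 kcal/mol; 110 µM
protein in a 1.4619 ml cell, 28 × 10 µl injections of 1.5 mM CaCl₂) and
refit it from perturbed starting values:

```python
import numpy as np
from bindfit.equilibria import SequentialBindingModel, delta_g
from bindfit.itc import ITCProtocol, simulate_isotherm, fit_sequential_itc

truth = SequentialBindingModel(kd=(265e-9, 758e-9, 379e-9),
                               dh=(-7.7, 3.0, -9.1))
iso = simulate_isotherm(truth, ITCProtocol())

init = SequentialBindingModel(kd=tuple(3 * k for k in truth.kd),
                              dh=tuple(3 * h for h in truth.dh))
fit = fit_sequential_itc(iso, init)
print("Kd (nM):", np.round(np.array(fit.model.kd) * 1e9, 1))
print("dH (kcal/mol):", np.round(fit.model.dh, 2))
print("dG1 (kcal/mol):", round(delta_g(fit.model.kd[0], 298.15), 2))
```

prints

```
Kd (nM): [265. 758. 379.]
dH (kcal/mol): [-7.7  3.  -9.1]
dG1 (kcal/mol): -8.97
```

i.e. the fitter recovers the generating stepwise constants and enthalpies
exactly from noiseless data, and the first binding step is worth
−8.97 kcal/mol at 25 °C.

The same workflow is available from the shell:

```sh
bindfit simulate itc --preset table4_na --seed 1 --out isotherm.csv
bindfit itc-fit isotherm.csv --out fit.json
```

Other subcommands: `titration-fit`, `bli-fit`, `exchange-fit`,
`activation-fit`, `dsf-ti`, `interface` (PDB census), each reading
unit-tagged CSV (`conc_uM`, `time_s`, `temp_C`, …) and writing a JSON
report with parameters, standard errors, diagnostics and provenance.

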