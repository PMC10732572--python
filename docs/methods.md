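# Methods

`bindfit` implements the quantitative models used to characterise a
Ca²⁺/Na⁺-regulated interaction between an EF-hand calcium sensor (NCS-1) and
its partner chaperone/GEF (Ric-8A): multi-site binding thermodynamics by
ITC, 1:1 equilibria by fluorescence titration and biolayer interferometry,
nucleotide-exchange kinetics with Ca²⁺ activation, thermal stability by
nano-DSF, and structural interface statistics. This note records the models,
their assumptions, the numerical choices, and what the synthetic-data tests
do and do not demonstrate.

## Sequential (stoichiometric) binding ladder

The core model is a three-step stoichiometric ladder,

    M + L ⇌ ML₁ + L ⇌ ML₂ + L ⇌ ML₃,

parameterised by stepwise dissociation constants K₁–K₃ (molar) and per-step
enthalpies ΔH₁–ΔH₃ (kcal/mol). These constants are *stoichiometric*: Kᵢ
governs adding the i-th ligand to the population, irrespective of which
physical EF-hand binds it. Microscopic (site-specific) constants are out of
scope. With overall association constants βᵢ = Π_{k≤i} 1/K_k, the fraction
of macromolecule carrying exactly i ligands at free-ligand concentration l
is the binding-polynomial term fᵢ = βᵢ lⁱ / (1 + Σ_k β_k l^k).

The only nonlinear step is inverting the ligand mass balance
l + M_tot·⟨n⟩(l) = L_tot for l. Its left side is strictly increasing on
[0, L_tot], so the solver uses a bracketed bisection there (90 halvings,
i.e. interval reduction 2⁻⁹⁰ — far below the 10⁻¹² relative target).
Bisection was chosen over Newton-type schemes deliberately: the residual is
cheap, the bracket can never fail, and the same loop vectorises across a
whole titration. Degenerate inputs short-circuit exactly (L_tot = 0 → all
free fractions; M_tot = 0 → l = L_tot).

Free energies use ΔG = −RT ln(1/K_d) with R fixed at 1.986 cal mol⁻¹ K⁻¹
(the convention of the source analyses, not CODATA) and 25 °C mapped to
298.15 K.

**Step availability (Θ).** The per-class "fraction of available sites" along
a titration is not uniquely defined for stoichiometric constants. This
package defines Θᵢ = Σ_{j<i} fⱼ — the probability that fewer than i ligands
are bound, i.e. that step i has not yet occurred. This interpretive choice
is stamped into `ThetaProfile.definition` so downstream consumers can see
which convention produced the numbers. Under it, Θᵢ is non-increasing in
total ligand and the third step demonstrably fills last under the measured
parameter sets.

## ITC forward model and fitter

The VP-ITC perfusion cell (V₀ = 1.4619 ml by default) overflows on
injection, so after the j-th injection the original cell content is diluted
by d_j = Π_{k≤j}(1 − v_k/V₀) and the in-cell totals are m_j = m₀·d_j,
l_j = c_syr·(1 − d_j). The default protocol is 110 µM macromolecule in the
cell titrated with 1.5 mM ligand. The injection schedule is not part of the
published protocol; the default is standard VP-ITC practice — a 2 µl first
injection (discarded from fitting but still diluting the cell) followed by
28 × 10 µl — and is fully configurable.

The cell's heat content after injection j is H_j = V₀·m_j·Σᵢ ΔH_cum(i)·fᵢⱼ
and the measured heat is the difference corrected for the enthalpy carried
out by the displaced volume, evaluated at the mean of adjacent states:

    q_j = H_j − H_{j−1} + (v_j/V₀)(H_j + H_{j−1})/2,

reported per mole of injectant. The exact displacement convention used by
commercial analysis software is unpublished; the mean-heat convention here
is the common textbook correction and is treated as an approximation.
Dilution heats are not modelled (negligible in the assays reproduced).
Concentrations are fixed at nominal values; no active-fraction ("site
number") factor is floated.

Fitting is nonlinear least squares (Levenberg–Marquardt) over six
parameters with K_d in log₁₀ space and ΔH linear; a multistart over K_d
scaled by {0.1, 10} runs only if the first solution's RMS residual exceeds
10⁻³ of the heat scale. Parameter standard errors come from the linearised
Jacobian at the optimum (no bootstrap); they are reported as fit SEs.

**Identifiability under this protocol.** The titrant is roughly 400-fold
above the stepwise K_d, so the simulated isotherm is nearly rectangular and
K_d information lives only in the curvature of the step edges. Noiseless
round trips recover all six parameters to better than 1%, but Monte Carlo
with 2% relative heat noise shows median worst-parameter errors above 50%
for the K_d regardless of starting values — intrinsic statistical
uncertainty, which the fitter surfaces as correspondingly large standard
errors rather than masking. The noise-robustness test therefore runs at
0.2% noise, where the 15% recovery bound genuinely holds, and a separate
test asserts the reported SEs acknowledge ≥10% uncertainty at 2% noise.

## Fluorescence titrations

Cation-binding titrations followed by tryptophan emission are normalised as
y = |I − I₀|/I₀ (the magnitude convention; the raw sign belongs to the
instrument trace, not the model) and fitted to the 1:1 saturation law
y = y_max·L/(K_d,app + L) under a free≈total ligand assumption, valid at the
≥10³-fold ligand excess of these experiments (tens–hundreds of mM cation vs
~10 µM protein). A closed-form straight line is the non-saturating
alternative, and corrected AIC (AICc) selects between them with ties going
to the line on parsimony. Flat data return a zero-amplitude fit with an
explicit unidentifiability warning instead of an arbitrary K_d.

## BLI 1:1 kinetics

Sensograms follow the 1:1 Langmuir model: association
R(t) = R_eq(1 − e^{−k_obs t}) with k_obs = k_on·C + k_off and
R_eq = R_max·C/(C + k_off/k_on); dissociation decays as e^{−k_off t} from
the association endpoint. The global fitter shares k_off between phases,
weights both phases equally (the vendor software's weighting is
proprietary), subtracts a straight-line baseline fitted to the
pre-association phase when present, and reports K_d,app = k_off/k_on — an
identity, so it holds bitwise. A steady-state R_eq-vs-C fit is available as
a fallback for multi-concentration series.

At a single analyte concentration, k_on and R_max are only jointly
determined through R_eq; when the fractional saturation C/(C + K_d) leaves
(0.02, 0.98) or the normal-equation condition number exceeds 10¹⁰, the fit
carries a weak-identifiability warning. This matters in the
highest-Ca²⁺ regime, where the apparent K_d (~0.1 M) is three orders above
the 50 µM analyte: the model cannot support a confident estimate there and
says so instead of printing one.

## Nucleotide-exchange kinetics and Ca²⁺ activation

GTPγS-binding progress curves are fitted empirically to
F(t) = F₀ + Σᵢ aᵢ(1 − e^{−kᵢt}) with one or two phases; rates are fitted in
log space and sorted so the slow phase is last. By fixed convention the
slow rate of a biphasic curve is the catalysed exchange rate (the fast
phase reports binding to an intermediary complex and is not modelled
mechanistically). AICc chooses the order, with one guard: when the
single-exponential fit already sits at the numerical noise floor of the
signal, the comparison is declared a tie and order 1 wins — otherwise AICc
on machine-zero residuals amplifies rounding noise into a spurious second
phase.

Rates measured across a CaCl₂ series are corrected by subtracting the
intrinsic (uncatalysed) rate at the *exactly matching* concentration — no
interpolation; a missing match is an error. Corrected (or, for the
intrinsic-enhancement constant, raw) rates are fitted to the one-site
total-binding velocity law v = v₀ + v_max[Ca²⁺]/(K_a + [Ca²⁺]), with K_a in
log space and a zero-Ca point required to anchor v₀. K_a recovery is
invariant to the arbitrary (v₀, v_max) pair, which the suite verifies over
a grid.

## Nano-DSF melt curves and Ti

Synthetic melt curves use a two-state van 't Hoff model on the 350/330 nm
fluorescence ratio: θ_U(T) = 1/(1 + exp[(ΔH_vH/R)(1/T − 1/T_m)]) (T in
kelvin) between linear folded/unfolded baselines, on a 0.1 °C grid over
35–95 °C by default.

Detection mirrors the instrument's first-derivative readout: Savitzky–Golay
smoothing (local quadratic, 1.5 °C window by default), d(ratio)/dT on the
grid, and every peak above a prominence threshold (5% of the derivative
range) is a transition; peak positions are refined by parabolic
interpolation of the three samples around the grid maximum. Because only
the curve's shape enters, detection is invariant to affine rescaling of the
ratio axis. Two guards reject baseline-only curves whose derivative is
constant at rounding level. Note the physics: the maximum of dθ_U/dT sits
slightly below T_m (the extra 1/T² factor from differentiating in T), about
0.05–0.07 °C at ΔH_vH = 100 kcal/mol — within the 0.1 °C grid step, and the
reason detected Ti is compared to generating midpoints with that tolerance.
Sloped baselines bias the derivative peak; the detector reports the raw
peak (matching instrument behaviour) and leaves baseline handling to the
caller. The proprietary instrument algorithm is unknown, so equality with
published Ti values is only ever asserted on synthetic curves built from
those values.

## Interface analysis

Structures are read from PDB files via gemmi into a flat atom table;
alternate locations collapse to the highest-occupancy conformer and residue
numbering is preserved verbatim. The default contact census counts heavy
(non-H) atom pairs across two disjoint chain selections within 4.2 Å,
excluding waters and ions — the source analyses do not state their
conventions, so every toggle (cutoff, hydrogens, waters, ions) is exposed
and the census method is embedded in the output metadata. Comparisons
against deposited-structure statistics (1469 contacts, nine H-bonds,
1140 Å² for the sensor/peptide interface) are reported, never asserted,
because the generating conventions are unstated and the coordinates require
download.

Hydrogen bonds pair donor and acceptor heavy atoms (fixed N/O/S dictionary
for the 20 standard residues plus backbone) within 3.5 Å; the D–H···A angle
test (≥120°) applies only when explicit hydrogens are present — crystal
structures at typical resolution lack them, so the distance-only criterion
is the default behaviour. Water-mediated bridges (one water oxygen within
range of a polar atom on each side) are optional. Unknown residues are
skipped with a warning.

Buried area is (SASA_A + SASA_B − SASA_AB)/2 with SASA from sphere-point
quadrature: 960 Fibonacci points per atom, probe 1.4 Å, Bondi van der Waals
radii (common ions appended). 960 points put the two-sphere analytic-cap
error below 0.1% and halving/doubling the point count moves toy-complex
buried areas by <0.5%.

## Synthetic data and what the tests show

Every fitter has a generator that emits data from the forward model plus
optional additive Gaussian noise, under a per-dataset RNG seeded from
(master seed, assay tag, replicate) — reproducible and independent across
assays. Ground truth travels in `.truth.json` sidecars, never in fitter
inputs. Default noise levels (ITC 2% of peak heat, titration/BLI/exchange
2–3% of amplitude, melt 0.5% of ratio range) are conventions chosen to
resemble published instrument scatter, not measurements.

The generators emulate the *models* of the assays under the published
protocols, not the instruments: no power-trace integration, interference
spectra, drift, photobleaching, mixing artefacts, or ligand impurities.
Passing round-trip tests therefore demonstrates that the fitters invert
their own forward models correctly under the published designs — a
consistency statement, not a validation against real instrument data. The
toy structural complexes place engineered contact pairs isolated from two
well-separated atom slabs, so their inter-chain contact count is known by
construction; they exercise the counting geometry, not protein realism.

## Problem sizes

Defaults used by the test suite and the acceptance script: 29-injection
isotherms; 15-point titrations; 1201-point sensograms (600 s at 0.5 s);
240-point progress curves; 601-point melt scans; toy complexes of 60–200
atoms. Monte Carlo studies use 25–200 replicates under fixed seeds. All
sizes are package defaults chosen to match the emulated protocols and keep
every study cheap on a single core.

## Known limitations

- Stoichiometric constants only; no microscopic site assignment, no
  Mg²⁺/Ca²⁺ competition, no Hill-type cooperativity.
- ITC: no ΔCp, no competitive titrations, no raw-power baseline
  integration; displacement correction is an approximation (above).
- BLI: no mass-transport limitation, no heterogeneous-ligand models, no
  loading-phase modelling.
- Exchange: the fast phase is an empirical exponential, not a mechanism;
  no Michaelis–Menten treatment of GEF turnover.
- DSF: no ΔG extraction, no irreversible-aggregation or scan-rate models.
- Interface: no symmetry mates, no electrostatics, no thermodynamic
  interface-significance scoring.
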