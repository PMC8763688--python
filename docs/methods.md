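# Methods

This note documents the model equations, the defaults and why they were
chosen, what the synthetic-data generators do and do not emulate, the
numerical choices, and the known limitations. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Whole-body model

### Structure

Each perfused organ has four sub-compartments — vascular plasma, vascular
blood cells, interstitial and intracellular space — with volumes taken
from the packaged organ tables (vascular and interstitial volume fractions
per organ; the remainder is cellular). The lung sits in series between the
venous and arterial pools and carries the entire cardiac output. Spleen,
gut, stomach and pancreas drain into the liver inflow (portal wiring), so
orally absorbed drug passes the liver before reaching the systemic
circulation and a first-pass effect emerges mechanistically. Organs with
zero blood flow in the table (human gallbladder and saliva) are inert
volume pools excluded from the dynamics.

Processes, all linear:

* **Convection**: flow Q_i splits into plasma and blood-cell streams by
  hematocrit.
* **Plasma ↔ interstitium**: endothelial permeability × a specific
  surface area (1 cm²/mL tissue, a lumped constant absorbed by the
  identified permeabilities) × unbound concentration difference
  (fu·C_pl − fu·C_int; interstitial binding is assumed plasma-like).
* **Interstitium ↔ cells**: cellular permeability, with the unbound
  tissue:plasma-water coefficient Kpu as the equilibrium ratio
  (flux ∝ fu·C_int − C_cell/Kpu).
* **Plasma ↔ blood cells** in every vascular space, with directional
  permeabilities and the blood-cell:plasma coefficient as equilibrium
  ratio. The directional permeabilities are not printed in the source;
  0.15 cm/min in both directions is a documented stand-in and the
  equilibrium ratio (21.28) is what matters at disposition timescales.
* **Elimination** — rat mode: total plasma clearance (6 L/h/kg) acting on
  venous plasma, which makes AUC(0–∞) = Dose/CL hold exactly for an IV
  bolus and is used as an internal closed-form oracle. Human mode:
  whole-liver intrinsic clearance (CL_int × hepatocellularity
  [120 × 10⁶ cells/g, documented constant] × liver mass) acting on the
  unbound intracellular liver concentration C_cell/Kpu_liver, which
  reproduces well-stirred behaviour including the flow-limited ceiling.
  Renal clearance is a separate term on kidney plasma, zero by default.
* **Charge correction**: all permeabilities are multiplied by the
  Henderson–Hasselbalch neutral fraction at plasma pH (charged species are
  assumed non-permeant). Plasma pH is 7.4, intracellular pH 7.0 per the
  organ tables.

### Tissue partitioning

Kpu follows the steady-state mechanistic equation for weak acids and
neutral compounds: tissue water (with the intracellular/plasma ionization
ratio X/Y), neutral lipid and neutral phospholipid partitioning via
P = 10^logP with the conventional (0.3·P + 0.7) phospholipid affinity, and
extravascular albumin binding estimated from plasma binding in excess of
the plasma-lipid contribution scaled by a tissue:plasma albumin ratio.
For very lipophilic compounds (homosalate, logP 6.34) the plasma-lipid
term alone can exceed the measured binding, leaving a negative albumin
bracket; it is clamped at zero, the standard convention. Homosalate is
treated with the acid/neutral model although its pKa (8.1) straddles the
class boundary as usually stated; at pH 7.4 it is ~83% neutral and the
acid/neutral grouping is the natural choice. Plasma water fraction is
0.96; Kp = Kpu·Fu/0.96 is exposed alongside Kpu.

The tissue-composition table (water/lipid fractions, albumin ratios) is
packaged, versioned data with representative literature-style values
shared across rat and human. The partition *equation* is tested against an
independent term-by-term oracle, separately from any choice of table
values.

### Units and integration

Amounts µg, volumes mL, time h, concentrations ng/mL (reported),
permeabilities entered in cm/min and converted internally. The entire
system (body + optional skin grid + cumulative trackers) is a constant
rate matrix; `simulate` advances it with matrix exponentials over the
output grid (exact for linear systems, unconditionally stable, and the
propagator's non-negativity guarantees non-negative states). Each
inter-dose interval uses a hybrid geometric/uniform output grid so the
fast disposition right after a bolus is resolved for trapezoid AUCs. A BDF
path with the exact Jacobian (rtol 1e-6, atol 1e-9 µg) is retained as a
cross-check. Dose events restart propagation. AUC(0–∞) is available in
closed form as −wᵀA⁻¹x₀ over the mass-carrying block; the NCA
extrapolation (λz from the final third of post-T_max points, ≥ 3 points,
earliest-time T_max tie-break) exists for observed-data-like use and is
conservative for this model's very slow terminal phase.

### Oral absorption

A single well-mixed gut lumen with first-order absorption
ka = permeability × effective surface area / lumen volume, in competition
with a transit (fecal) loss rate, so Fa = ka/(ka + k_transit) < 1.
Calibration of the intestinal permeability to a target bioavailability
(Fb = AUC ratio, evaluated with the exact linear AUC) is a monotone root
search. In rat mode (clearance on venous plasma) there is no hepatic
extraction, so Fb = Fa and calibrating Fb = 50% yields Fa = 50%; the
source workflow's Fa = 81% at Fb = 50% depends on its platform's
absorption internals and is deliberately not asserted. Lumen geometry and
transit defaults (rat: 4 mL, 100 cm², 0.66/h) are documented stand-ins.

## Dermal model

A 1-D slab of stratum corneum (SC), viable epidermis (VE) and dermis (DE),
each split into 40 serial sub-layers (the 4 × 10 structure read as serial —
the only reading compatible with 1-D Fickian diffusion). Flux between
nodes uses water-referenced activity a = C/K, continuous across layer
interfaces, with interface resistances Δx/(2·D·K) summed from both sides;
this makes a single-layer grid reduce exactly to the classic homogeneous
membrane (steady flux K·D·C_v/h, lag h²/6D — both verified against the
analytic solution).

On top sits a well-mixed vehicle film (2 µL/cm², matching a 2 mg/cm²
application). Two vehicle processes:

* **Vehicle partition** (1e5 vs water): homosalate's escaping tendency
  from an oily formulation; sets the surface activity driving uptake.
* **Drying** (immobilization 0.35/h, half-life ≈ 2 h): film content moves
  to an inert surface pool and stops participating. This is the mechanism
  behind front-loaded delivery: without it a finite dose at a few-percent
  penetrated fraction gives a quasi-constant flux and plasma that peaks
  only at the end of the application interval, contradicting the observed
  mid-interval plasma peak (T_max 10–12 h). The rate was fixed once against
  that clinical observation — the same role the source workflow's
  surface-pool compartments play — and is not adjusted per scenario.
  An evaporation rate to an air pool exists in the data model, default
  off (no parameters are established for it).

Systemic uptake is first-order (1/h) from every viable (VE + DE) sub-layer
into venous blood, zero in the SC; a dermis-only switch exists. The deep
boundary is sealed by default; a sink bottom serves membrane-experiment
oracles. The operator is one matrix: standalone penetration runs use
implicit Euler (fixed 0.01 h steps, LU factored once; the discrete update
conserves mass exactly), and coupling to the body embeds the same matrix
in the systemic system scaled by the application area.

Defaults for the permeant: K_sc/w 5e4 (lipid-partition scale
~10^(0.74·logP)), D_sc 2e-8 cm²/h — an SC diffusion lag of hours, making
the SC a depleting reservoir; viable tissue K 200, D 3.6e-3 cm²/h
(1e-6 cm²/s). Layer thicknesses 20/80/1200 µm. The calibration to a
measured 24-h penetrated fraction scales D_sc alone by a bounded scalar
root search (tolerance 0.5% relative): Q is monotone in D_sc throughout,
whereas scaling K_sc/w also inflates the finite-dose SC reservoir and
reverses the trend at extreme multipliers, so K is not a default free
parameter (it can be requested).

## Sensitivity analysis

S = (ΔPK/PK)/(Δp/p) on a ladder of ±k·step perturbations (default five
steps of 10%, symmetric; one-sided available), averaged over valid steps;
steps violating an invariant (e.g. Fu > 1) are skipped and logged.
Classification bands: |S| ≥ 0.5 high, ≥ 0.2 medium, ≥ 0.1 low, otherwise
negligible (suppressed from the default view, retained in raw output).
The estimator is exact for proportional endpoints at any step size; for
curved endpoints it carries an O(δ²) bias — for AUC ∝ 1/CL each step
returns exactly −1/(1−δ²), so the default ladder averages ≈ −1.13 and a
2% step returns −1.004. The step size is exposed for that reason, and the
reference checks use the small step. Partition sets are rebuilt only when
the perturbed parameter can affect them.

## Parameter identification

Pure seeded Monte-Carlo random search (uniform in linear or log transform
space within bounds), matching the named algorithm class of the source
workflow; no gradient steps by default (an optional Nelder–Mead polish is
off for reproducibility). Loss: sum of squared residuals in log
concentration (IV washout spans orders of magnitude); observations below
a configurable LOQ are excluded. Candidate evaluation steps the linear
system directly to the observed times (matrix exponentials), which is
exact and fast enough for thousands of draws. Deterministic given the
seed; the best-so-far trace is recorded. A 1.25-fold C_max/AUC ratio rule
is the documented "good fit" default.

## Populations and uncertainty

Body weight (and age for humans) is sampled uniformly over the stated
ranges (0.185–0.275 kg rat; 45–100 kg, 16–70 y human) — the source states
ranges, not a distribution; a truncated-normal option exists. Physiology
co-varies with body weight by isometric scaling of organ volumes, flows,
cardiac output and GFR; within these ±20% ranges richer allometry is not
warranted. Parameter uncertainty is truncated-normal per parameter
(resampling out-of-bounds draws), independent across parameters.
Population variability and parameter uncertainty are combined in a single
Monte-Carlo layer (individual i gets draw i); whether the source nested
them is unstated. Summaries report the mean and empirical 5th/95th
percentiles with numpy's linear interpolation (type 7), recorded in every
result object.

## Synthetic data

The rat IV generator simulates the packaged identified model at
0.5/2/5 mg/kg and multiplies by lognormal noise exp(N(0, σ)),
σ = √ln(1+CV²); CV defaults to 0.3, consistent with the reported C_max
scatter (SD/mean ≈ 0.32) — a documented stand-in, as is the 8-point
sampling schedule (0.033–8 h). The clinical dermal generator runs the
trial's application schedule (Day 1 single; Days 2–4 four applications at
2-h intervals; 150 µg/cm² on 19000 cm²) with per-subject lognormal
multipliers (CV 0.4) on dermal delivery and hepatic clearance. Noise-free
generation returns the forward model exactly, and every dataset records
its truth parameters for recovery testing. The generators emulate the
studies' designs and noise structure, not their actual measurements: a
green recovery test establishes that the identification machinery works
on data this model could have produced, not that the original studies are
reproduced.

## Known limitations

* The headline plasma predictions of the source platform (e.g. IV C_max
  320 ng/mL; the repeated-dose C_max/AUC tables) are not reproducible by
  an independent implementation: they depend on proprietary-in-detail
  organ parameterizations. This implementation predicts substantially
  higher dermal-scenario plasma concentrations (its distribution into the
  very-high-Kp tissues is permeability-limited and slower), so the
  worked MoIE example can fall below the safety factor where the source
  reports a pass. Printed, recomputable arithmetic (dose arithmetic,
  IVIVE conversion, BMI, dermal calibration targets, closed-form AUC) is
  reproduced and asserted instead.
* The source reports AUC(0–∞) = 123.1 ng·h/mL for 0.5 mg/kg IV alongside
  CLs = 6 L/h/kg, but Dose/CL = 83.3 ng·h/mL; the two are mutually
  inconsistent, and the engine asserts its own closed form.
* Metabolites, transporters, skin metabolism, hair-follicle transport and
  vehicle evaporation are out of scope; penetrated mass is parent only.
* The NCA λz extrapolation underestimates AUC(0–∞) for this compound's
  extremely slow terminal phase; use the closed-form AUC for model-based
  values.
* logP is reported at 40 °C and pKa at 20 °C; no temperature correction
  is applied (none is established).
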