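# Methods

## The model

`mitonadph` simulates the hydrogen-peroxide clearance network of the
mitochondrial matrix as a well-mixed mass-action ODE system, with a
chemogenetic H2O2 source and the NADPH economy that pays for clearance.
The reaction topology follows the established cytosolic H2O2-clearance
framework (peroxiredoxin oxidation/condensation/hyperoxidation, Trx-mediated
peroxiredoxin recycling, TrxR reduction of oxidized thioredoxin by NADPH,
a GPx/GR glutathione cycle, and generic protein-thiol oxidation with
glutathionylation/glutaredoxin recovery), restricted to the matrix and
modified in four ways:

1. **DAAO source.** D-amino acid oxidase expressed in the matrix converts
   D-alanine to pyruvate + H2O2.  External D-alanine is clamped (HeLa cells
   have no endogenous DAAO); matrix D-alanine follows
   `d[DalaM]/dt = k_perm ([Dala]_ext − [DalaM]) − k_gen,H2O2 [DalaM]` with
   `k_perm = P · (S/V)`.  The surface-to-volume constant is *derived*, not
   assumed: it is the unique value for which the quasi-steady DAAO flux at
   50 mM equals the reference 70.7 μM/s given the fitted permeability
   `P = 6.92e-10 cm/s` and turnover `k_gen,H2O2 = 8.83e-2 /s`
   (≈ 2.08e6 /cm; see `calibrated_surface_to_volume`).  The quasi-steady
   flux is exactly linear in the external dose, reproducing the
   generation-rate ladder (1.4 → 70.7 μM/s over 1 → 50 mM).
2. **Lumped NADPH regeneration**, first order in NADP+:
   `v_regen = k_gen,NADPH [NADP+]` with `k_gen,NADPH = 1.59 /s`,
   standing in for IDH2, ME3, NNT and MTHFD2.
3. **Stress-dependent NADPH influx** `v_α = α · s_cal · g(v_tot)`,
   representing shuttle-mediated transfer of cytosolic reducing equivalents
   into the matrix under stress (`α = 80.9`).  The default gating
   `g = max(0, v_tot − v_basal)` closes the flux at the basal operating
   point; the literal form `g = v_tot` is selectable.  Because the influx
   adds to the pyridine pool without a matching NADP+ sink, its time
   integral equals the growth of the total NADPH+NADP+ pool; a raw
   `α·v_tot` (≈ 300–6000 μM/s against a ~40 μM pool) is therefore
   dimensionally untenable, and the calibration scale `s_cal = 5e-7` is
   fixed so that the 50 mM trajectory reaches the reference ~7.9 μM NADPH
   endpoint.  Over the hour this grows the pool by ~12 μM — enough to raise
   the regeneration capacity toward the stressed demand, which is exactly
   the role the coefficient plays in the sensitivity analysis.
4. **Glutathione exchange** (constant influx, first-order degradation,
   optional GSSG efflux, off by default) replaces cytosolic glutathione
   synthesis; thioredoxin has no turnover terms.

Units: concentrations μM, time seconds internally (minutes at the I/O
boundary), second-order constants 1/(μM·s); external D-alanine is mM at
entry.  PrxSS is counted monomerically, so the conserved peroxiredoxin
moiety is the plain four-form sum.  Catalase is excluded (matrix model);
hyperoxidation and sulfiredoxin recovery are retained.

### Rate-constant calibration

The matrix-specific rate constants of this adaptation are not fully
published; the defaults here are literature-scale values calibrated once
against the model's documented operating anchors, in this order:

* **Basal fixed point.**  With a basal generation flux of 4 μM/s, the
  pseudo-first-order clearance coefficient must be ≈ 1212 /s for a 3.3 nM
  steady H2O2.  The split is ~95% peroxiredoxin (`k_prx_ox = 19.7 /(μM·s)`
  ≈ 2e7 /(M·s), 60 μM Prx3 mostly reduced), ~5% protein thiols
  (`k_psh_ox·PSH_tot = 60 /s` over a 60 mM reactive-thiol buffer) and a
  small enzyme-limited GPx flux (`2 /s`, first order in H2O2, saturable in
  GSH with a 50 μM half-saturation — bare mass action in GSH would empty
  the 3 mM pool within seconds under stress).
* **Pyridine pool.**  `NADP_total = 36.7 μM`.  The printed basal
  quantities are mutually inconsistent at the ~20% level: a 41.8 μM NADPH
  pool with ratio 13.4 implies NADP+ = 3.12 μM, while a 4.05 μM/s
  regeneration flux at 1.59 /s implies 2.55 μM.  At the model's own fixed
  point the NADP+ level is pinned by flux balance (consumption ≈ the 4 μM/s
  H2O2-driven demand), so honouring the flux/ratio pair
  (2.55 × (1 + 13.4) = 36.7 μM) keeps both the basal ratio (13.6) and the
  regeneration flux (4.0 μM/s) self-consistent; the sensor-based 41.8 μM
  estimate is retained as the calibration anchor of the observation model
  instead.
* **Stressed branch.**  The Prx→Trx channel saturates near ~30 μM/s
  (set by `k_prx_cond = 10 /s`, `k_prx_red = 0.15 /(μM·s)`,
  `k_trxr = 0.10 /(μM·s)`); under 50 mM stimulation the protein-thiol
  buffer absorbs the early surplus and hands the load to the NADPH-cycled
  channels as it depletes, while GSSG accumulation (`k_gr = 4.5e-3`)
  adds a slowly growing glutathione-reductase demand.  Together these
  produce the observed phenotype: a fast fall of NADPH to ~13 μM within
  3 min, a slow decline to ~7.3 μM at 60 min (ratio ≈ 0.18), a ~7–9-fold
  H2O2 rise at 15 mM with a ~30% NADPH drop, and readout declines of ~26%
  (3 min) and ~39% (60 min) through the sensor map.
* Prx3 hyperoxidation is slow (`1e-4 /(μM·s)`) with sulfiredoxin recovery
  `5e-3 /s`, consistent with the relative hyperoxidation resistance of the
  mitochondrial isoform; this keeps the clearance machinery alive through
  the 60-min stress window.

One transient feature is *not* reproduced: the brief rebound of NADPH
(a dip near 0.5 min followed by a ~27% recovery within ~8 min) under
50 mM stimulation.  The calibrated network relaxes monotonically onto its
stressed quasi-steady branch; producing a rebound requires a fast-relaxing
consumption overshoot that this reaction set does not generate without
breaking the late-time anchors.  The acceptance script measures the rebound
faithfully (first local minimum within 5 min, rise to the maximum within
the next 8.5 min) and reports zero.

At 50 mM the late-phase H2O2 rises into the high-μM/mM range once the
protein-thiol buffer is spent; this tail is not constrained by any
reported quantity and should be read qualitatively (production exceeds the
NADPH-fundable clearance capacity), not as a concentration prediction.

### Steady-state initialisation

Initial oxidized-species concentrations are obtained by root-finding on
the reduced system with the conservation relations substituted (species
scaled by their pool totals; tolerance 1e-10 on scaled residuals), with a
1e5-s integration fallback, and verified to satisfy max |dC/dt| < 1e-6
μM/s.  The solver treats free glutathione as an unknown because its pool
is open (transport/degradation/efflux).

### Numerical choices

LSODA with rtol 1e-8 / atol 1e-12 μM for science runs (both configurable).
During fitting the tolerance is relaxed to 1e-6/1e-9 — verified to leave
the residual numerical noise four orders of magnitude below the
finite-difference signal — and the local refiner (trust-region bounded
least squares in log10 parameter space) uses an explicit relative step of
1e-3, well above the solver noise floor; the default machine-epsilon step
produces garbage jacobians on ODE-constrained residuals.  Multistart draws
are log-uniform within ±2-decade bounds; near-ties (ΔZ < 1e-6) resolve to
the smallest-norm log-parameter vector relative to the bound-box centre.
Objective failures (integration collapse, no steady state) score +inf and
are simply discarded by the multistart.

## Observation model

The sensor readout is the 415/488-nm excitation ratio of the
mitochondrially targeted NADPH sensor normalized to its binding-dead
control, `R' = R_iNap/R_iNapC`.  A one-site binding equilibrium maps
concentration to the bound fraction `Y = NADPH/(Kd + NADPH)` with
`Kd = 25.2 μM`; the span calibration `Y_exp = (R' − R'_min)/(R'_max −
R'_min)` uses synthetic defaults `R'_min = 0.4`, `R'_max = 1.6` (the study
measured but did not print the two numbers), placed so the documented mean
cellular readout maps to the 41.8 μM basal estimate.  Out-of-span readouts
clip to [0, 1] with a logged warning rather than failing, since measurement
noise can cross the calibration bounds.  Whether the original analysis used
global or per-condition span constants is unknown; the calibration is
parameterized per dataset.

## Fitting and validation

The fitted subset is θ = {P, k_gen,H2O2, k_gen,NADPH, α}.  The objective
is the SEM-weighted sum of squared differences between `Y_exp` and
`Y_model` over the 21-point (0–60 min, 3-min spacing) series; the default
design fits the 50 mM condition only and validates the remaining six,
reporting per-condition weighted RMS and the fraction of points within
±SEM.  (The alternative joint multi-condition fit is a one-line config
change.)  For each candidate θ the model re-derives its own basal steady
state, so the t = 0 prediction is θ-dependent — this is what makes
k_gen,NADPH identifiable from the early points.

## Sensitivity analysis

One-sided finite differences, +10% by default, of NADPH at 3 min,
normalized as `s̄ = (∂C/C)/(∂θ/θ)`; evaluated for the full parameter
vector under each condition with the top five flagged.  The initial state
is held at the unperturbed basal steady state across the perturbation, so
the statistic measures stimulus-response sensitivity rather than resting
shifts.  A central-difference flag exists for verification; ties order
alphabetically.

## Tracer statistics

Pathway statistics operate on natural-abundance-corrected MIDs.  The
correction inverts the convolution of the fragment's elemental isotope
distributions (carbon-only by default; a full fragment formula including
derivatization atoms is accepted), clipping small negative artefacts and
renormalizing; matrices with condition number above 1e8 are rejected.  The
oxPPP share of triose production is M1/(M1+M2) of lactate from
[1,2-13C2]glucose — invariant under unlabeled dilution, which is the reason
M+0 is excluded — and the glycolytic share its complement.  TCA enrichment
tabulates M+1…M+5 per intermediate, with M+1 as the diagnostic for
dilution by DAAO-derived unlabeled pyruvate.  Shifts versus control are
reported in percentage points (relative percent is derivable from the same
table).

## Synthetic data

The generator emulates the study design: doses {0, 1, 5, 10, 15, 25, 50}
mM with the study's per-condition cell counts (21, 13, 12, 10, 14, 17, 21
from 50 → 0 mM), 21 timepoints at 3-min spacing.  Per-cell traces are the
model readout scaled by a lognormal per-cell factor (σ = 0.08 by default,
chosen so control-condition aggregate scatter stays inside the documented
13% band; the study reports error bars only, so the magnitude is an
assumption) plus per-timepoint Gaussian noise (σ = 0.01); aggregates carry
SEM = SD/√n.  Lactate MIDs are built so that the corrected noise-free
statistic equals the generating oxPPP share exactly (the glycolytic
channel contributes one unlabeled sibling triose per M+2 triose); TCA MIDs
implement first-turn PDH/PC labeling only.  Seeds are mandatory arguments;
equal seeds give bit-identical tables.

What passing tests on these data do **not** show: robustness to per-cell
noise that is correlated in time, to photobleaching drifts, to segmentation
errors, or to multi-turn TCA isotopomer structure — none of which the
generator emulates.

## Problem sizes

The test suite and the acceptance script run the model at its study scale
(15 species, 60-min simulations, 21-point series).  The in-suite parameter
recovery uses the full 50-start multistart on the 50 mM condition;
`analysis/04_fit_parameters.py` defaults to 24 starts, which is routinely
sufficient to reach the generating basin, and both are seed-reproducible.

## Known limitations

* Single compartment: no cytosolic pool, no cytosol–matrix H2O2 or NADPH
  coupling beyond the lumped α-influx, no aquaporin efflux.
* The transient NADPH rebound under strong stimulation is not reproduced
  (see above).
* The late-phase 50 mM H2O2 tail is qualitative.
* Clearance constants are effective, compartment-lumped values calibrated
  to operating anchors, not individually measured rates.
* The GPx flux form is an enzyme-limited approximation, not a full
  ping-pong mechanism.
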