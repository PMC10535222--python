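# Methods

`lumenvbe` asks a regulatory-science question in silico: when two oral
formulations of a gut-locally-acting drug are declared bioequivalent from
plasma pharmacokinetics, are they also bioequivalent at the site of action
inside the gut?  The package answers it for an enteric-coated, ethylcellulose
controlled-release budesonide multiparticulate (the reference product targets
the ileum and ascending colon in Crohn's disease) by simulating virtual
crossover BE trials and comparing plasma decisions with decisions based on
simulated lumen and enterocyte exposure in eight gut segments.

## Dissolution model and the virtual formulation panel

In-vitro release is described by the empirical Weibull function

    F(t) = F_max (1 - exp(-((t - T_lag)^beta) / alpha)),

with the reference product at F_max = 100%, alpha = 3.12 h^beta,
beta = 0.94, T_lag = 0 and an enteric trigger pH of 5.5.  T_lag is fixed at 0
for all panel members.  Sampling uses a 0.5–12 h grid (13 points); the
literature source for the reference curve does not state its sampling times,
so the grid is package configuration, and the f2 values attached to the
virtual formulations are carried input attributes rather than recomputed
quantities.

Virtual test formulations are constructed from the sampled reference curve
by either

* **delta modification** — add a constant ±Δ percent-points at every sampling
  time, cap at 100%, standardise 100% release at 12 h (7 h for the +20%
  variant, whose shifted curve completes much earlier), then refit the
  Weibull with F_max fixed at 100; or
* **trigger-pH modification** — leave the curve untouched and change only the
  pH at which the enteric coat opens (variants at pH 5 and 6).

The f2 similarity factor, f2 = 50 log10(100 / sqrt(1 + mean squared
difference)), is computed over **all** supplied points.  The regulatory
convention of dropping points after both curves pass 85% release is available
as `similarity_f2_fda` but is not the default, because the package's f2
anchors (a uniform 10-point offset gives exactly f2 ≈ 50 regardless of n)
hold only when every point enters the mean.  The bootstrap f2 resamples
replicate dissolution units (vessels) with replacement on each side and
reports the median and 5th/95th percentiles of f2 between resampled means.
Replicate units for testing are synthesised by mean-one multiplicative
lognormal noise on the Weibull curve, clipped to [0, 100] and monotonised by
cumulative max; the monotonisation introduces a small positive bias near the
100% plateau (≈0.8% at CV 2%, ≈2% at CV 5%), which is why generator checks
against the law of large numbers are run at assay-typical CV 2%.

## Gut absorption and disposition model

The GI tract is stomach + 8 absorptive segments (duodenum, jejunum 1–2,
ileum 1–4, colon), each with three layers: undissolved pellets, dissolved
drug in luminal fluid, and the enterocyte compartment.  All transfers are
first order except P-gp efflux.  The state vector carries explicit cumulative
ledgers (gut metabolism, hepatic metabolism, renal excretion, fecal solid and
dissolved loss), so the sum of all states equals the dose at every time to
solver precision — conservation is a structural property, and
`SimResult.mass_balance_error()` reports the worst defect (≈1e-15 in
practice, against a 1e-6 acceptance bound).

**Transit.**  Pellets leave the stomach with MRT 0.8 h; the small-intestinal
pellet MRT of 3 h is split over the seven SI segments proportionally to
segment length, forming an Erlang-like chain of first-order compartments.
Dissolved drug transits with the fluid MRTs (gastric 0.27 h, SI 3.4 h
length-split, colon 37.5 h male / 55.75 h female whole-colon values).  Drug
leaving the colon in either form is fecal loss.  Pellets in the colon use the
colonic fluid MRT, since no separate colonic pellet residence is specified.

**pH-triggered release.**  Release occurs only in segments whose pH is at or
above the formulation trigger pH.  Segment pH defaults (fasted) are: stomach
1.5, duodenum 6.0, jejunum 6.2/6.4, ileum 6.8/7.0/7.2/7.4, colon 6.4 —
explicit configuration, chosen as literature-typical fasted values such that
trigger pH 5.5 opens release in the duodenum.  Release applies the Weibull
hazard h(t) = F'(t)/(100 − F(t)) to remaining solid, with the release clock
equal to simulation time; a stationary pellet bed therefore reproduces the
in-vitro curve exactly, and the hazard form respects an F_max < 100 asymptote
naturally.  Note that under the default pH profile every intestinal segment
is at or above pH 6.0, so the trigger-pH 5/5.5/6 variants share the same
release-eligible set; the pH variants become discriminating only under
user-configured pH profiles (e.g. a duodenal pH below 6).

**Absorption.**  Apical uptake clearance per segment is
permeability × fluid-wetted area × regional absorption scalar, where the
wetted area is the cylindrical mucosa scaled by the fraction of the segment
volume the resting fluid occupies (algebraically 2·V_fluid/r).  The intrinsic
transcellular permeability is P_trans,0 = a·P_o:w^b = 1798.5 × 1e-6 cm/s
(a = 2.36e-6, b = 1.1, logP 2.62), plus a small paracellular term.  Regional
absorption scalars are 0.06 (duodenum), 0.12 (jejunum), 0.54 (ileum) and
1.44 (colon).  The colon additionally carries a mucosal accessibility factor
of 0.05 (haustral sequestration and mucus), a calibration without which the
small colonic fluid volume would absorb implausibly fast and colonic lumen
concentrations could not reach the ~0.1 mM scale expected for this product.

**Enterocyte layer.**  Enterocytes receive apical influx, lose drug to
P-gp efflux back to the lumen (Michaelis–Menten on unbound enterocyte
concentration, J_max 93 pmol/min/cm² scaled by wetted area and a distally
increasing relative transporter abundance, K_m 9.4 µM — the literature cites
J_max without units, so the surface-density reading is configuration),
to CYP3A4 metabolism (4.1 µL/min/pmol scaled by segment abundance: the SI
total of 65.4 nmol distributed over the seven SI segments with a
proximal-heavy share vector, the colon's own 1.99 nmol total), and to
basolateral transfer (P_baso 6000 × 1e-6 cm/s on the same wetted area with an
area multiplier, default 5, representing basolateral amplification).  The
basolateral multiplier is the calibration that sets the enterocyte:lumen
concentration ratio (≈0.2–1.6% across segments at steady state, inside the
0.1–10% plausibility band) and a gut-wall extraction of roughly 35–45% in
the small intestine.  Enterocyte volume defaults to 1% of segment fluid
volume; it affects only equilibration speed and saturation, not the
steady-state concentration ratio, which is a clearance ratio.

**Systemic disposition.**  Portal inflow passes a well-stirred hepatic first
pass, E_H = fu_b·CL_int,liver/(Q_H + fu_b·CL_int,liver), with whole-liver
CL_int scaled from 4.1 µL/min/pmol × abundance (137 pmol/mg healthy) ×
MPPGL 40 mg/g × 1650 g liver = 2224.5 L/h; at fu 0.15 and B:P 0.8 this gives
E_H ≈ 0.82, the expected extensive first pass.  Distribution is a lumped
two-compartment model with V_ss = K_p-scalar (0.8) × 2.69 L/kg × body
weight; the central fraction (0.35) and inter-compartment clearance (30 L/h)
are defaults chosen to give a biphasic decline — full tissue-composition
K_p prediction is deliberately out of scope.  Elimination is hepatic
(Q_H·E_H) plus renal CL_R = fu × GFR = 1.55 L/h at fu 0.15 and GFR
172.42 mL/min; the GFR printed per 1.73 m² is used directly as mL/min for
the representative, matching the source arithmetic.  The unbound fraction is
rescaled from albumin by fu' = 1/(1 + (1−fu)/fu · HSA'/HSA_ref), a
proportional binding-capacity stand-in for an explicit K_D model.

**Solver.**  Stiff BDF integration with analytic Jacobian, rtol 1e-8, atol
1e-10 nmol, default output 0–24 h at 0.25 h.  The enterocyte compartments are
fast (rate constants up to ~1e4/h), which the Jacobian-supplied BDF handles
in ~0.1 s per subject.  Reduced-configuration switches (instant release into
a chosen segment, single absorbing segment, enterocyte bypass,
one-compartment disposition, P-gp and gut-metabolism toggles) let the model
collapse onto the closed-form first-order-absorption (Bateman) solution,
which it matches to ~1e-6 relative — the primary structural verification.

## Populations and variability

Healthy volunteers: Table-level means are gastric/SI fluid MRT 0.27/3.4 h,
liver CYP3A4 137 pmol/mg, SI CYP3A4 65.4 nmol, colon CYP3A4 1.99 nmol, HSA
50.34 (M) / 49.38 (F) g/L, sex-specific colonic MRTs.  The Crohn's-disease
population overrides exactly four parameters: liver CYP3A4 55.4 (M) /
80.5 (F), SI CYP3A4 8.6, colon CYP3A4 0.2, HSA 30.13 (M) / 25.2 (F).  With
variability off, the CD representative has ≈2.5× the healthy plasma AUC at
the same dose (less first pass at both gut and liver).

Between-subject variability is not published for the source populations;
package defaults are lognormal CVs of 30% on enzyme abundances, 20% on
residence times and GFR, 15% on albumin and body weight, truncated to
physiological bounds — configuration flagged as assumption, not data.
Within-subject (occasion) variability follows the published table: gastric
fluid MRT CV 38.217% on [0.01, 12] h, SI fluid MRT 21.132% on [0.5, 12] h,
colonic fluid MRTs 44.962% on [0.1, 240]/[0.1, 72] h, applied as independent
mean-one lognormal redraws per period and clamped to the limits.  Occasions
are independent (only CVs and limits are published, not correlations).

The one-at-a-time local sensitivity analysis sweeps each parameter over the
healthy↔CD span (5 points, log-spaced when the span exceeds 3×) with
deterministic simulations of the representative; plasma AUC_last falls
monotonically as hepatic CYP3A4 rises, the expected dominant axis.

## Virtual BE trials and statistics

The design is the standard two-sequence, two-treatment, two-period crossover:
10 trials × 12 subjects, sequences TR/RT balanced 6/6, complete washout (no
carryover is simulated).  A fresh cohort is drawn per trial; within a trial
the same subjects face both formulations, and the occasion redraw belongs to
the period, shared by whichever treatment that period carries.  Plasma is
sampled on a clinical 13-point schedule (0–24 h); gut sites use the dense
solver grid, since local "sampling" is a modelling construct.  NCA uses the
linear trapezoid to the last positive concentration; C_max and earliest
t_max complete the metric set (AUC_inf and t_max statistics are out of
scope).

The BE analysis is the mixed model with sequence, period and treatment fixed
and subject-within-sequence random — which for balanced complete 2×2 data
reduces exactly to the closed-form contrast implemented here: the treatment
effect is half the between-sequence difference of mean within-subject period
differences, with a t-based 90% CI on n₁+n₂−2 df.  The equivalence of the
closed form with a brute-force linear-model fit is asserted on 200 random
datasets to 6 decimals (they agree to machine precision).  BE requires the
90% CI of the geometric mean ratio within [0.80, 1.25]; a formulation is BE
overall when ≥ 80% of trials conclude BE (≥ 8 of 10; ceil(0.8 n) generally).
The combined metric declares a trial BE only when both AUC_last and C_max
are BE, combining per trial before applying the ≥ 80% rule.

## Discordance classification

Each (formulation, segment, metric) cell pairs the plasma decision with the
local decision: true positive (BE/BE), true negative (NBE/NBE), false
positive (plasma BE, locally NBE — a substandard product passing a PK BE
study) and false negative (plasma NBE, locally BE — a usable product
rejected).  Heatmap rows are ordered by f2 (most similar first) with
trigger-pH variants last; the rendered figure encodes local NBE as hatching,
and all semantics are carried in the exported CSV, which round-trips
losslessly.

Under the default study conditions the package reproduces the qualitative
headline: for the ±10% dissolution shifts the duodenal-enterocyte AUC
displacement exceeds the plasma AUC displacement in 10/10 trials, plasma
AUC remains BE while upper-gut sites fail (false-positive cells), and plasma
C_max is the more sensitive plasma metric, flagging the ±10% variants NBE.
The null comparison (reference vs itself with occasion variability on)
passes plasma BE in 10/10 trials at n = 12, confirming the design is not
anti-conservative by construction.

## Problem sizes and scale choices

The panel driver's default scale is 3 trials × 8 subjects × 3 formulations
in each population (a few minutes on one CPU); the full 8-formulation,
10 × 12 design sits behind a flag (`lumenvbe panel --full`).  The acceptance
script runs the full 10 × 12 design for the null and ±10% comparisons
(~90 s total), a 50-simulation randomized mass-balance sweep, and the
closed-form oracles.

## What the synthetic conditions do and do not show

The virtual populations emulate parameter-level physiology (residence times,
abundances, binding), not covariate structure: no height/weight/organ-size
correlations, no age dependence of GFR or abundances, no correlated WSV
across parameters.  Dissolution replicates are noise around a smooth Weibull
curve, not real vessel data, so the bootstrap f2 CI describes assay-style
noise only.  The gut model omits bile-micelle solubilisation, supersaturation
and precipitation, fed-state physiology, metabolite kinetics, and mechanistic
dissolution; colonic accessibility and the basolateral area multiplier are
calibrations, not measurements.  Passing tests therefore demonstrate internal
consistency, closed-form correctness and the direction and rough magnitude of
the local-vs-systemic discordance mechanism — not clinical predictivity for
any specific product.

## Known limitations

* Table-printed f2 values and the exact simulated exposure tables of the
  source platform are treated as inputs or qualitative anchors, never as
  reproduction targets; the proprietary fluid-dynamics absorption machinery
  is replaced by the documented transit/wetted-area surrogate above.
* The trigger-pH panel variants are non-discriminating under the default
  segment pH profile (all intestinal segments ≥ pH 6); exploring them
  requires a user-supplied pH profile.
* Local dosing (colonic administration with time-axis compensation) and
  dropout handling in the BE analysis are not implemented.
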