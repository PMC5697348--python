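# Methods

## Model structure and assumptions

The simulator tracks nine state variables of a batch culture: one
intracellular metabolite pool (acyl-ACP), one culture-level product
(free fatty acid, FA), cell number (OD600), two relative nutrient
reservoirs, the alarmone ppGpp, relative ribosomal activity, and a
two-stage transcriptional biosensor (repressor I, reporter GFP). All
rates are deterministic mass-action/Michaelis–Menten/Hill laws; time is
in minutes, intracellular concentrations in uM, FA in mg per litre of
culture.

Key structural assumptions:

- **Lumped enzymology.** Fatty-acid synthesis (FAS), phospholipid
  synthesis (PLS, committed step PlsB) and thioesterase (Tes) are single
  saturable reactions. FAS carries linear product inhibition by
  acyl-ACP; PLS carries Hill inhibition by ppGpp (n = 2, the minimal
  cooperative choice for the multi-level regulation of PlsB); Tes is
  plain Michaelis–Menten in acyl-ACP.
- **Protein-synthesis coupling.** FAS, PLS and growth are proportional
  to ribosomal activity `rib`, whose synthesis is proportional to the
  activity of the tandem rRNA promoter P1/P2. P1/P2 responds to ppGpp
  within minutes, so it is algebraic: `P1P2 = 1/(1+(ppGpp/Ki)^m)` with
  m = 2 for the tandem promoter.
- **Two-nutrient phase phenomenology.** Depletion of `lim` ends
  exponential growth by slowing ppGpp hydrolysis (SpoT inhibition);
  depletion of `nutr` ends growth altogether. Both deplete
  proportionally to cell number with a saturation floor of 0.001 that
  prevents negative values. Phase boundaries are defined operationally
  as the first downward crossings of 0.01 (linearly interpolated) —
  insensitive to the floor and reproducible.
- **ppGpp balance.** Synthesis is ribosome-bound (rate `kp_ppGpp·rib`);
  hydrolysis has a `lim`-dependent part and a background part, both
  gated by acyl-ACP occupancy of SpoT
  (`AcylACP/(AcylACP+Km_Ac_pp)`), which is how acyl-ACP depletion in
  high-Tes lines raises ppGpp without any nutrient change.
- **Downstream-only sensor.** I and GFP appear in no other equation.
  Synthesis and degradation rate constants of each sensor protein are
  equal, so both variables live in [0, 1]. mRNA is collapsed into the
  protein equations (protein lifetimes dominate); GFP repression uses
  l = 4 for the tetrameric repressor–operator complex.
- **No dilution by division** (< 0.01 /min, slow against every other
  rate) and no GFP photophysics; GFP is a relative amount.
- ACP and acetyl-CoA are constant, saturating pools by default
  (`acp_coupling="constant"`); a conservation variant
  (`ACP_free = ACP_const − AcylACP`) is switchable for exploring the
  alternative reading, but the shipped calibration uses the constant
  form, consistent with the nine-variable state.

## Parameters

Printed, fixed constants: `m_hill = 2`, `l_hill = 4`,
`k_GFP = 0.1 /min`, depletion floor 0.001, control-line Tes activity
0.08 mg/l/OD/min and producer-line activities 1.6 / 19 / 110 (a
sweep-diagnostics context also lists line 3 at 100; both are shipped as
presets `line3` and `line3_fig5`). Sensor coupling strengths
`Ki_I ∈ {0.02, 0.1, 0.3}` are shipped as named presets
(`diagnostics_steep`, `diagnostics_optimal`, `response_time_reference`).

Everything else is fixed by a documented, deterministic calibration
(`experiments.calibrate_reference_set`) against six constraints, checked
in order on candidate sets drawn from fixed grids over the two
most scale-uncertain parameters (the volume conversion `k_fa` and the
SpoT half-saturation `Km_Ac_pp`), base values first:

a. control-line ppGpp peaks within one output step (10 min) of the
   phase-1 boundary;
b. that peak lies in the observable window 50–1000 uM;
c. ppGpp declines after its peak during phase 2 (by > 5%);
d. growth stops when `nutr` depletes (final specific growth rate below
   1% of its maximum);
e. the 24-h FA yield vs Tes activity curve has an interior maximum;
f. the 24-h yield ratio line 1 : line 3 is 3.0 ± 15%.

The first feasible candidate is shipped as the package default
(`ModelParameters()`), and a regression test re-runs the search. With
the shipped set the measured quantities are: phase boundaries 209 and
398 min, control ppGpp peak 480 uM lagging the phase-1 boundary by
3.9 min, a yield optimum near V_tes ≈ 15–20 mg/l/OD/min, and a yield
ratio of 2.92.

Choices worth flagging:

- **Ribosomal gain** `kp_rib/km_rib = 2`, so `rib` relaxes to
  `2·P1P2`. `rib` is a relative activity, not a fraction; the gain lets
  normal growth coexist with a mid-range exponential-phase P1/P2
  activity (~0.55), which in turn gives the stringent spike room to
  drive P1/P2 deep — the dynamic range the biosensor reads. With the
  spike, P1/P2 falls to ~0.05 and stationary-phase activity settles
  near 0.12.
- **Repressor turnover** `k_I = 0.15 /min`: a rapidly degraded
  repressor, comparable to the GFP turnover it controls. Much faster
  and the repressor stage stops shaping the response time (the
  inhibition-strength effect on T0.5 disappears); much slower and the
  sensor cannot follow the spike at all.
- **ppGpp scale**: `kp_ppGpp`, `Ki_P1P2_ppGpp` and `Ki_ppGpp` jointly
  set the absolute ppGpp axis (the dynamics depend only on their
  ratios). They are placed so that exponential-phase ppGpp is ~130 uM,
  the control-line peak ~480 uM, and the steady-state dose–response is
  informative across 50–1000 uM — the physiologically observable
  window.

## Scenarios, events, and the upshift protocol

A `Scenario` is a parameter set, an initial state (or pre-equilibration
directive), a horizon (default 1440 min = 24 h, the yield horizon), an
output grid (default 10 min for batch runs; 0.5 min for response-time
runs) and an event schedule. Events are instantaneous resets
(`set_lim`, `set_nutr`, `clamp_ppGpp`, `release_clamp`) applied at a
fixed time or at the first downward crossing of a core state variable;
integration restarts at the event, so trajectories are exact piecewise
solutions.

Default initial conditions: fresh medium (`nutr = lim = 1`), inoculum
N = 0.01 OD, no FA; acyl-ACP, ppGpp and `rib` at their
exponential-growth quasi-steady state, obtained by a pre-equilibration
run with both nutrients clamped (this avoids spurious transients and
makes initial conditions a deterministic function of the parameters);
the repressor starts fully expressed (I = 1) with GFP at the matching
repressed level `1/(1+(1/Ki_I)^l)`.

The **nutrient upshift** used for response-time measurements resets
`lim` to 1, triggered at the crossing of `lim` through 0.01 *plus a
fixed 12-minute delay*. The delay matters: `lim` collapses from 0.01 to
its floor within about a minute, while the ppGpp spike and the sensor's
GFP rise develop over the following ~10 minutes. Upshifting exactly at
the crossing would catch GFP still near its baseline, and a two-fold
GFP decrease — the definition of T0.5,GFP — would not exist. The
delayed upshift reproduces the intended protocol: the medium is
restored once the sensor already reports starvation, and T0.5,GFP
measures how fast the signal relaxes. With the reference sensor
(k_GFP = 0.1, Ki_I = 0.3) T0.5,GFP is 11.4 min; tenfold faster GFP
turnover shortens it to 3.5 min, tenfold stronger inhibition
(Ki_I = 0.03) to 8.3 min, and tightening Ki_I from 0.1 to 0.02 both
shortens the response and lowers its amplitude — the rate/amplitude
trade-off.

## Numerics

- **Integrator**: SciPy `solve_ivp` with BDF, rtol 1e-8, atol 1e-10.
  The system is stiff (acyl-ACP turns over in seconds under high Tes
  drain while the culture evolves over a day). All reported outputs are
  stable to < 0.1% under tolerance halving; the residual is dominated
  by the timing sensitivity of the steep nutrient crashes.
- **Exact sensor cascade**: the 7-variable core system is solved first;
  the (I, GFP) pair is then integrated against the dense core solution.
  This honours the model's one-way coupling exactly, so perturbing
  sensor parameters leaves the core trajectory bit-identical — a
  structural property the tests assert literally.
- **Non-negativity**: every loss term vanishes at zero, so the flow
  preserves the non-negative orthant; the tiny negative excursions a
  multistep solver can produce are clipped to zero inside the
  right-hand side (the identity on valid states, preserving the
  algebraic flux-balance identity exactly).
- **Peaks** are refined by a parabola through the three samples
  bracketing the discrete maximum (grid-independent); **crossings**
  (phase boundaries, T0.5) are linearly interpolated.
- **Steady-state dose–response** uses the closed form
  `I* = P1P2(ppGpp)`, `GFP* = 1/(1+(I*/Ki_I)^l)`; a long clamped-ppGpp
  simulation serves as an independent ODE oracle and agrees to < 1e-6.
- **Yield inversion** (`calibrate_vtes`) brackets one branch of the
  non-monotone yield curve and uses Brent root finding to ~1e-3
  relative; non-uniqueness across the optimum is the caller's to
  resolve by choosing the bracket.

## Problem sizes

The shipped studies are desk-scale: a 24-h batch run integrates 9 ODEs
over 1440 min (fractions of a second); the default Tes sweep uses 25
logarithmic points on [0.01, 300] mg/l/OD/min (the test suite uses 13);
the sensitivity scan covers 24 kinetic parameters at folds 0.5 and 2
with a 7-point sweep per cell (tests scan representative subsets). The
full test suite runs in well under a minute.

## Known limitations

- The reference parameter set reproduces the qualitative figure
  topology and the printed quantitative anchors (yield ratio, ppGpp
  window), not any unpublished fitted values; absolute yields and OD
  values should be read as order-of-magnitude.
- Far beyond the producer-line range (V_tes ≳ 130 mg/l/OD/min) the
  culture is growth-arrested from inoculation, `lim` never depletes,
  and the batch ppGpp/GFP transient disappears; sweep diagnostics are
  therefore asserted on the line range [0.08, 110] only.
- FA keeps accumulating slowly in stationary phase (ribosomal activity
  does not vanish); the model has no maintenance or death terms.
- The GFP dose–response saturates above ~700 uM with the optimal sensor
  (Ki_I = 0.1); resolution at the top of the observable window requires
  the weaker-coupling preset.
- Batch culture only; no chemostat mode, no stochasticity, no explicit
  RelA/SpoT enzyme states, no mRNA dynamics.
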