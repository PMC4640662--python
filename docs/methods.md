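# Methods

## Model structure

The pancreas is a population of N independent secretory units. Unit *n*
is described by three states — threshold B_n (mM), releasable packet J_n
(pmol/kgBW), potentiation D_n (pmol/kgBW) — and nine parameters: resting
threshold G_n, refractory threshold R_n, recovery rate α_n, packet decay
rate k_n, basal packet D̄_n, maximal potentiation-loading rate ρ_n,
half-potentiation glycemia Γ_n, potentiation steepness γ_n, and packet
relaxation rate ζ_n. Firing is a state-triggered impulse: whenever the
sensed glycemia satisfies G ≥ B_n (threshold crossing *or* exceedance, so
units whose threshold decays below a steady glycemia also fire), the unit
releases J_n, sets J_n = 0 and jumps B_n to R_n. Because R_n ≈ 1000 mM,
the unit is absolutely refractory until B_n decays back into the
physiological range; the exponential decay rate α_n sets the refractory
period, log((R_n − G_n)/(G − G_n))/α_n at constant glycemia G.

Potentiation is second-order: D_n integrates a Hill function of glycemia
delayed by τ (τ = 8 min in vivo, 0 in vitro), and J_n relaxes toward D_n
at rate ζ_n. This separation produces the biphasic response: the first
phase releases the standing packets of all units recruited by a glucose
step; the second phase reflects packet regrowth toward a rising D_n plus
cyclic re-firing of the recruited subpopulation.

Heterogeneity: G_n follows the Hill CDF F(g) = g^ν/(g_half^ν + g^ν),
identified by unweighted OLS (in mM; mg/dl divided by 18.016) from the
six percent-activation points shipped in
`isletsim/data/grodsky_activation.csv`. Our fit gives ν = 2.5277,
g_half = 9.7701 mM (the originally reported values are ν = 2.5137,
g_half = 9.7697 mM; the ~0.6% difference in ν is within optimizer/units
conventions, and the packaged species defaults carry the original
values). All other parameters are independent log-normals; the tabulated
"mean"/"sd" pairs are interpreted as arithmetic moments and moment-matched
to log-space (σ² = ln(1 + sd²/mean²), μ = ln mean − σ²/2). sd = 0
degenerates to a point mass. G_n samples are truncated to (0.1, 100) mM —
the Hill distribution's tails are heavy and sub-0.1 mM or supra-100 mM
thresholds are physiologically meaningless; the excluded mass is ~0.3%.

Population-size invariance: the packet-size means (D̄, ρ) scale by
N_ref/N (N_ref = 10⁵ in vivo, 10⁴ in vitro), keeping the organ's total
available insulin fixed, so N is a numerical resolution knob rather than
a physiological quantity. Standard deviations are not rescaled; their
tabulated values are small enough that this choice is immaterial.

## Environments

**In vivo (human).** Released insulin enters a liver chain of L
compartments (L = 1 by default, configurable): transfer rate h_d carries
insulin toward plasma and h_x clears it, so the hepatic extraction
fraction is h_x/(h_d + h_x) = 0.357 at the defaults. Plasma insulin I
(pM) clears at k₄ with distribution volume V_I. Glycemia obeys

    dG/dt = −k₁·max(0, G − G_u) − k₂·I·G + (k₃(t) + k_ga·A + k_ex(t))/V_G,

with renal spill above G_u, insulin-dependent uptake k₂·I·G (negative
sign; insulin is hypoglycemic), and net hepatic output k₃(t) = k̄₃ +
sat(ξ(t)) where ξ is an Ornstein–Uhlenbeck process (reversion a,
volatility b; stationary sd b/√(2a) ≈ 2.0·10⁻³ mmol/kgBW/min) clipped to
[m, M]. Enteral feeding fills a splanchnic compartment A absorbed at
k_ga; IV infusions k_ex enter glycemia directly. ξ₀ is drawn from the
stationary distribution.

The closed loop's fixed point is set by k₂·I·G = k̄₃/V_G: at the default
parameters the model settles at ~5.2 mM fasting glycemia and ~70 pM
insulin. The parameter G_b = 4.25 mM serves as the initial condition and
the pre-run delay history, not as the equilibrium.

**In vitro (rat).** The protocol imposes the perfusate glucose
concentration directly (no transport delay, τ = 0). Released insulin
flows through the loss-free linear chain portal → serum → measurement
(rates k_ip = 0.85/min, k_mi = 4.8/min; the source tabulates k_ip both
as 0.85 and 0.8 — we use 0.85). ISR(t) = (M(t+Δ) − M(t))/Δ with
Δ = 0.5 min, mimicking timed effluent collection. The basal state is
zero glucose with B_n = G_n and J_n = D_n = D̄_n; no burn-in.

## Numerics

Fixed-step integration at dt = 0.1 min in vivo and dt = 0.5 min in
vitro. Firing is checked before the continuous update, on start-of-step
state; simultaneous eligibility fires all eligible units in the same
step, and a unit fires at most once per step.

Unit ODEs are advanced with an exponential integrator: B_n's update is
exact (its input G_n is constant) and J_n, D_n use exact relaxation with
inputs frozen over the step (first-order accurate overall). We do not
use explicit Euler here because α_n is log-normal — in vitro
(mean 0.65, sd 0.4/min) its upper tail violates the Euler stability
bound 2/dt at dt = 0.5 — while the exponential update is unconditionally
stable and no slower. For the same reason the in vitro P→I→M chain uses
its exact matrix-exponential transition (k_mi·dt = 2.4 would make Euler
diverge); this also conserves chain mass to round-off. The in vivo
environment uses explicit Euler (all its rates are far inside the
stability region) with the released mass injected into the liver
compartment as an impulse before the continuous update; the insulin mass
ledger (released = hepatic clearance + plasma clearance + stored) then
closes exactly by construction, which the test suite asserts.

Delayed glycemia G(t − τ) is read from the stored glycemia trace with
linear interpolation; pre-history is G_b (in vivo).

In vivo runs start from an analytic basal guess (B_n = G_n, J_n = D_n at
the asymptotic packet size for G_b, empty insulin stores) followed by a
600-min closed-loop burn-in with no exogenous input, long relative to
every time constant in the loop (the slowest is the ~100-min ultradian
cycle); protocol time 0 starts after the burn-in. Reported in vivo series
are sampled every 1 min (glycemia and insulinemia at bin starts, ISR and
firing counts summed per bin).

## Protocols and phenotypes

Protocol builders cover: the staircase (50→200 mg/dl in 50 mg/dl steps
every 5 min), constant perfusions (50–500 mg/dl), 300 mg/dl
stimulation–5-min washout–restimulation, ramp-and-hold, pure ramp,
constant/sinusoidal/pulsed IV infusion, constant enteral feeding, and the
IVGTT bolus (0.36 g/kgBW over 3 min; 180.16 g/mol) with the standard
23-point sampling schedule. Conversions: 18.016 mg/dl per mM; 4 kcal/g
glucose-equivalent for enteral feeds (90 kcal/h at 60 kg ↔ 0.035
mmol/kgBW/min); 0.2 g/cc infusion solution for pump settings
(6 mg/kgBW/min at 70 kg ↔ 126 cc/hr).

The ramp-and-hold default rises to 150 mg/dl over 40 min and holds
30 min. The hold level deliberately sits near the mode of the threshold
distribution: the drop in ISR at hold onset is the loss of the
recruitment flux N·f(G)·dG/dt, which is a substantial share of total ISR
only where the threshold density f is large. Holding at 300 mg/dl (above
the distribution bulk) produces no visible drop because recruitment is
already exhausted and potentiation growth dominates. Both ramp protocols
are configurable.

Phenotype scenarios multiply (k₂, k̄₃, mean ρ, mean D̄) by
(1, 1, 1, 1) NGT; (1, 1.6, 0.5, 1) IFG; (0.65, 1, 0.5, 1) IGT;
(0.65, 1.6, 0.25, 1) IFG+IGT; (0.3, 1.6, 0.05, 0.3) T2DM. The
`T2DM-shift` variant additionally sets g_half = 4 mM, modeling a left
shift of the recruitment distribution; at its hyperglycemic baseline most
units are then already recruited, which abolishes the first-phase IVGTT
response.

## Analysis conventions

- Assay noise: multiplicative Gaussian, value·(1 + cv·z), floored at 0
  (cv = 1% glycemia, 5.8% insulinemia where used); three-point centered
  moving-average filter with endpoints copied.
- Pulse detection: `scipy.signal.find_peaks` with prominence ≥ 0.5 × the
  standard deviation of the series. For fast pulses riding the ultradian
  swing, an optional detrending window (moving-mean subtraction, 30 min
  for 10-min pulses) relocates the peak search; the prominence scale
  stays the raw-series SD, so a pulse counts only if it is appreciable
  against the overall signal variability.
- Period estimation: lag of the first autocorrelation peak with
  prominence ≥ 0.2, after subtracting a centered moving mean (240 min
  for ultradian work) and normalizing the acf. White noise is reported
  as "no significant period" (None). The estimator needs ten or more
  cycles; ultradian analyses therefore use 24-h runs, matching the
  duration of the underlying feeding/infusion experiments. In irregular
  feeding runs whose consecutive cycles alternate in amplitude, the
  first prominent acf peak can be the two-cycle lag (~190–200 min);
  the estimate is deterministic and stable across population sizes,
  which is what the convergence check requires.
- Entrainment ratio: fraction of forcing periods [kT, (k+1)T) containing
  exactly one detected pulse; 1 is perfect 1:1 locking.
- Phase metrics for step stimuli: first-phase peak within 5 min of
  onset, nadir within the following 15 min, second-phase slope over the
  30 min after the nadir.

## What the simulations do and do not establish

All experiments are self-generated: the only measured inputs are the six
percent-activation points and the tabulated meta-parameters. Passing
tests therefore show that the published mechanism with the published
parameters reproduces the qualitative and quantitative experiment
families — not that the model is identified from raw data. Known
limitations:

- The closed-loop fasting glycemia (~5.2 mM) is an emergent equilibrium
  ~20% above the G_b parameter; it lies in the normal human fasting
  range, but G_b should not be read as the model's steady state.
- The threshold-distributed population has no small-signal excitability
  floor: arbitrarily small periodic IV inputs (e.g. 2 mg/kgBW/min
  pulses) still produce a coherent phase-locked insulinemia ripple of a
  few pM. Experimentally such a ripple would vanish below assay noise;
  a scale-invariant detector finds it whenever the surrounding 90-min
  window happens to have a quiescent ultradian component. "No
  appreciable response" at small forcing is thus a statement about
  measurement scale, not about the dynamics.
- No glucagon, incretins, neural modulation, intracellular calcium or
  granule-pool dynamics, or inter-unit coupling; the liver is a linear
  chain; enteral nutrition is a single first-order compartment with all
  calories treated as glucose equivalents.
- Euler discretization of the in vivo environment carries O(dt) bias
  (e.g. the liver mass fixed point is r(1 − (h_d+h_x)dt)/(h_d+h_x)
  under constant release r); at dt = 0.1 min this is a few percent on
  compartment masses and does not affect the mass ledger, which closes
  exactly.
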