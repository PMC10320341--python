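# Methods

## The model

Three interconverting forms X1, X2, X3 of a single protein complex live
on a closed 1-D domain of length L (no-flux ends, total molecule number
N conserved).  They react through three reversible linear conversions
(X1<->X2 with k12/k21, X2<->X3 with k23/k32, X3<->X1 with k31/k13) and
one reversible autocatalytic step X1 + 2 X2 <-> 3 X2 (kt12/kt21), and
diffuse with constants D1, D2, D3 (activator X2 slow; D1 = D3 by
default, as the two species are conformations of the same complex).
The network has two independent reaction cycles whose irreversibility
parameters

    Gamma  = kt21 k12 / (kt12 k21),      Gamma' = k13 k32 k21 / (k12 k23 k31)

equal 1 at thermodynamic equilibrium.  W = -ln Gamma is the free energy
(kT) dissipated per completion of the dominant cycle; it is the single
driving knob in all sweeps (varied through kt21 with everything else
fixed).

Units: 1-D concentrations u = n/dx in um^-1; the autocatalytic rate
constants therefore carry units s^-1 um^2, matching the reference
parameter sets.  The concentration convention makes the cubic term
kt12 u1 u2^2 dimensionally consistent.

Two bundled presets hold the reference parameter values: `accuracy`
(k21 = 3.6 s^-1, kt12 = 1.67e-5 s^-1 um^2, slow X3 cycle, D1 = 0.3,
D2 = 0.012 um^2/s, L = 6 um, 60 boxes, N = 7200) and `robustness`
(ten-fold faster X3 cycle, D1 = 1.8, operating Gamma = 0.011).  The
`robustness` set does not pin kt12 independently; it is derived from
the declared Gamma, kt12 = kt21 k12/(Gamma k21) = 2.1086e-4 s^-1 um^2.
The `accuracy` preset's default kt21 = 1e-6 s^-1 um^2 (W = 4.79) sits
well inside the patterned regime; the source value of k12 is a swept
list, and the preset default is k12 = 0.5 s^-1.

## Dissipation accounting

Every channel (reaction in a box, hop between boxes) dissipates
(J+ - J-) ln(J+/J-) >= 0 in kT/s.  Chemical and diffusive dissipation
rate densities are evaluated from concentration fields; the diffusive
density exists in a continuum form, sum_k D_k (du_k/dx)^2 / u_k, and a
discrete hop-flux form that matches the lattice model channel by
channel.  At a steady state the spatial integral of the two densities
collapses to the cycle-flux expression

    Wdot = J_1c ln(1/Gamma) + J_2c ln(1/Gamma'),

with J_2c = k23 N2 - k32 N3 the three-state-loop flux and J_1c the
integrated net autocatalytic flux, which the steady-state balances give
from species totals as J_1c = (k21 N2 - k12 N1) + (k23 N2 - k32 N3).
With this identification the identity holds to machine precision at a
Newton-polished discrete steady state, and J_1c >> J_2c (the
autocatalytic cycle dominates the energy budget).  Identifying J_1c
with the linear-reaction flux k12 N1 - k21 N2 instead breaks the
identity (the expression can go negative); this package uses the
channel-consistent form above.

The closed-form estimate for the diffusive/chemical dissipation ratio,
(2 pi^2 / W)(Delta_u2/<u2>)^2, is provided
(`thermo.diffusive_fraction_estimate`) but should be treated as
trend-level only: for the bundled presets it overstates the directly
integrated ratio (~0.02) by about two orders of magnitude, while its
qualitative dependences (zero at zero amplitude, decreasing in W) hold.
Quantitative work should use `thermo.dissipation_breakdown`, which
computes the ratio by direct integration.

Stochastic dissipation is available through two estimators: a
mean-field plug-in (the deterministic formulas applied to time-averaged
concentrations) and an exact per-event tally of ln(a_fwd/a_rev) along
the trajectory.  The tally has zero mean at equilibrium and is used for
the detailed-balance null test.

## Linear stability and onsets

The dispersion relation rho(q) is the largest real eigenvalue part of
J - q^2 diag(D) at the homogeneous fixed point.  The fixed point is the
root of the well-mixed equations reached by relaxation from the
equal-partition state; for parameter regions with multiple nonnegative
roots (small k12 at weak kt21) all roots are exposed through
`all_fixed_points`, and the onset machinery is only defined on the
relaxation branch.  The q -> 0 growth rate is exactly zero along the
conservation direction, so onset bisections evaluate the maximum growth
on q >= 0.3 um^-1.

The infinite-system onset kt0 is the kt21 at which max_q rho = 0.
Finite systems quantize the wavevector (q_n = 2 pi n / L, wavelength
L/n; the Neumann-cosine convention q = n pi / L is available as a
switch), and phase stability of the n-stripe pattern requires the
stricter

    ktc = kt0 (1 - 3 xi^2 dq^2),     dq = q_n - q0,

where xi^2 = -(tau/2) d2rho/dq2 at q0 and tau is the reciprocal of
kt0 |drho/dkt21| at onset, so that rho ~ (eps0 - xi^2 (q-q0)^2)/tau
near onset.  This normalization (curvature scaled by the onset
timescale) makes 3 xi^2 dq^2 dimensionless and reproduces ktc <= kt0
with zeta = ktc/kt0 in (0, 1) for the monostable part of the k12
family; it is the package's own reading of the implicit definitions of
xi and tau.

d_min is the smallest diffusion ratio d = D1/D2 (D2 fixed, D1 = D3
varied) with a Turing band at infinite driving (kt21 = 0).  The
reference rate set leaves k12 ambiguous (it is specified as a swept
list), so the headline number is the family minimum: min over the
listed k12 values of d_min(k12) = 1.72 at k12 = 0.4 (k12 <= 0.3 gives
no instability on the relaxation branch even at infinite driving;
k12 = 0.5 gives 1.95, k12 = 0.55 gives 2.05).  Below the family
minimum no pattern is possible for any rate choice in the family.

## The molecule-number window

In relative concentrations the autocatalytic rates become
beta_12(21) = kt_12(21) (N/L)^2, so N moves the system through the
onset.  In the fast-inhibitor limit (d >> 1) the critical effective
rate has the closed form

    beta0 = (k21 + k23)/v2*^2 - 2 (k12 v1* + k32 v3*)/v2*^3,
    v1*   = (1 - R2 v2*)/R1,
    R1    = (k31+k32+k13)/(k31+k32),   R2 = (k31+k32+k23)/(k31+k32),

derived from the vanishing of the activator self-coupling combined with
the steady-state balances, with v2* evaluated self-consistently at
beta21 = beta0.  The derivation was validated against the numeric
dispersion onset: the agreement becomes exact as d -> infinity, while
at the robustness preset's finite d = 150 the closed form overestimates
the onset by about a factor 2.  Gamma_0 = beta0 k12/(beta12 k21) and
Gamma_c(N) = zeta Gamma_0(N), with zeta evaluated once at the peak of
Gamma_0(N) and treated as constant across N.

Gamma_c(N) rises sharply to a peak at N* and then decays as N^-2.
Solving Gamma_c(N) = Gamma on the two flanks yields [N_min, N_max];
increasing the driving widens the window, with ln N_max growing with
slope 1/2 in the strong-driving asymptote (exactly, from the N^-2
tail) and with a fitted slope of about 0.44 over the two units of
driving above the operating point of the robustness preset.  Because
the closed form is a d -> infinity result applied at finite d, the
predicted window is systematically wider than the window measured by
direct stochastic persistence scans; the measured agreement factor is
about 1.5 on N_max (documented here, asserted as < 1.6 in the tests),
while N* and N_min agree much more closely.

## Stochastic simulation

The reaction-diffusion master equation is sampled exactly with the
direct Gillespie method on the box lattice: hops at D/dx^2 per molecule
(inward only at the ends), reactions with falling-factorial
combinatorial propensities (the backward autocatalytic channel needs
three distinct X2).  Per-box propensity subtotals are updated
incrementally; totals are refreshed periodically against float drift.
Snapshots store integer counts; total N is conserved exactly at every
event.  Replicates are seeded seed_base + index.  Statistical
exactness is tested against a brute-force enumeration of the one-box
master equation (496 states at N = 30), and mean-field convergence by
growing the volume at fixed concentration.

## Positional error

The central stripe (the one whose template position is nearest L/2) is
tracked with sub-grid resolution by parabolic interpolation through the
maximum box and its neighbours of the time-smoothed activator field
(10-sample window at 1 s sampling; the five-species analyses also
smooth over 3 boxes because their bound-species pool is noisier).
Stripe identity is followed by continuity from the domain centre, so a
neighbouring stripe wandering past the centre is not mistaken for the
tracked one.  Samples whose stripe count differs from the target are
flagged invalid; stripe counting uses prominence-filtered maxima (20%
of the profile range) with boundary half-stripes included.

Two sigma estimators are provided.  `track_peak` follows the
single-trajectory definition: the standard deviation of x_p(t) about
its own mean over valid samples after burn-in (the leading 20-30% of
the trajectory and everything before the stripe count has stabilized).
Parameter scans (`experiments.scan_sigma_vs_N`, `sweep_error_energy`)
instead pool valid samples across replicates and report the RMS
deviation from the template's self-positioned peak location.  The
pooled, anchored form was adopted after observing that run-level
rejection (discarding trajectories with many invalid samples)
preferentially censors strongly wandering trajectories and biases sigma
low exactly where the pattern is least stable; anchoring to the
template position keeps slow excursions in the estimate.  Replicates
still count as "sustained" only if at least 75% of their samples keep
the target stripe count, and a grid point is sustained if a majority of
replicates are.

## Phase-diffusion theory

The pattern phase obeys dphi/dt = D2 phi_xx - D4 phi_xxxx + dx(eta)
with conserved noise of strength Delta0.  The positional variance is
evaluated as a (q, omega) integral with the frequency integral done
analytically (pi/(D2 q^2 + D4 q^4)) and the q integral numerically from
pi/L; with D2 = d2 eps and constant D4 this reproduces
sigma^2 = sigma0^2 / S(eps), S(eps) = a sqrt(eps)/arctan(a sqrt(eps)),
a = (L/pi) sqrt(d2/D4), sigma0^2 = (lambda/2pi)^2 Delta0 L / D4, to
quadrature accuracy.  Expanding the error-reduction function about
strong driving gives the error-energy relation

    sigma = sigma_min / (1 - c1 exp(-dW) + h.o.t.),

fitted by nonlinear least squares with the series truncated at c1.
The desk-scale sweep bundled in the tests (three k12 values 0.4-0.5,
five dW values 0.3-3, three replicates, 180 s horizons at N = 7200)
recovers c1 within [0.7, 1.1]; the sweep is restricted to the
monostable part of the k12 family because the finite-system onset
construction is ill-defined on the multistable branch (k12 <= 0.35 at
weak kt21).

## Five-species Muk model

The MukBEF variant has species X1 (closed dimer-of-dimers, DNA-free),
M1 (DNA-bound intermediate), X2 (closed DD, DNA-bound), M2 (DNA-free
intermediate) and X3 (open dimer), with the DD loop
X1 -> M1 -> X2 -> M2 -> X1 (capture and release hydrolysis-driven, one
ATP each), a cooperative capture channel X1 + 2 X2 -> M1 + 2 X2 of the
same cubic form as the minimal model (DNA capture is strongly enhanced
by neighbouring bound complexes), and a de-dimerization path
X2 -> 2 X3 (both ATPs hydrolysed together, two fuel events) with
re-dimerization 2 X3 -> X1.  DNA-free species diffuse at 0.3 um^2/s,
DNA-bound at 0.012.  Conservation counts DD species with weight 2 and
the open dimer with weight 1 (a documented stoichiometric choice).

Driving enters through the ATP/ADP ratio measured in units of its
equilibrium value: forward rates are held fixed and each backward rate
is scaled by atp_adp^-n_hyd from its detailed-balance value, so
atp_adp = 1 is exact equilibrium (all cycle affinities zero; checked at
construction) and the DD loop and X3 path carry affinities 2 ln R and
3 ln R.  Keeping the forward kinetics pinned means the dispersion
relation, and hence the selected wavelength, barely move as the driving
is swept - the same protocol as the kt21 sweep of the minimal model.

The default rate table is the package's own choice (no reference values
are printed for this system), constructed to (a) satisfy cycle
consistency, (b) sustain a three-stripe pattern at the reference ratio
(about 100) in L = 6 um at the default monomer-equivalent total
N_w = 14400, and (c) reproduce the qualitative driving trends: sigma
non-increasing and N_max non-decreasing in atp_adp, loss of the
pattern at the equilibrium ratio, and formation with a smaller stripe
number below the lower bound of the supported ratio range (about 15).
The three-stripe state is obtained by seeding the mode at ratio 30
(where a weak seed converges directly) and continuing the solution in
ratio and total mass.

## Numerical choices

* Deterministic integration: method of lines, second-order central
  Laplacian with ghost-cell reflection, LSODA with banded Jacobian
  (box-major ordering), rtol 1e-8, atol 1e-12 c_tot.  Steady states
  are polished by a Newton solve in which one residual component is
  replaced by the mass constraint (the PDE Jacobian is singular along
  the conserved direction); the polished residual is at machine
  precision, which the dissipation identity test relies on.
* Pattern seeding: homogeneous fixed point plus a 1% cosine seed of
  the target mode, phased so activator peaks sit in the interior.
* Onset bisections to relative 1e-6; d_min to 1e-3 in a [1, 100]
  bracket; q-grid 800 points to 80 um^-1 with parabolic peak
  refinement.
* Well-mixed fixed points: exact cubic roots; multi-root cases resolved
  by ODE relaxation from equal partition (continuity tracking inside
  scans).
* The synthetic kymograph generator emulates stripes as Gaussian bumps
  with i.i.d. Gaussian centre jitter - no correlated phase dynamics,
  no amplitude noise, no stripe-count changes - so tracker-calibration
  tests validate the estimator, not the physics.

## Problem sizes

Stochastic test experiments are sized for a desktop run: error-energy
sweep 3 x 5 conditions x 3 replicates x 180 s; sigma(N) scan six N
values x 3 replicates x 250 s; Muk scans four ratios with 100-120 s
horizons and a three-point N grid.  Longer horizons sharpen the sigma
estimates (the tracked peak decorrelates over tens of seconds) but do
not change the qualitative outcomes.

## Known limitations

* The closed-form onset (and everything downstream: Gamma_c(N), the
  window, the fitted slope) is a d >> 1 result; at d = 150 it runs
  about a factor 2 above the numeric onset and the predicted N_max
  about 1.5x above the stochastically measured one.
* zeta is evaluated at one reference point and treated as constant in
  N and driving.
* sigma values at desk scale carry method dependence (smoothing,
  burn-in, anchoring) of order tens of percent; trend statements are
  robust, absolute values are not.
* The Muk rate table is illustrative; only its consistency rules and
  qualitative trends are meaningful.
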