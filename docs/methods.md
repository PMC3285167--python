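# Methods

`steerpmf` recovers equilibrium free-energy profiles from nonequilibrium
steered trajectories. This note records the models, the numerical choices,
and what the packaged toy systems do and do not establish.

## Units

Lengths in Å, energies in kcal/mol, time in ps, temperature in K,
k_B = 0.0019872041 kcal/(mol·K) — the conventional biomolecular-simulation
unit system. The default temperature is 300 K (k_B T ≈ 0.596 kcal/mol).
Spring constants are kcal/(mol·Å²); the overdamped drag coefficient γ is
kcal·ps/(mol·Å²), so the diffusion constant is D = k_B T / γ.

## Collective variables and restraints

The only CV class is the linear combination of distances (LCOD):
ξ(r) = Σᵢ cᵢ‖r_{aᵢ} − r_{bᵢ}‖ over ordered atom pairs with signed
coefficients. With pairs [(D,H), (A,H)] and coefficients (+1, −1) this is
the proton-transfer coordinate d(D,H) − d(A,H): negative while the proton
is donor-bound, zero at the donor–acceptor midpoint, positive after
transfer. Atoms may repeat across pairs; gradient contributions accumulate
additively, which a shared-hydrogen CV requires. A pair at zero separation
evaluates to zero but has no defined gradient, so gradient evaluation
raises there rather than returning an arbitrary direction.

Steering applies U(r, λ) = (k/2)(ξ(r) − λ)² with λ moving linearly between
two endpoints. A flat-well spherical restraint (zero inside a radius,
harmonic wall outside, C¹ at the wall) is provided to confine satellite
atoms — the standard device for keeping a water near an active site
without biasing its interior motion. No periodic-boundary minimum-image
handling is applied: the model systems are non-periodic by construction.

## Toy model systems

The synthetic-data engine emulates the statistical structure of replicate
steered runs — thermal noise at fixed temperature, snapshot initialization
from a restrained pre-run, per-replicate seeds, restraint lag, rare
unforced barrier crossings — while remaining exactly solvable. All systems
live on the x-axis: atoms carry 3-D coordinates (so the LCOD machinery is
exercised unchanged), but only selected x-components are mobile, and an
anchor atom frozen at the origin turns the distance CV into the mobile
coordinate itself. Consequently every oracle is a one-dimensional (or
separable two-dimensional) Boltzmann quadrature, with no Jacobian
(entropic 2kT·ln r) corrections to track.

* **dragged_harmonic_trap** — a free particle (U = 0); dragging a harmonic
  restraint across it has ΔF = 0 exactly. An optional static well
  (`k_well`) turns it into the equipartition test bed, and `n_particles`
  vectorizes many independent copies for cheap decorrelated sampling.
* **stiffness_switch** — a transverse harmonic mode whose stiffness
  interpolates geometrically from k1 to k2 (defaults k1 = 5,
  k2 = e²·k1) as the pulled coordinate crosses a switch window. The free
  energy along the pulled coordinate is linear inside the window, with
  ΔF = (k_B T/2)·ln(k2/k1) = exactly 1 k_B T at the default ratio. The
  switch window coincides with the steering range, and the pulled
  coordinate itself is flat, so the stiff-spring broadening error at the
  endpoints vanishes.
* **quartic_double_well** — U(x) = h((x−c)²/a² − 1)² (+ optional linear
  tilt), minima at c ± a, interior barrier h (default h = 2 kcal/mol
  ≈ 3.4 k_B T at 300 K, c = 2 Å, a = 1 Å). With a single mobile
  coordinate the PMF equals U up to a constant.
* **three_atom_transfer** — collinear donor–H–acceptor (donor–acceptor
  distance 2.8 Å, bond length 1.0 Å) with a quartic double well for the
  hydrogen (default barrier 1.5 kcal/mol ≈ 2.5 k_B T), low enough that
  unforced transfer events occur on tens-of-ps timescales.

## Integrators

Two schemes are provided, selected per protocol:

* **overdamped Euler–Maruyama** (default for unrestrained runs):
  x ← x + (F/γ)dt + √(2k_B T dt/γ)·ξ. Simple and adequate for soft
  landscapes, but only stable for k·dt/γ < 2 and it inflates the stationary
  variance of a harmonic mode by 1/(1 − k·dt/2γ); tests that compare
  variances choose dt so this inflation stays below ~5%.
* **BAOAB** (default for stiff-spring steering): the
  kick–drift–Ornstein-Uhlenbeck–drift–kick splitting with unit masses and
  collision rate γ/m. Configurational averages carry only O((ωdt)²) error,
  so the stiff k = 1000 kcal/(mol·Å²) restraint (ω ≈ 32 ps⁻¹) is
  integrated accurately at dt = 5 fs (ω·dt ≈ 0.16) — roughly 50× the
  largest stable overdamped step for the same spring.

Seeding is explicit: every replicate records its integer seed (NumPy
PCG64), and identical seeds reproduce trajectories bit for bit. Wall-clock
(system-time) seeding was deliberately not adopted; distinct fixed integers
achieve the replicate decorrelation that clock seeding is meant to provide,
without sacrificing reproducibility.

## Steering protocol

Replicates initialize from equally spaced snapshots of a pre-run restrained
at λ0, each with its own seed, so all starting states sample the same
restrained ensemble. λ moves linearly over the schedule (endpoints exact
by construction). Work is accumulated per integrator step via the midpoint
rule in λ, W += −k(ξ − ½(λⱼ + λⱼ₊₁))·Δλ, which is exact for a constant
integrand and consistent with one force evaluation per step; within a step
the dynamics feel the restraint at the step's target λⱼ₊₁. Work and
achieved-CV curves are decimated to a reporting grid (default: the
snapshot/sampling interval) rather than stored per step.

The default spring constant k = 1000 kcal/(mol·Å²) puts the equilibrium
restraint width √(k_B T/k) ≈ 0.024 Å far below every landscape feature, so
the restraint energy at even a 0.1 Å lag (5 kcal/mol) exceeds the toy
barrier heights — the stiff-spring regime in which work-vs-λ curves read
as work-vs-CV. Diagnostics report, per replicate, the maximum lag
|achieved − target|, the fraction of frames lagging beyond 4 widths
(flagged above 5%), the largest inter-frame CV jump (flagged beyond 10
widths — the operational definition of a catch-up discontinuity), and the
slope of the achieved-vs-target line.

### Desk-scale study conditions

The packaged oracle scenarios use 30 replicates with BAOAB, k = 1000,
γ = 0.5, dt = 5 fs:

| scenario | steering | steps | duration | exact answer |
|---|---|---|---|---|
| stiffness_switch | 1.0 → 2.5 Å | 10 000 | 50 ps | ΔF = 1 k_B T |
| dragged_trap | 1.0 → 2.5 Å | 10 000 | 50 ps | ΔF = 0 |
| double_well | 1.0 → 3.0 Å | 20 000 | 100 ps | PMF by quadrature |

At these pulling speeds the dissipated work is a few hundredths of k_B T
(measured, not assumed), placing the estimators in the near-equilibrium
regime where 30 replicates resolve ΔF to better than 0.1 k_B T. The
full-scale preset (30 × 2 000 000 steps of 0.5 fs = 1 ns, sampled every
2.5 ps) is packaged for protocol validation and arithmetic checks; it is
not run by the test suite.

## Jarzynski estimation and bias correction

The raw estimator ΔF_JE(λ) = −k_B T·ln[(1/N)Σᵢ e^(−Wᵢ(λ)/k_B T)] is
evaluated with log-sum-exp, so works of thousands of k_B T neither overflow
nor underflow. It is positively biased at finite N (Jensen: the rare
low-work tail is under-sampled).

The correction backend adopts the near-equilibrium work model — Gaussian
work with the fluctuation–dissipation variance σ² = 2k_B T·W_dis — under
which the expected bias of the N-sample estimator is computed *exactly* by
deterministic quadrature: with Y = e^(−βW) lognormal and S = ΣYᵢ, the
identity ln S = ∫₀^∞ (e^(−t) − e^(−tS)) dt/t reduces E[ln S] to a
one-dimensional integral of e^(−e^u) − φ(u)^N over u = ln t, where
φ(u) = E[e^(−e^u·Y)] is a Gaussian-smoothed Gumbel CDF. The resulting
B(N, W_dis) is exact at N = 1 (bias = W_dis), matches the delta-method
asymptote k_B T(e^(2βW_dis) − 1)/2N at large N, and interpolates correctly
in between — the regime where closed-form expansions fail badly (at
W_dis = 2 k_B T, N = 30 the delta method overestimates the bias more than
threefold). Because the plug-in dissipation Ŵ_dis = W̄ − ΔF_JE is itself
reduced by the bias, Ŵ_dis is refined by a short fixed-point iteration
W_dis ← Ŵ_dis + B(N, W_dis), which converges since dB/dW_dis < 1.
Quadrature resolution (du = 0.015, kernel reach σ + 10 smoothing widths)
keeps the bias accurate to ~10⁻³ k_B T; when many distinct dissipation
values are requested the bias is interpolated from a 32-node geometric
grid in W_dis (B is smooth and monotone).

The backend is validated against a brute-force Monte-Carlo oracle
(ensembles of Gaussian works with analytically known ΔF = 0), not against
any printed constant: at W_dis = 2 k_B T, N ∈ {10, 30, 100}, correction
reduces the expected |bias| by roughly an order of magnitude.

The error band is ΔF_BC ± √MSE with MSE = variance + bias². The variance
interpolates harmonically between the single-sample variance σ² and the
delta-method large-N variance (k_B T)²(e^(2βW_dis) − 1)/N; this is
deliberately conservative in the intermediate regime (no exact quadrature
identity of comparable simplicity exists for the second moment). The band
is a ~1σ statement: a correct estimate falls outside it roughly a third of
the time, which is the expected behaviour, not a failure.

PMFs are referenced to zero at λ0 regardless of steering direction;
"forward" is the steered direction. Barrier heights are read off the
bias-corrected curve: forward = max − value at the start, reverse =
max − value at the far end; for a monotone curve one barrier is zero.

## Transfer-event analysis

Event detection is geometric. A frame is on side +1/−1 of a transfer
coordinate when it lies beyond ±hysteresis (default 0.1 Å); runs of equal
nonzero side shorter than `min_dwell_frames` (default 4) are discarded as
thermal recrossings; each surviving run of side opposite to the
established one registers one event, whose crossing time is the first
frame with the new sign after the last frame beyond the old threshold.
The defaults suppress recrossing noise at toy-system amplitudes and are
configurable — no universal thresholds exist, and real identification
work would also consult end-state atom provenance, which the classifier
mirrors geometrically by reporting each hydrogen's nearest role heavy atom
in the final frame.

Pathway classification scans three coordinates (acid→water and
acid→acceptor for the acid hydrogen, water→acceptor for the water
hydrogen). Water mediation requires both water legs to fire; a direct
transfer is an acid→acceptor event without the water pattern. A lone
acid→water crossing does not veto "direct": any hydrogen that reaches a
distant acceptor necessarily ends closer to an intervening water than to
its origin, so that coordinate fires on geometry alone. If both patterns
appear the water-mediated label is kept with an `ambiguous` flag. Two
events are "concomitant" when separated by at most one trajectory sampling
interval (default 2.5 ps in the full-scale preset) — the finest statement
the sampling resolution supports.

Heavy-atom departure ("oxygen transfer") analyses reuse the same
machinery with the departing heavy atom in the hydrogen slot; no separate
operator exists.

## What the toy systems do not show

The Langevin engine generates statistically faithful work ensembles, but
it is not a molecular force field: there are no electronic-structure
energies, no solvent, no multidimensional orthogonal relaxation, and the
work distributions are close to Gaussian by construction. Passing tests
therefore establish the correctness of the estimators, restraint algebra
and event logic — not that a particular chemical barrier height is right,
and not that the near-equilibrium bias model is accurate for strongly
non-Gaussian work distributions (for such data the correction degrades
gracefully toward undercorrection, since the bias estimate is capped at
Ŵ_dis). Production-scale barrier heights for the enzyme chemistry that
motivated this pipeline require a QM/MM engine and are out of scope.

## Degenerate inputs and tie-breaks

Null steering (λ0 = λ1) is valid, flagged, and yields identically zero
work. N = 1 ensembles admit a raw estimate (ΔF_JE = W) but no bias
correction. The barrier position ties break toward the first grid maximum
(`argmax`). Duplicate replicate seeds, non-finite works, too-short
snapshot pre-runs and Jensen-violating PMF inputs are rejected with named
errors rather than propagated.
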