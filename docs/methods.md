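# Methods

## Model

Four metabolic elements are represented as populations of Kuramoto phase
oscillators: glycolysis (GO, N oscillators), OXPHOS (MO, M oscillators),
and their supplies, glucose (G, one driver per glycolysis oscillator) and
oxygen (O, one per OXPHOS oscillator).  The governing phase velocities are

    θ̇_Gi  = ω_Gi(t)
    θ̇_Oi  = ω_Oi(t)
    θ̇_GOi = ω_GOi(t) + (K_GO/N) Σ_j W_ij sin(θ_GOj − θ_GOi)
            − ε_G sin(θ_GOi − θ_Gi) + F_GO r_MO sin(Ψ_MO − θ_GOi)
    θ̇_MOi = ω_MOi(t) + (K_MO/M) Σ_j W_ij sin(θ_MOj − θ_MOi)
            − ε_O sin(θ_MOi − θ_Oi) ± F_MO r_GO sin(Ψ_GO − θ_MOi)

Working in phase only keeps the model thermodynamically open (no mass
balance is imposed) and non-autonomous frequency modulation replaces the
noise term of the ancestral two-oscillator model:

    ω_Xi(t) = ω_X + A_X sin(ω_Xm (t + t_i)),  t_i ~ U[0, 1/ω_Xm].

Phases are integrated and stored unwrapped, so differences over time are
meaningful for boundedness tests.

### Ring weighting

Oscillators of one network are indexed around a ring;
`d(i,j) = min(|i−j|, N−|i−j|)` is the ring distance (this closed form
equals the two-branch near/wrapped definition for even ring sizes and is
its symmetric completion for odd ones).  The default kernel is
*harmonic decay*, `W_ij = W/d` with `W = 1` and `W_ii = 0` — coupling
falls off with distance, as diffusive molecular exchange suggests.  Three
alternative readings of the weighting expression are selectable:
`uniform` (the unweighted all-to-all network), `power_decay` (`W^d`) and
`linear_growth` (`W·d`).  Only relative weights matter, since the network
term is scaled by `K_X`.

### Three deliberate conventions

The model definition leaves three choices open that the implementation
had to fix.  All three defaults were selected because the alternative
measurably destroys the model's characteristic regime structure; each is
reversible by one config flag.

1. **Modulation offsets are time shifts** (`offset_mode="time_shift"`):
   `t_i ~ U[0, 1/ω_m]` enters as `sin(ω_m(t + t_i))`, so a population
   spans under 1 rad of modulation phase — frequencies are distributed,
   but the element stays nearly modulation-synchronous.  Reading the same
   `t_i` as a bare phase addend (`offset_mode="time"`) makes the addend
   range ≈ 318 rad ≈ 50 modulation cycles, i.e. effectively uniform
   modulation phases; the resulting ±A frequency spread between an
   oscillator and its driver caps driver-pair coherence near |J₀(1)| ≈
   0.77, below the 0.9 threshold, and no driver-entrainment regime can
   exist at the standard couplings.  A full-cycle `U[0, 2π)` mode
   (`"phase"`) is also available.
2. **Both mean-field terms are attractive** (`mo_go_attractive=True`).
   With the repulsive sign on the MO←GO term, OXPHOS flees the glycolysis
   mean field while glycolysis chases OXPHOS; measured at desk scale the
   chase disorders both networks as F grows (r ≈ 0.04 at F = 0.27)
   instead of producing the mutual-synchronization regime that dominates
   the coupling plane.
3. **Drivers start at a common zero phase** (`random_driver_phases=False`).
   Drivers are pure rotators and never feel a coupling, so their ensemble
   keeps whatever coherence it starts with.  Randomizing them freezes a
   quenched random pinning field (each network oscillator is pulled
   toward its own driver's arbitrary phase), which keeps both networks
   disordered at low inter-network coupling.  Network oscillators always
   start uniform on [0, 2π).

## Numerics

* **Adaptive scheme** (default): LSODA via `scipy.integrate.solve_ivp`,
  error-controlled and stiffness-capable, with output evaluated exactly
  on the sampling grid; `rel_tol = 1e-7`, `abs_tol = 1e-9`.  The contract
  is the tolerance, not the particular scheme.
* **Fixed-step scheme**: classical four-stage Runge-Kutta, default step
  0.01 s (oscillation periods in the HeLa scenario are ~3–7 s, so ≥ 300
  steps per period), sampling every 0.1 s.  Additive white frequency
  noise (σ > 0) is only available here, applied as an Euler–Maruyama
  increment `σ√h·ξ` after each deterministic step.
* The standard protocol integrates 10,000 s, samples at 0.1 s intervals
  ("sampling frequency of 0.1 s" is read as a 10 Hz grid — a 0.1 Hz grid
  would leave ~10 samples per oscillation) and discards the first
  5,000 s as transient.
* Offsets and initial phases derive from `ModelConfig.seed`; noise
  increments from `SimulationSpec.seed`; both are recorded with every
  `PhaseSeries`.
* Schedule segments are half-open `[t_start, t_end)` with the final
  segment closed on the right; printed breakpoint pairs like
  355.9 s / 356 s become one breakpoint at the next integer second.
  Negative schedule evaluations clamp to zero (couplings are
  non-negative); the HeLa ramp is constructed to reach ~−6e−5 at its
  hand-off, so clamping introduces no visible jump.

## Synchronization classification

Over the analysis window:

* **Pair coherence**: `|⟨e^{iΔθ}⟩_t|`.  Frequency modulation keeps even
  locked non-autonomous pairs below 1, hence the operating threshold 0.9.
* **Boundedness**: `max Δθ − min Δθ < 2π`.  Coherent but unbounded pairs
  are *intermittently* synchronized — episodic 2π slips with no parameter
  change, a finite-time phenomenon invisible to asymptotic averaging.
* **Networks**: synchronized when the time-averaged order parameter
  exceeds 0.5; *permanent* when `max r − min r < 0.2` ("varied by less
  than 0.2" is read as the range of the r series), else *intermittent*.
* Six modes are reported: GO–G, GO network, GO→MO mean field, MO→GO mean
  field, MO network, MO–O.  Driver and mean-field modes are evaluated per
  oscillator and aggregated by majority vote, ties broken toward the
  weaker label (none < intermittent < permanent); the per-mean-phase
  alternative is available through the library functions.  The mean-field
  phase Ψ is unwrapped over time before differencing; samples with
  r < 1e-6 carry the previous Ψ (the argument is undefined at r = 0).
* Mode combinations are mapped to the nine-colour taxonomy of the
  network-model regimes; combinations outside it are reported as
  `"unlisted"`, never forced into a listed colour.
* The classifier warns when the window covers fewer than ten periods of
  the slowest mean oscillation (the warning is keyed to the oscillation
  period, not the much slower modulation period, which the standard
  window covers only 2.5 times).

## Regime sweep

The (F_GO, F_MO) plane is covered by a 50-value arithmetic grid per axis,
step 0.006, anchored at zero (so the maximum is 0.294; zero must be on
the grid because the zero-coupling corners carry biological meaning,
and 51 values would overshoot the 2,500-cell total).  Each cell runs an
independent simulation seeded `base_seed + cell_index`, so maps are
reproducible and independent of worker count.  Per-cell solver failures
are recorded and skipped, not fatal.

The packaged `desk` preset — N = M = 20, 3,000 s runs with 1,500 s
transient, 10 × 10 grid with step 0.03 — is the scaled-down configuration
used by the verification suite; it preserves the structure of the
full-scale map (driver/network synchronization without inter-network
modes at the zero corner, mutual network synchronization at large F, and
no cell with both networks disordered) at roughly 1/400 of the cost.  The
full-scale standard sweep ships as the long-running `table2` preset.

## HeLa scenario

N = M = 100; mean periods 20/3 s (glycolysis, glucose) and 10/3 s
(OXPHOS, oxygen); modulation frequencies 3π/100 rad/s (0.015 Hz, chosen
inside the 0.01–0.02 Hz band extracted from measured NADH fluorescence)
and 3π/50 rad/s; modulation amplitudes one third of the mean frequency.
The couplings follow piecewise-quadratic schedules with
A = 9.511e-7, B = 1.931e-3 (a quadratic fit to the measured envelope):
ε_G ramps `−At² + Bt + 0.025` until 356 s then plateaus at 0.7;
F_GO = F_MO ramp `At² − Bt + 0.6` until they cross zero at 383 s, zero
afterwards; all other couplings stay at 0.025.  Integration is
fixed-step RK4 over the full 800 s with no transient discard — the
initial coherence spike is part of the phenomenon.  The output is the
two-network order parameter

    s(t) = |Σ_i e^{iθ_GOi} + Σ_j e^{iθ_MOj}| / (N + M),

a proxy for single-cell NADH fluorescence (NADH production peaks when
both branches act coherently).  The curve depends on the randomized
initial phases and is therefore reported seed-averaged where a statistic
is needed.  During the strong-coupling segment the faster OXPHOS
modulation (0.03 Hz) contributes most of the ripple; over the full curve,
and especially in the declining phase after the ramps reach zero, the
glycolysis modulation at 0.015 Hz dominates the spectrum.

## Synthetic fixtures

The fixture generators produce series whose verdict is known by
construction: locked pairs (constant difference plus clipped bounded
jitter — clipping, not noise integration, so boundedness is guaranteed),
slipping pairs (2π steps inserted into a locked difference; a 2π step
leaves the coherence phasor untouched), drifting pairs (constant detuning
over ≥ 10 cycles), and ordered / redrawn-uniform / alternating-spread
networks exploiting `r ≈ exp(−σ_c²/2)` for wrapped-normal spread σ_c.
Every fixture re-verifies its own label with the same brute-force
statistics the classifier uses and retries a bounded number of times if
a draw lands outside its class.  These fixtures exercise the statistics
and thresholds, not the model: passing them shows the classifier applies
its definitions correctly, not that real metabolic data would be
classified correctly.

## Problem sizes in the verification suite

The packaged test suite and the reproduction script use the desk-scale
sweep (10 × 10 × 3,000 s, N = M = 20), five seeds of the full-size HeLa
scenario, 50 seeds per fixture kind, and RHS-oracle instances up to
N = M = 5 — sizes chosen so the whole suite completes in minutes on one
CPU while still exercising every code path of the full-scale presets.

## Known limitations

* No amplitude dynamics, metabolite concentrations or mass-action
  kinetics; no spatial structure beyond the ring index; no intercellular
  coupling.
* The regime taxonomy colours only combinations that occur in the
  published classification; novel combinations are honestly `"unlisted"`.
* Intermittency is detected solely via unboundedness of an otherwise
  coherent difference; no sub-windowing or time-frequency analysis.
* The observed "islands" of off-family cells in coarse maps are
  sensitive to integrator tolerances, as expected for marginally locked
  non-autonomous dynamics.
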