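# Methods

## Model and assumptions

The simulator implements an event-driven, collapse-dominated caricature of
phage predation in a well-mixed community. Its assumptions, in order of
importance:

1. **Saturated growth.** Between collapses the community sits at the
   carrying capacity (normalised to 1) and only relative abundances change:
   `P_i(t+Δt) = P_i e^{g_i Δt} / Σ_j P_j e^{g_j Δt}`. Growth rates `g_i` are
   fixed per species; only differences matter (the normalisation removes any
   common offset).
2. **Poisson collapse clock.** Waiting times between collapse events are
   exponential with mean τ. Events are independent of the state.
3. **Kill-the-Winner victim lottery.** The victim of an event is species `i`
   with probability `P_i` evaluated after the growth step. Two collapse
   modes: multiply the victim by its ratio `γ_i ∈ (0,1)` (`factor`) or reset
   it to the level γ (`threshold`). After a collapse the total is transiently
   below 1; the next growth step restores it exactly, which implements the
   "regrow to carrying capacity" narrative without any ad-hoc renormalisation.
4. **Variants.** `selection_mode="king"` always collapses the current
   largest population (deterministic for equal rates). `k_extra=K` collapses
   K additional victims per event, drawn uniformly without replacement among
   the other alive species, each with its own γ and the same mode.

No explicit phage populations, resources beyond the single shared one,
mutation, or spatial structure are modelled.

## Parameters

| name | meaning | units | default |
|---|---|---|---|
| `n_species` | community size N | – | required |
| `sigma` | growth-rate spread σ (Gaussian s.d. / exponential mean) | 1/time | 1.0 |
| `tau` | mean inter-collapse interval τ | time | 1.0 |
| `gamma` | collapse ratio(s) γ, severity is \|log γ\| | – | 1e-3 |
| `k_extra` | extra victims per event K | – | 0 |
| `n_events` | collapse budget of a run | events | 1000 |
| `extinction_floor` | bookkeeping cutoff for the `alive` flag | rel. abundance | 1e-300 |
| `survival_cutoff` | diversity-count threshold | rel. abundance | min(γ)·1e-3 |

The diversity threshold default sits three decades below the lowest
post-collapse level a cycling survivor can reach: survivors never fall far
below γ, while excluded species decay exponentially without bound, so any
cutoff in that gap gives the same count once transients have passed. All
steady-state formulas use τ for the "time between collapses" parameter; the
product στ is the selection strength per collapse interval.

## Steady-state theory

A survivor's excess growth `(g_i − g_cc)τ` per event must balance its
expected log-loss `c_i |log γ_i|`, with one collapse per event in total:

    c_i = max(g_i − g_cc, 0) · τ / |log γ_i|,   Σ_i c_i = 1.

`solve_gcc_empirical` solves this exactly for a realised rate vector by
scanning the sorted rates (the left side is piecewise linear and strictly
decreasing in `g_cc`, so the root lies in exactly one bracket); heterogeneous
γ_i enter as per-species weights `1/|log γ_i|`. Cycle periods are
`T_i = 1/c_i` events. Averaging over the rate distribution gives
`D = |log γ|/(στ)` for exponential rates, and for Gaussian rates the
condition `N στ [φ(z) − z Q(z)] = |log γ|` with `z = g_cc/σ`, solved by
bracketed Brent iteration on `z ∈ [−12, 12]` to 1e-10 (`φ`: standard normal
density, `Q`: upper-tail probability); `D = N·Q(z)`, clipped to `[1, N]`.
When no bracket exists the appropriate cap (N or 1) is returned with a
warning. With heterogeneous collapse ratios the scalar laws use the mean
|log γ_i|.

**Heterogeneous severities.** Replacing |log γ_i| by its arithmetic mean in
the scalar laws is a leading-order convenience: the exact balance weighs
species by 1/|log γ_i|, i.e. a harmonic mean, and for γ log-uniform over
[10⁻⁸, 10⁻⁴] the two differ by ~3% in D. `solve_gcc_empirical` accepts the
per-species vector and is exact; the test suite checks both forms at their
respective precisions.

**K extra victims.** With K uniform extra victims per event, every species
absorbs an additional mean loss of |log γ|·K/N per event. This is invisible
when survivors' excess growth per event (~|log γ|/D) dwarfs it — i.e. under
strong selection — but truncates the survivor band under weak selection:
at N = 500, γ = 10⁻⁶, even K = 1 lowers the measured diversity by ~30% at
σΔt = 0.05 while leaving the σΔt ≥ 2.5 points statistically unchanged.
K = 25 lowers diversity across the grid. When extinctions shrink the alive
pool below K+1 late in a strongly selected run, the simulator collapses all
remaining other species instead of aborting.

These expectation forms omit an O(1) correction: one fastest grower always
survives regardless of the balance. For exponential rates the correction is
exactly +1 (the survivor count is a renewal count of unit-mean spacings,
`E[D] = |log γ|/(στ) + 1`); the test suite verifies both the bare law and
this correction against brute-force averages of the exact per-realisation
solver. At the simulation scales used (D ≳ 8) the correction is within
Monte-Carlo scatter of full runs.

## Estimators

`empirical_stats` discards the first third of events as burn-in (extinction
transients dominate early dynamics) and then counts primary-victim
frequencies and mean inter-collapse gaps. Time-averaged abundances are plain
means over the post-growth snapshots: because the collapse clock is Poisson,
event epochs sample time uniformly, making the unweighted event average the
consistent estimator of the continuous time average. Weighting snapshots by
the preceding interval would bias fast growers upward (their abundance at an
epoch correlates with the interval length); this bias is large in practice
(~0.14 absolute on a species with c ≈ 0.4).

`ktw_identity_check` tests ⟨P_i⟩ = c_i using the per-event residual
`P_i(t_event) − 1{victim = i}`, which is a martingale difference under the
model: exactly mean zero with uncorrelated increments, so its standard error
is `std/√M` with no autocorrelation correction.

## Rank-ratio dynamics

Sorting abundances descending and forming `δ_i = P_(i+1)/P_(i)` turns the
equal-rate Kill-the-King dynamics into a deterministic relaxation problem.
`ktk_round` applies one full round of N king-collapses (growth between
equal-rate collapses is a pure renormalisation, so waiting times drop out);
it preserves the abundance ranking exactly and each species collapses once
per round.

**Fixed point.** The equal-ratio steady state is `δ* = γ^{1/N}` to leading
order. The exact round map settles slightly above it: the collapsed king
holds a finite share `≈ 1 − δ*` of the total, and the renormalisation this
forces shifts the self-consistent equal ratio to the root of
`δ^N (1−δ) ≈ γ (1−δ^N)` — e.g. 0.2588 vs `δ* = 0.2512` for N = 10,
γ = 10⁻⁶ (+3.0%), shrinking as δ* → 0 (+0.33% at N = 3, γ = 10⁻⁶). The
package reports the analytic δ* (`steady_state_ratio`) and treats the round
map itself as ground truth; convergence measures use a 15% relative
tolerance on δ*, far above the finite-N offset.

**Relaxation regimes.** Far from the steady state the largest ratio decays
like `1/(t/N)` (t in collapse events); near it the deviation decays
exponentially at rate δ* per *round* (per N events) — the natural clock of
the round map. Both laws are asymptotic and need the scale separation
`N² ≪ t ≪ N/δ*`, i.e. small δ*: they are exhibited cleanly at N = 3,
γ = 10⁻⁶ (δ* = 0.01). At N = 10, γ = 10⁻⁶ (δ* = 0.25) the window is empty
(N² = 100 > N/δ* = 40): honest fits there give an early slope around −0.2
to −0.6 and a late per-event rate of ≈ 0.04 δ* (the map's slowest
eigenmode), and the corresponding acceptance-style checks pinned to those
parameters fail by construction. `relaxation_profile` therefore reports its
fit windows explicitly; the early fit runs where `max δ > 2δ*` (and below
0.98 to skip the initial plateau), the late fit where the deviation from the
empirical plateau lies in `[0.1, 1]·δ*`, each needing ≥ 10 samples. The
late-fit asymptote defaults to the series' final value, which absorbs the
finite-N offset of the true fixed point.

The analytic relaxation scale — events to travel from δ ~ 1 to δ ~ δ* — is
`N/δ*`, i.e. 300 for N = 3, γ = 10⁻⁶.

## Numerical choices

- **Log-space state.** Abundances are stored as natural logs and
  renormalised with a max-shifted log-sum-exp: doomed species decay to
  relative abundances far below double-precision underflow, and log space
  keeps their dynamics exact over thousands of events. A linear-space
  re-implementation agrees to 1e-8 on small communities and short budgets
  (oracle test).
- **Victim selection** is inverse-CDF on the cumulative abundance vector;
  a state whose total deviates from 1 by more than 1e-8 is rejected
  (selection must follow a growth step). Species below the extinction floor
  are excluded from the lottery (their probability is numerically 0 anyway)
  and from extra-victim draws; they stay in the state for bookkeeping.
- **Ties** in Kill-the-King break to the lowest index. Threshold collapses
  of a species already below γ raise it to γ (the restart level is
  history-independent, e.g. recolonisation by a fixed inoculum).
- **Determinism.** One `numpy.random.Generator` per run, seeded from the
  config; identical configs reproduce event logs byte-for-byte. Rates are
  drawn with scale σ even at σ = 0 so runs are continuous in σ at fixed
  seed.
- **Initial condition** defaults to equal shares 1/N; ratio-relaxation
  experiments use a symmetric Dirichlet(1) random start.

## What the experiments emulate — and what they do not

Simulated communities have fixed, independently drawn growth rates, a
state-independent Poisson collapse clock, and exactly one (plus optionally K
random) victims per event. Real communities have correlated traits, bursty
and density-dependent phage epidemics, structured infection networks,
invasions and evolution. Passing tests therefore show that the simulator and
its theory are mutually consistent under the stated assumptions — e.g. that
measured diversity follows the σΔt law, or that ⟨P_i⟩ = c_i — not that
those laws hold in any particular natural ecosystem.

Problem sizes in the test suite are chosen to keep the full run modest while
leaving Monte-Carlo error well below the effects under test: the diversity
law uses N = 500 with 2×10⁴ events and 10 seeds per grid point; the identity
and period checks one 5×10⁴-event run of N = 20; variant comparisons reuse
the diversity grid. With 2×10⁴ events, species within ≈ 10⁻³σ of the
threshold have not finished dying out, a small upward bias on measured D
that is visible only at the weakest selection strengths and stays within the
quoted scatter.

## Known limitations

- The continuum (Burgers-type) description of the ratio field is not solved
  numerically; only its asymptotic relaxation predictions are checked
  against the round map.
- Fat-tailed growth-rate distributions, explicit phage dynamics,
  multi-resource competition and pre-saturation collapses are out of scope.
- `predict_diversity_*` return expectations for an ensemble of rate draws;
  for a single realised community use `solve_gcc_empirical` on its actual
  rates.
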