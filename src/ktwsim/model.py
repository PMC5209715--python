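"""The stochastic Kill-the-Winner simulator.

One update cycle: draw an exponential waiting time, let relative abundances
change exponentially while the total stays saturated at the carrying
capacity, pick a victim with probability equal to its relative abundance
(or deterministically the largest, in Kill-the-King mode), and collapse it —
multiplying it by its collapse ratio gamma, or resetting it to the fixed
threshold gamma, depending on the collapse mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ConfigError, SimulationParams
from .rates import generate_growth_rates
from .state import CollapseEvent, CommunityState, EventLog, Snapshots, LN10

_NORM_TOL = 1e-8


def draw_interval(rng: np.random.Generator, tau: float) -> float:
    """Waiting time until the next collapse, exponential with mean tau."""
    if not tau > 0:
        raise ConfigError(f"tau must be > 0, got {tau}")
    return float(rng.exponential(tau))


def grow(state: CommunityState, dt: float) -> CommunityState:
    """Advance relative abundances by dt of saturated exponential growth.

    log P_i  ->  log P_i + g_i dt - logsumexp_j(log P_j + g_j dt),
    which also restores the carrying-capacity normalisation after a
    preceding collapse left the total below 1.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    s = state.copy()
    la = s.log_abundance
    la += s.growth_rate * dt
    m = la.max()
    la -= m + np.log(np.exp(la - m).sum())
    s.model_time += dt
    return s


def selection_probabilities(state: CommunityState) -> np.ndarray:
    """Collapse lottery weights: relative abundances, extinct species zeroed."""
    p = np.exp(state.log_abundance)
    p[~state.alive] = 0.0
    return p / p.sum()


def select_winner(state: CommunityState, rng: np.random.Generator) -> int:
    """Draw the collapse victim with probability equal to relative abundance.

    Inverse-CDF sampling on the cumulative abundance vector; species flagged
    extinct are excluded (their probability is numerically zero anyway).
    """
    p = np.exp(state.log_abundance)
    if abs(p.sum() - 1.0) > _NORM_TOL:
        raise RuntimeError(
            "state is not normalised to the carrying capacity; "
            "collapse-victim selection must follow a growth step"
        )
    p[~state.alive] = 0.0
    cdf = np.cumsum(p)
    u = rng.random() * cdf[-1]
    return int(min(np.searchsorted(cdf, u, side="right"), state.n_species - 1))


def apply_collapse_factor(
    state: CommunityState, i: int, gamma_i: float
) -> CommunityState:
    """Multiply species i's population by gamma_i (constant-factor collapse)."""
    if not 0 < gamma_i < 1:
        raise ConfigError(f"gamma must lie strictly in (0, 1), got {gamma_i}")
    s = state.copy()
    s.log_abundance[i] += np.log(gamma_i)
    return s


def apply_collapse_threshold(
    state: CommunityState, i: int, gamma: float
) -> CommunityState:
    """Reset species i to the fixed threshold gamma, whatever its prior size.

    A victim already below gamma is raised up to it: the restart level is
    independent of history (e.g. recolonisation by a fixed-size inoculum).
    """
    if not 0 < gamma < 1:
        raise ConfigError(f"gamma must lie strictly in (0, 1), got {gamma}")
    s = state.copy()
    s.log_abundance[i] = np.log(gamma)
    return s


def _collapse_inplace(state: CommunityState, victims: list[int], mode: str) -> None:
    for j in victims:
        gj = state.collapse_ratio[j]
        if mode == "factor":
            state.log_abundance[j] += np.log(gj)
        else:
            state.log_abundance[j] = np.log(gj)


def _select_victims(
    state: CommunityState, params: SimulationParams, rng: np.random.Generator
) -> tuple[int, list[int]]:
    # local import: variants builds on this module
    from .variants import select_extra_victims, select_king

    if params.selection_mode == "king":
        primary = select_king(state)
    else:
        primary = select_winner(state, rng)
    extras: list[int] = []
    if params.k_extra:
        # late in a run extinctions can shrink the pool below K other alive
        # species; collapse all that remain rather than aborting the run
        available = int(state.alive.sum()) - 1
        k = min(params.k_extra, max(available, 0))
        if k:
            extras = select_extra_victims(state, primary, k, rng)
    return primary, extras


def step(
    state: CommunityState,
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[CommunityState, CollapseEvent]:
    """One full update: wait, grow to the collapse time, pick victims, collapse.

    The returned state is left unnormalised by the collapse on purpose; the
    next growth step restores the total to the carrying capacity exactly.
    """
    s, ev, _ = _step_full(state, params, rng)
    return s, ev


def _step_full(
    state: CommunityState,
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[CommunityState, CollapseEvent, np.ndarray]:
    dt = draw_interval(rng, params.tau)
    s = grow(state, dt)
    la_pre_collapse = s.log_abundance.copy()
    primary, extras = _select_victims(s, params, rng)
    victims = [primary, *extras]
    before = [float(s.log_abundance[j]) for j in victims]
    _collapse_inplace(s, victims, params.collapse_mode)
    after = [float(s.log_abundance[j]) for j in victims]
    s.event_count += 1
    ev = CollapseEvent(
        event_index=s.event_count - 1,
        model_time=s.model_time,
        dt=dt,
        species_id=primary,
        extra_victims=extras,
        log_abundance_before=before,
        log_abundance_after=after,
    )
    return s, ev, la_pre_collapse


def initial_state(
    params: SimulationParams, rng: np.random.Generator
) -> CommunityState:
    """Build the configured starting community (rates first, then abundances)."""
    g = generate_growth_rates(
        params.n_species,
        params.sigma,
        params.rate_distribution,
        rng,
        params.growth_rates,
    )
    if params.initial_condition == "dirichlet":
        p = rng.dirichlet(np.ones(params.n_species))
        la = np.log(p)
    else:
        la = np.full(params.n_species, -np.log(params.n_species))
    return CommunityState(
        log_abundance=la,
        growth_rate=g,
        collapse_ratio=params.gamma_vector(),
        extinction_floor=params.extinction_floor,
    )


@dataclass
class SimulationResult:
    """Final state, full event log and abundance snapshots of one run."""

    params: SimulationParams
    state: CommunityState
    event_log: EventLog
    snapshots: Snapshots | None

    def __iter__(self):  # allow  state, log, snaps = simulate(...)
        return iter((self.state, self.event_log, self.snapshots))

    def diversity(self, survival_cutoff: float | None = None) -> int:
        cutoff = (
            self.params.effective_survival_cutoff()
            if survival_cutoff is None
            else survival_cutoff
        )
        return surviving_diversity(self.state, cutoff)


def simulate(params: SimulationParams) -> SimulationResult:
    """Run ``params.n_events`` collapse events from the configured start.

    Snapshots are taken post-growth, pre-collapse at every
    ``params.snapshot_thin``-th event (0 disables them); each carries the
    preceding waiting time dt so time averages can be dt-weighted.
    """
    rng = np.random.default_rng(params.seed)
    state = initial_state(params, rng)
    log = EventLog(params.to_dict())

    thin = params.snapshot_thin
    snap_idx: list[int] = []
    snap_time: list[float] = []
    snap_dt: list[float] = []
    snap_la: list[np.ndarray] = []

    for k in range(params.n_events):
        state, ev, la_pre = _step_full(state, params, rng)
        log.append(ev)
        if thin and k % thin == 0:
            snap_idx.append(k)
            snap_time.append(state.model_time)
            snap_dt.append(ev.dt)
            snap_la.append(la_pre / LN10)

    snapshots = None
    if thin:
        snapshots = Snapshots(
            event_index=np.array(snap_idx, dtype=int),
            model_time=np.array(snap_time),
            dt=np.array(snap_dt),
            log10=(
                np.vstack(snap_la)
                if snap_la
                else np.empty((0, params.n_species))
            ),
            thin=thin,
        )
    return SimulationResult(params=params, state=state, event_log=log, snapshots=snapshots)


def surviving_diversity(state: CommunityState, survival_cutoff: float) -> int:
    """Count species whose relative abundance exceeds the survival cutoff."""
    if survival_cutoff >= 1:
        raise ConfigError("survival_cutoff must be < 1")
    return int(np.sum(state.log_abundance > np.log(survival_cutoff)))
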