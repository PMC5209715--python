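"""Rank-ordered abundance ratios and their relaxation dynamics.

Sorting the community by decreasing abundance and forming the ratios
delta_i = P_(i+1)/P_(i) of successive populations turns the Kill-the-King
(and fixed-threshold Kill-the-Winner) dynamics into a relaxation problem:
the ratios flow toward the equal-spacing steady state delta* = gamma^(1/N),
where the log abundances sit equidistantly on a ladder of depth |log gamma|.
Far from the steady state the largest ratio decays like 1/(t/N) in collapse
events; close to it the decay crosses over to exp(-delta* t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ConfigError
from .state import CommunityState, Snapshots


@dataclass
class RatioSeries:
    """Rank-ratio vectors sampled along a run.

    ``delta[k]`` holds the ratios at sample k (columns: rank pairs, largest
    first), ``events[k]`` the collapse-event count at which it was taken,
    and ``round_index[k]`` the completed full rounds (events // N).
    """

    events: np.ndarray  # (n_samples,)
    delta: np.ndarray  # (n_samples, n_ratios)
    n_species: int

    @property
    def round_index(self) -> np.ndarray:
        return self.events // self.n_species

    def __len__(self) -> int:
        return self.events.size


def rank_ratios(
    state: CommunityState, wrap_gamma: float | None = None
) -> np.ndarray:
    """Ratios of successive rank-ordered abundances, largest pair first.

    Returns the N-1 plain ratios P_(i+1)/P_(i) in (0, 1].  With
    ``wrap_gamma`` given, a wrap-around N-th ratio is appended: the current
    smallest population's ratio read after its next collapse, when the freshly
    collapsed king sits at the threshold gamma below it — i.e. gamma/P_(N).
    """
    if state.n_species < 2:
        raise ConfigError("rank ratios need at least two species")
    la = np.sort(state.log_abundance)[::-1]
    la = la - la[0] - np.log(np.exp(la - la[0]).sum())  # normalise
    delta = np.exp(np.diff(la))
    if wrap_gamma is not None:
        delta = np.append(delta, wrap_gamma * np.exp(-la[-1]))
    return delta


def steady_state_ratio(gamma: float, n_species: int) -> float:
    """Equal-spacing steady-state ratio delta* = gamma^(1/N)."""
    if not 0 < gamma < 1 or n_species < 1:
        raise ConfigError("require 0 < gamma < 1 and N >= 1")
    return float(gamma ** (1.0 / n_species))


def ktk_ratio_series(
    state: CommunityState,
    gamma: float,
    n_events: int,
    sample_every: int = 1,
) -> RatioSeries:
    """Deterministic Kill-the-King relaxation, sampling rank ratios as it runs.

    Applies king collapses to the fixed threshold gamma (equal growth rates;
    regrowth between collapses is a common renormalisation) for ``n_events``
    collapses, recording the plain rank-ratio vector every ``sample_every``
    collapses.  Sample 0 is the initial state.
    """
    g = state.growth_rate
    if not np.allclose(g, g[0], rtol=0, atol=1e-12):
        raise ConfigError("KtK ratio relaxation requires equal growth rates")
    la = state.log_abundance.copy()
    log_gamma = np.log(gamma)
    events, deltas = [0], [_ratios_from_log(la)]
    for t in range(1, n_events + 1):
        m = la.max()
        la -= m + np.log(np.exp(la - m).sum())
        la[np.argmax(la)] = log_gamma
        if t % sample_every == 0:
            events.append(t)
            deltas.append(_ratios_from_log(la))
    return RatioSeries(
        events=np.array(events, dtype=int),
        delta=np.vstack(deltas),
        n_species=state.n_species,
    )


def _ratios_from_log(la: np.ndarray) -> np.ndarray:
    s = np.sort(la)[::-1]
    return np.exp(np.diff(s))


def convergence_time(
    series: RatioSeries,
    gamma: float,
    n_species: int,
    tol: float = 0.15,
) -> int:
    """First event count at which all ratios are within tol of delta*.

    Convergence means max_i |delta_i - delta*| / delta* < tol.  Returns the
    sentinel ``series.events[-1] + 1`` if the tolerance is never reached
    within the sampled budget.
    """
    if not tol > 0:
        raise ConfigError(f"tol must be > 0, got {tol}")
    dstar = steady_state_ratio(gamma, n_species)
    dev = np.max(np.abs(series.delta - dstar), axis=1) / dstar
    hit = np.flatnonzero(dev < tol)
    if hit.size == 0:
        return int(series.events[-1] + 1)
    return int(series.events[hit[0]])


@dataclass
class RelaxationProfile:
    """Fitted diagnostics of the two relaxation regimes of max_i delta_i(t).

    ``early_slope``: log-log slope of delta vs collapse events while delta is
    well above delta* (the 1/(t/N) law predicts -1).  ``late_rate``: decay
    rate per collapse event of the deviation from the plateau (the
    exp(-delta* t) law predicts delta*).  Windows record the event spans
    used; a regime with fewer than ``min_points`` samples is reported None.
    """

    early_slope: float | None
    early_window: tuple[int, int] | None
    late_rate: float | None
    late_window: tuple[int, int] | None


def relaxation_profile(
    series: RatioSeries,
    gamma: float,
    n_species: int,
    early_band: tuple[float, float] = (2.0, 0.98),
    late_band: tuple[float, float] = (0.1, 1.0),
    asymptote: float | None = None,
    min_points: int = 10,
) -> RelaxationProfile:
    """Fit the early power-law and late exponential relaxation regimes.

    The scalar trajectory is d(t) = max_i delta_i(t).  The early fit runs
    where d exceeds ``early_band[0]`` times delta* but is below
    ``early_band[1]`` (so the initial plateau near 1 and the region near the
    steady state are both excluded).  The late fit runs where the deviation
    d - asymptote lies within ``late_band`` times delta*; the asymptote
    defaults to the final sampled value (the empirical plateau), which
    absorbs the finite-N offset of the true fixed point from gamma^(1/N).
    """
    dstar = steady_state_ratio(gamma, n_species)
    d = series.delta.max(axis=1)
    t = series.events.astype(float)

    early_slope = early_window = None
    mask = (d > early_band[0] * dstar) & (d < early_band[1]) & (t > 0)
    if mask.sum() >= min_points:
        slope = np.polyfit(np.log(t[mask]), np.log(d[mask]), 1)[0]
        early_slope = float(slope)
        early_window = (int(t[mask].min()), int(t[mask].max()))

    a = float(d[-1]) if asymptote is None else float(asymptote)
    dev = d - a
    late_rate = late_window = None
    mask = (dev > late_band[0] * dstar) & (dev < late_band[1] * dstar)
    if mask.sum() >= min_points:
        rate = -np.polyfit(t[mask], np.log(dev[mask]), 1)[0]
        late_rate = float(rate)
        late_window = (int(t[mask].min()), int(t[mask].max()))

    return RelaxationProfile(early_slope, early_window, late_rate, late_window)


def detect_reorderings(snapshots: Snapshots) -> np.ndarray:
    """Event indices where the descending-abundance permutation changes.

    Compares the rank permutation of each snapshot with the previous one; a
    deterministic Kill-the-King round sequence sampled per round never
    reorders, while fixed-threshold Kill-the-Winner runs show clustered
    bursts of reorderings when a small population collapses out of turn.
    """
    order = np.argsort(-snapshots.log10, axis=1, kind="stable")
    changed = np.any(order[1:] != order[:-1], axis=1)
    return snapshots.event_index[1:][changed]
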