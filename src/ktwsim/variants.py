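"""Variants of the collapse rule.

Kill-the-King (KtK): the deterministic extreme of Kill-the-Winner in which
the largest population always collapses next.  With equal growth rates and
fixed-threshold collapses its dynamics is a deterministic map, exposed here
as :func:`ktk_round` (one full round of N collapses, each species once).

K-extra-victims: each phage event additionally collapses K other species
drawn uniformly among the alive ones, emulating a more interconnected
phage-bacterial infection network.
"""

from __future__ import annotations

import numpy as np

from .params import ConfigError
from .state import CommunityState


def select_king(state: CommunityState) -> int:
    """Index of the largest population; ties broken by lowest index."""
    return int(np.argmax(state.log_abundance))


def ktk_round(state: CommunityState, gamma: float) -> CommunityState:
    """One deterministic Kill-the-King round: N threshold collapses of the king.

    Defined for equal growth rates only — growth between collapses is then a
    pure renormalisation (a common factor restoring the total to the carrying
    capacity), so the waiting times drop out and the round is an exact
    deterministic map on abundances.  Each species collapses exactly once per
    round and the abundance ranking is preserved.
    """
    g = state.growth_rate
    if not np.allclose(g, g[0], rtol=0, atol=1e-12):
        raise ConfigError("the deterministic KtK round requires equal growth rates")
    if not 0 < gamma < 1:
        raise ConfigError(f"gamma must lie strictly in (0, 1), got {gamma}")
    s = state.copy()
    la = s.log_abundance
    log_gamma = np.log(gamma)
    n = la.size
    for _ in range(n):
        # regrow to carrying capacity (equal rates: common rescale), then
        # collapse the king to the fixed threshold
        m = la.max()
        la -= m + np.log(np.exp(la - m).sum())
        la[np.argmax(la)] = log_gamma
        s.event_count += 1
    # leave the state normalised so rank ratios can be read off directly
    m = la.max()
    la -= m + np.log(np.exp(la - m).sum())
    return s


def select_extra_victims(
    state: CommunityState,
    primary: int,
    k: int,
    rng: np.random.Generator,
) -> list[int]:
    """K distinct extra victims, uniform without replacement among alive species.

    The primary victim is excluded; extras collapse with their own gamma in
    the same event.  K=0 reduces to the base model (no RNG draw consumed).
    """
    if k == 0:
        return []
    alive = np.flatnonzero(state.alive)
    candidates = alive[alive != primary]
    if k > candidates.size:
        raise ConfigError(
            f"k_extra={k} exceeds the {candidates.size} other alive species"
        )
    return sorted(int(j) for j in rng.choice(candidates, size=k, replace=False))
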