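"""Independent straightforward re-implementation used as a simulation oracle.

Plain linear-space abundance arithmetic, no log-space tricks: adequate for
small communities and short event budgets with mild collapse ratios, where
nothing underflows.  Deliberately mirrors the model definition step by step
so it can be compared against the packaged simulator on the same seed.
"""

from __future__ import annotations

import numpy as np


def simulate_linear(
    n_species: int,
    sigma: float,
    tau: float,
    gamma: float,
    n_events: int,
    seed: int,
    collapse_mode: str = "factor",
) -> tuple[np.ndarray, list[int], list[float]]:
    """Run the collapse-driven dynamics in direct abundance space.

    Returns the final abundances, the victim list and the drawn intervals.
    Matches the packaged simulator's RNG consumption order: rates first,
    then per event one exponential and one uniform draw.
    """
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, sigma, size=n_species)
    P = np.full(n_species, 1.0 / n_species)
    victims: list[int] = []
    dts: list[float] = []
    for _ in range(n_events):
        dt = rng.exponential(tau)
        P = P * np.exp(g * dt)
        P = P / P.sum()
        u = rng.random() * np.cumsum(P)[-1]
        i = int(min(np.searchsorted(np.cumsum(P), u, side="right"), n_species - 1))
        if collapse_mode == "factor":
            P[i] = P[i] * gamma
        else:
            P[i] = gamma
        victims.append(i)
        dts.append(float(dt))
    return P / P.sum(), victims, dts
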