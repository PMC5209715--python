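"""Growth-rate generation.

Each species carries a fixed intrinsic growth rate; only rate differences
matter because the community total is renormalised to the carrying capacity,
so the distributions are centred arbitrarily (Gaussian at 0, exponential at
its natural origin).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .params import ConfigError


def generate_growth_rates(
    n_species: int,
    sigma: float,
    distribution: str = "gaussian",
    rng: np.random.Generator | None = None,
    growth_rates: Sequence[float] | None = None,
) -> np.ndarray:
    """Draw per-species growth rates.

    ``gaussian``: N(0, sigma^2).  ``exponential``: Exp with mean sigma (its
    standard deviation is also sigma, so the spread parameter has the same
    meaning in both families).  ``user_supplied``: return ``growth_rates``
    verbatim.
    """
    if sigma < 0:
        raise ConfigError(f"sigma must be >= 0, got {sigma}")
    if distribution == "user_supplied":
        if growth_rates is None:
            raise ConfigError("user_supplied distribution requires growth_rates")
        g = np.asarray(growth_rates, dtype=float)
        if g.size != n_species:
            raise ConfigError("growth_rates length must equal n_species")
        return g.copy()
    if rng is None:
        raise ConfigError("a random generator is required for sampled rates")
    # scale 0 yields exact zeros while consuming the same stream draws, so a
    # run is continuous in sigma at fixed seed
    if distribution == "gaussian":
        return rng.normal(0.0, sigma, size=n_species)
    if distribution == "exponential":
        return rng.exponential(sigma, size=n_species)
    raise ConfigError(f"unknown rate distribution {distribution!r}")
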