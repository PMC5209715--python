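"""Run configuration for the dynamic Kill-the-Winner simulator.

A single dataclass, :class:`SimulationParams`, captures everything needed to
reproduce a run: community size and growth-rate statistics, collapse timing
and severity, model variant switches, the RNG seed and the event budget.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Sequence

import numpy as np

RATE_DISTRIBUTIONS = ("gaussian", "exponential", "user_supplied")
COLLAPSE_MODES = ("factor", "threshold")
SELECTION_MODES = ("winner", "king")
INITIAL_CONDITIONS = ("equal", "dirichlet")


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass
class SimulationParams:
    """Full configuration of one collapse-driven simulation run.

    Parameters
    ----------
    n_species:
        Number of competing species/strains N (>= 1).
    sigma:
        Spread of the growth-rate distribution (1/time, >= 0). For the
        exponential family this is both the mean and the standard deviation.
    rate_distribution:
        ``"gaussian"`` (zero mean, s.d. sigma), ``"exponential"`` (mean
        sigma) or ``"user_supplied"`` (take :attr:`growth_rates` verbatim).
    tau:
        Mean of the exponentially distributed inter-collapse interval (> 0).
    gamma:
        Collapse ratio in (0, 1): the factor a collapsing population is
        multiplied by (``collapse_mode="factor"``) or the fixed level it
        restarts from (``collapse_mode="threshold"``). Scalar or one value
        per species.
    collapse_mode:
        ``"factor"`` or ``"threshold"``.
    selection_mode:
        ``"winner"``: victim drawn with probability equal to its relative
        abundance (Kill-the-Winner). ``"king"``: the largest population
        always collapses (Kill-the-King).
    k_extra:
        Number K of additional victims collapsed alongside the primary one
        in each event, drawn uniformly among the other alive species.
    n_events:
        Total number of collapse events to simulate.
    seed:
        Seed for the single per-run ``numpy.random.Generator``.
    extinction_floor:
        Relative abundance below which a species is flagged extinct for
        bookkeeping (it stays in the state vector).
    survival_cutoff:
        Relative abundance above which a species counts as surviving when
        diversity is measured at the end of a run.  ``None`` selects the
        default ``min(gamma) * 1e-3``, three decades below the lowest level
        a cycling survivor reaches after a collapse.
    growth_rates:
        Explicit per-species rates, required iff ``rate_distribution`` is
        ``"user_supplied"``.
    initial_condition:
        ``"equal"`` starts every species at 1/N; ``"dirichlet"`` draws a
        symmetric Dirichlet(1) (i.e. uniform on the simplex) random start.
    snapshot_thin:
        Record the post-growth abundance snapshot every this many events;
        0 disables snapshots entirely.
    """

    n_species: int
    sigma: float = 1.0
    rate_distribution: str = "gaussian"
    tau: float = 1.0
    gamma: float | Sequence[float] = 1e-3
    collapse_mode: str = "factor"
    selection_mode: str = "winner"
    k_extra: int = 0
    n_events: int = 1000
    seed: int = 0
    extinction_floor: float = 1e-300
    survival_cutoff: float | None = None
    growth_rates: Sequence[float] | None = None
    initial_condition: str = "equal"
    snapshot_thin: int = 1

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if int(self.n_species) < 1:
            raise ConfigError(f"n_species must be >= 1, got {self.n_species}")
        self.n_species = int(self.n_species)
        if self.sigma < 0:
            raise ConfigError(f"sigma must be >= 0, got {self.sigma}")
        if self.rate_distribution not in RATE_DISTRIBUTIONS:
            raise ConfigError(
                f"rate_distribution must be one of {RATE_DISTRIBUTIONS}, "
                f"got {self.rate_distribution!r}"
            )
        if not self.tau > 0:
            raise ConfigError(f"tau must be > 0, got {self.tau}")
        g = self.gamma_vector()
        if np.any(g <= 0) or np.any(g >= 1):
            raise ConfigError("all collapse ratios gamma must lie strictly in (0, 1)")
        if self.collapse_mode not in COLLAPSE_MODES:
            raise ConfigError(f"collapse_mode must be one of {COLLAPSE_MODES}")
        if self.selection_mode not in SELECTION_MODES:
            raise ConfigError(f"selection_mode must be one of {SELECTION_MODES}")
        if not 0 <= self.k_extra <= self.n_species - 1:
            raise ConfigError(
                f"k_extra must satisfy 0 <= K <= N-1 = {self.n_species - 1}, "
                f"got {self.k_extra}"
            )
        if self.n_events < 0:
            raise ConfigError("n_events must be >= 0")
        if not 0 < self.extinction_floor < 1:
            raise ConfigError("extinction_floor must lie in (0, 1)")
        if self.survival_cutoff is not None and not self.survival_cutoff < 1:
            raise ConfigError("survival_cutoff must be < 1")
        if self.rate_distribution == "user_supplied":
            if self.growth_rates is None:
                raise ConfigError("user_supplied distribution requires growth_rates")
            if len(np.atleast_1d(self.growth_rates)) != self.n_species:
                raise ConfigError("growth_rates length must equal n_species")
        if self.initial_condition not in INITIAL_CONDITIONS:
            raise ConfigError(f"initial_condition must be one of {INITIAL_CONDITIONS}")
        if self.snapshot_thin < 0:
            raise ConfigError("snapshot_thin must be >= 0")

    # -- derived views ---------------------------------------------------
    def gamma_vector(self) -> np.ndarray:
        """Per-species collapse ratios, broadcast from a scalar if needed."""
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if g.size == 1:
            return np.full(self.n_species, float(g[0]))
        if g.size != self.n_species:
            raise ConfigError("gamma must be scalar or length n_species")
        return g.copy()

    def effective_survival_cutoff(self) -> float:
        if self.survival_cutoff is not None:
            return float(self.survival_cutoff)
        return float(self.gamma_vector().min() * 1e-3)

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["gamma"], np.ndarray):
            d["gamma"] = d["gamma"].tolist()
        if d["growth_rates"] is not None:
            d["growth_rates"] = list(np.asarray(d["growth_rates"], dtype=float))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    def with_(self, **kwargs) -> "SimulationParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
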