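"""Community state and per-collapse event records.

Relative abundances are stored as natural logarithms.  Doomed species keep
losing ground exponentially for thousands of events, so their relative
abundances fall far below the double-precision underflow threshold; keeping
the state in log space preserves the exact competitive dynamics regardless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

LN10 = np.log(10.0)


@dataclass
class CommunityState:
    """Log-scale relative abundances plus per-species parameters.

    ``log_abundance[i]`` is the natural log of species i's share of the
    total community, which is pinned at the carrying capacity 1 after every
    growth step (``logsumexp(log_abundance) == 0``).  Between a collapse and
    the next growth step the total is transiently below 1.
    """

    log_abundance: np.ndarray
    growth_rate: np.ndarray
    collapse_ratio: np.ndarray
    extinction_floor: float = 1e-300
    model_time: float = 0.0
    event_count: int = 0

    def __post_init__(self) -> None:
        self.log_abundance = np.asarray(self.log_abundance, dtype=float).copy()
        self.growth_rate = np.asarray(self.growth_rate, dtype=float).copy()
        self.collapse_ratio = np.asarray(self.collapse_ratio, dtype=float).copy()
        n = self.log_abundance.size
        if not (self.growth_rate.size == n and self.collapse_ratio.size == n):
            raise ValueError("state vectors must have equal length")
        if np.any(~np.isfinite(self.log_abundance)):
            raise ValueError("abundances must be strictly positive (finite log)")
        if np.any(self.collapse_ratio <= 0) or np.any(self.collapse_ratio >= 1):
            raise ValueError("collapse ratios must lie strictly in (0, 1)")

    @property
    def n_species(self) -> int:
        return self.log_abundance.size

    @property
    def abundance(self) -> np.ndarray:
        """Relative abundances on the linear scale (may underflow to 0)."""
        return np.exp(self.log_abundance)

    @property
    def alive(self) -> np.ndarray:
        """Boolean mask: species above the extinction floor."""
        return self.log_abundance >= np.log(self.extinction_floor)

    @property
    def log10_abundance(self) -> np.ndarray:
        return self.log_abundance / LN10

    def total_abundance(self) -> float:
        return float(np.exp(logsumexp(self.log_abundance)))

    def copy(self) -> "CommunityState":
        return CommunityState(
            log_abundance=self.log_abundance,
            growth_rate=self.growth_rate,
            collapse_ratio=self.collapse_ratio,
            extinction_floor=self.extinction_floor,
            model_time=self.model_time,
            event_count=self.event_count,
        )


@dataclass
class CollapseEvent:
    """Record of one collapse: who fell, when, from and to what level."""

    event_index: int
    model_time: float
    dt: float
    species_id: int
    extra_victims: list[int]
    log_abundance_before: list[float]  # natural log, primary victim first
    log_abundance_after: list[float]

    @property
    def victims(self) -> list[int]:
        return [self.species_id, *self.extra_victims]


class EventLog:
    """Append-only stream of collapse events for one run."""

    def __init__(self, params_dict: dict | None = None) -> None:
        self.events: list[CollapseEvent] = []
        self.params_dict = params_dict or {}

    def append(self, event: CollapseEvent) -> None:
        self.events.append(event)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def victim_counts(self, n_species: int, include_extra: bool = True) -> np.ndarray:
        """Number of collapses suffered by each species."""
        counts = np.zeros(n_species, dtype=int)
        for ev in self.events:
            counts[ev.species_id] += 1
            if include_extra:
                for j in ev.extra_victims:
                    counts[j] += 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "event_index": ev.event_index,
                "model_time": ev.model_time,
                "dt": ev.dt,
                "species_id": ev.species_id,
                "extra_victims": ";".join(str(j) for j in ev.extra_victims),
                "log10_before": ev.log_abundance_before[0] / LN10,
                "log10_after": ev.log_abundance_after[0] / LN10,
            }
            for ev in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "event_index",
                "model_time",
                "dt",
                "species_id",
                "extra_victims",
                "log10_before",
                "log10_after",
            ],
        )

    @property
    def dts(self) -> np.ndarray:
        return np.array([ev.dt for ev in self.events])

    @property
    def victims_primary(self) -> np.ndarray:
        return np.array([ev.species_id for ev in self.events], dtype=int)


@dataclass
class Snapshots:
    """Post-growth, pre-collapse abundance snapshots of a run.

    ``log10`` has one row per recorded event (every ``thin``-th event) and
    one column per species.  Together with the matching ``dt`` weights these
    suffice to recompute time-averaged abundances.
    """

    event_index: np.ndarray  # (n_recorded,)
    model_time: np.ndarray  # (n_recorded,)
    dt: np.ndarray  # (n_recorded,) interval preceding each snapshot
    log10: np.ndarray  # (n_recorded, n_species)
    thin: int = 1

    def __len__(self) -> int:
        return self.event_index.size

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.log10,
            columns=[f"sp{j}" for j in range(self.log10.shape[1])],
        )
        df.insert(0, "dt", self.dt)
        df.insert(0, "model_time", self.model_time)
        df.insert(0, "event_index", self.event_index)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, thin: int = 1) -> "Snapshots":
        sp_cols = [c for c in df.columns if c.startswith("sp")]
        return cls(
            event_index=df["event_index"].to_numpy(dtype=int),
            model_time=df["model_time"].to_numpy(dtype=float),
            dt=df["dt"].to_numpy(dtype=float),
            log10=df[sp_cols].to_numpy(dtype=float),
            thin=thin,
        )
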