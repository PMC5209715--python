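"""Steady-state theory of the collapse-driven Kill-the-Winner model.

In the long run every surviving species cycles: its excess growth rate over
the self-consistent survival threshold g_cc, accumulated over the mean
inter-collapse interval tau, is exactly paid back by the logarithmic loss
|log gamma| of its collapses, which strike it with per-event probability

    c_i = (g_i - g_cc) * tau / |log gamma_i|.

One collapse per event (sum_i c_i = 1) pins g_cc, the number of species with
g_i > g_cc is the surviving diversity D, and each survivor cycles with period
T_i = 1/c_i collapse events.  Averaging over the growth-rate distribution
gives closed forms: D = |log gamma|/(sigma*tau) for exponentially distributed
rates, and a Gaussian analogue solved here by root finding on the standard
normal partial expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import norm

from .params import ConfigError
from .state import EventLog, Snapshots


@dataclass
class AnalyticPrediction:
    """Self-consistent steady-state quantities for one community.

    Attributes
    ----------
    g_cc:
        Survival threshold growth rate; species with g_i <= g_cc are driven
        to extinction.
    D_pred:
        Predicted diversity (number of survivors), in [1, N].
    c:
        Per-species, per-event collapse probabilities (sum to 1 over
        survivors, zero for the doomed).
    T:
        Cycle periods 1/c_i in units of collapse events (inf for the doomed).
    mean_log_gamma:
        |log gamma_i| averaged across species — the severity scale entering
        the diversity law when collapse ratios are heterogeneous.
    """

    g_cc: float
    D_pred: float
    c: np.ndarray | None = None
    T: np.ndarray | None = None
    mean_log_gamma: float | None = None


def solve_gcc_empirical(
    growth_rates: np.ndarray,
    tau: float,
    log_gamma_abs: float | np.ndarray,
) -> AnalyticPrediction:
    """Exact threshold for a realised set of growth rates.

    Solves sum_i max(g_i - g_cc, 0) * tau / |log gamma_i| = 1 by scanning the
    piecewise-linear, strictly decreasing left-hand side over the sorted
    rates: for each candidate survivor set (the top-k rates) the balance is
    linear in g_cc and the unique root lies in exactly one bracket.

    ``log_gamma_abs`` may be a scalar or per-species vector of |log gamma_i|.
    """
    g = np.asarray(growth_rates, dtype=float)
    if g.size < 1:
        raise ConfigError("need at least one species")
    if not tau > 0:
        raise ConfigError(f"tau must be > 0, got {tau}")
    L = np.broadcast_to(np.atleast_1d(np.asarray(log_gamma_abs, dtype=float)), g.shape)
    if np.any(L <= 0):
        raise ConfigError("log_gamma_abs must be > 0")

    order = np.argsort(g)[::-1]
    gs, Ls = g[order], L[order]
    w = 1.0 / Ls  # balance weight of each species
    cum_gw = np.cumsum(gs * w)
    cum_w = np.cumsum(w)
    n = g.size

    g_cc = None
    for k in range(1, n + 1):
        cand = (cum_gw[k - 1] - 1.0 / tau) / cum_w[k - 1]
        upper = gs[k - 1]
        lower = gs[k] if k < n else -np.inf
        if lower <= cand < upper or (k == n and cand < upper):
            g_cc = cand
            break
    if g_cc is None:  # all rates equal: balance shared evenly
        g_cc = (cum_gw[-1] - 1.0 / tau) / cum_w[-1]

    c = np.maximum(g - g_cc, 0.0) * tau / L
    with np.errstate(divide="ignore"):
        T = np.where(c > 0, 1.0 / np.where(c > 0, c, 1.0), np.inf)
    return AnalyticPrediction(
        g_cc=float(g_cc),
        D_pred=float(np.sum(g > g_cc)),
        c=c,
        T=T,
        mean_log_gamma=float(L.mean()),
    )


def predict_diversity_exponential(
    n_species: int,
    sigma: float,
    tau: float,
    log_gamma_abs: float,
) -> AnalyticPrediction:
    """Diversity law for exponentially distributed growth rates.

    D = |log gamma| / (sigma * tau), clipped to [1, N]; a single fastest
    grower always survives and no more than N species exist.  The matching
    threshold is g_cc = sigma * log(N / D).
    """
    if sigma < 0 or not tau > 0 or not log_gamma_abs > 0:
        raise ConfigError("require sigma >= 0, tau > 0, log_gamma_abs > 0")
    if sigma == 0:
        # no rate spread: competitive exclusion is void, everything ties
        return AnalyticPrediction(g_cc=0.0, D_pred=float(n_species),
                                  mean_log_gamma=log_gamma_abs)
    D = float(np.clip(log_gamma_abs / (sigma * tau), 1.0, n_species))
    g_cc = sigma * np.log(n_species / D)
    return AnalyticPrediction(g_cc=float(g_cc), D_pred=D, mean_log_gamma=log_gamma_abs)


def predict_diversity_gaussian(
    n_species: int,
    sigma: float,
    tau: float,
    log_gamma_abs: float,
    z_bracket: float = 12.0,
    z_tol: float = 1e-10,
) -> AnalyticPrediction:
    """Diversity law for Gaussian growth rates, by root finding.

    With g ~ N(0, sigma^2) and z = g_cc/sigma, the expected one-collapse-
    per-event balance reads

        N * sigma * tau * [phi(z) - z * Q(z)] / |log gamma| = 1,

    where phi is the standard normal density and Q(z) = P(Z > z); the
    bracketed term is the partial expectation E[max(Z - z, 0)].  The
    predicted diversity is the expected survivor count D = N * Q(z),
    clipped to [1, N].
    """
    if n_species < 1 or sigma < 0 or not tau > 0 or not log_gamma_abs > 0:
        raise ConfigError("require N >= 1, sigma >= 0, tau > 0, log_gamma_abs > 0")
    if sigma == 0:
        return AnalyticPrediction(g_cc=0.0, D_pred=float(n_species),
                                  mean_log_gamma=log_gamma_abs)

    target = log_gamma_abs / (n_species * sigma * tau)

    def excess(z: float) -> float:
        # E[max(Z - z, 0)] = phi(z) - z * Q(z), strictly decreasing in z
        return norm.pdf(z) - z * (1.0 - ndtr(z))

    lo, hi = -z_bracket, z_bracket
    if excess(lo) <= target:
        warnings.warn("no bracket: collapses dominate, capping diversity at N")
        return AnalyticPrediction(g_cc=float(-z_bracket * sigma),
                                  D_pred=float(n_species),
                                  mean_log_gamma=log_gamma_abs)
    if excess(hi) >= target:
        warnings.warn("no bracket: selection dominates, capping diversity at 1")
        return AnalyticPrediction(g_cc=float(z_bracket * sigma), D_pred=1.0,
                                  mean_log_gamma=log_gamma_abs)
    z = brentq(lambda x: excess(x) - target, lo, hi, xtol=z_tol)
    D = float(np.clip(n_species * (1.0 - ndtr(z)), 1.0, n_species))
    return AnalyticPrediction(g_cc=float(z * sigma), D_pred=D,
                              mean_log_gamma=log_gamma_abs)


def collapse_rates_and_periods(
    prediction: AnalyticPrediction,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-species collapse probabilities and cycle periods (events)."""
    if prediction.c is None:
        raise ConfigError("prediction carries no per-species rates")
    c = prediction.c
    with np.errstate(divide="ignore"):
        T = np.where(c > 0, 1.0 / np.where(c > 0, c, 1.0), np.inf)
    return c, T


def empirical_stats(
    event_log: EventLog,
    snapshots: Snapshots,
    n_species: int | None = None,
    burn_in_fraction: float = 1.0 / 3.0,
) -> pd.DataFrame:
    """Per-species run statistics after discarding the burn-in transient.

    Returns a frame indexed by species with columns ``collapse_count``,
    ``collapse_frequency`` (share of post-burn-in events in which the species
    was the primary victim), ``time_avg_abundance`` and ``mean_period`` (mean
    event-count gap between its consecutive collapses; NaN below two
    collapses).

    The time average is the plain mean of the post-growth snapshots: collapse
    epochs form a Poisson process, so event times sample time uniformly and
    the unweighted event average is the consistent estimator of the
    continuous time average (weighting by the preceding interval would
    over-count fast growers, whose abundance at an epoch correlates with the
    interval length).
    """
    if len(event_log) == 0:
        raise ConfigError("empty event log")
    if n_species is None:
        n_species = snapshots.log10.shape[1]
    total = len(event_log)
    burn = int(np.floor(burn_in_fraction * total))

    victims = event_log.victims_primary
    kept = victims[burn:]
    counts = np.bincount(kept, minlength=n_species)
    freq = counts / kept.size

    keep_mask = snapshots.event_index >= burn
    P = np.power(10.0, snapshots.log10[keep_mask])
    time_avg = P.mean(axis=0)

    periods = np.full(n_species, np.nan)
    idx_all = np.arange(total)[burn:]
    for i in range(n_species):
        hits = idx_all[kept == i]
        if hits.size >= 2:
            periods[i] = float(np.mean(np.diff(hits)))

    return pd.DataFrame(
        {
            "collapse_count": counts,
            "collapse_frequency": freq,
            "time_avg_abundance": time_avg,
            "mean_period": periods,
        },
        index=pd.RangeIndex(n_species, name="species"),
    )


def ktw_identity_check(
    event_log: EventLog,
    snapshots: Snapshots,
    n_species: int | None = None,
    burn_in_fraction: float = 1.0 / 3.0,
) -> pd.DataFrame:
    """Per-species test of the <P_i> = c_i identity with exact errors.

    The victim of each event is drawn with probability equal to the
    species' post-growth abundance at that very epoch, so the per-event
    residual 1{victim = i} - P_i(t_event) is a martingale difference: it has
    mean zero under the model and consecutive residuals are uncorrelated.
    The reported ``mean_diff`` is the mean abundance minus the victim
    frequency over the post-burn-in events and ``se`` its exact Monte-Carlo
    standard error, std(residual)/sqrt(M) — no autocorrelation correction is
    needed, unlike for the abundances themselves.

    Requires unthinned snapshots (one per event).
    """
    if n_species is None:
        n_species = snapshots.log10.shape[1]
    total = len(event_log)
    if snapshots.thin != 1 or len(snapshots) != total:
        raise ConfigError("identity check requires one snapshot per event")
    burn = int(np.floor(burn_in_fraction * total))
    victims = event_log.victims_primary[burn:]
    P = np.power(10.0, snapshots.log10[burn:])

    indicator = np.zeros_like(P)
    indicator[np.arange(victims.size), victims] = 1.0
    resid = P - indicator
    mean_diff = resid.mean(axis=0)
    se = resid.std(axis=0, ddof=1) / np.sqrt(victims.size)
    counts = np.bincount(victims, minlength=n_species)
    return pd.DataFrame(
        {
            "collapse_count": counts,
            "mean_diff": mean_diff,
            "se": se,
            "z": np.where(se > 0, mean_diff / np.where(se > 0, se, 1.0), np.nan),
        },
        index=pd.RangeIndex(n_species, name="species"),
    )
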