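"""Diagonal recurrence profile around the line of synchrony (LOS).

The LOS is the main diagonal of a square cross-recurrence plot: cells of
zero delay. The profile tracks the recurrence rate RR_tau on each
diagonal at delay tau within a +/- window (default 60 s), where
``tau = j - i`` for recurrent cell (i, j): positive delays mean the
gesture occurred first (gestures lead speech).

Derived measures: %Sync (100 * RR at tau = 0), RR_peak (maximum RR_tau),
tau_peak (its delay), and Q_LOS (recurrence mass on the speech-leading
side divided by the gesture-leading side; < 1 means gestures lead).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .events import TierSeries
from .recurrence import CrossRecurrencePlot


@dataclass(frozen=True)
class LosProfile:
    """Per-diagonal recurrence rates (and raw counts) in a +/- window."""

    window_s: int
    rr_by_delay: np.ndarray  # shape (2*window+1,), index k -> tau = k - window
    counts_by_delay: np.ndarray
    n: int

    @property
    def delays(self) -> np.ndarray:
        return np.arange(-self.window_s, self.window_s + 1)

    def rr_at(self, tau: int) -> float:
        if abs(tau) > self.window_s:
            raise ValueError(f"delay {tau} outside +/-{self.window_s} window")
        return float(self.rr_by_delay[tau + self.window_s])


@dataclass(frozen=True)
class LosMeasures:
    """Scalar summaries of a LOS profile; NaN encodes 'missing'."""

    pct_sync: float
    rr_peak: float
    tau_peak: float  # NaN when there is no recurrence in the window
    q_los: float  # NaN when the gesture-leading side has no recurrence
    rr_peak_p: float = float("nan")


def _diagonal_counts(recurrent: np.ndarray, window_s: int) -> np.ndarray:
    n = recurrent.shape[0]
    counts = np.empty(2 * window_s + 1, dtype=np.int64)
    for k, tau in enumerate(range(-window_s, window_s + 1)):
        counts[k] = int(np.trace(recurrent, offset=tau))
    return counts


def compute_profile(crp: CrossRecurrencePlot, window_s: int = 60) -> LosProfile:
    """Diagonal recurrence profile of a square plot.

    RR_tau is normalized per diagonal: the count of recurrent cells with
    ``j - i = tau`` divided by the diagonal's length ``n - |tau|``.
    """
    if crp.n_rows != crp.n_cols:
        raise ValueError("LOS profile requires a square plot")
    n = crp.n_rows
    if window_s >= n:
        raise ValueError(f"window_s={window_s} must be smaller than series length {n}")
    if window_s < 0:
        raise ValueError("window_s must be non-negative")
    counts = _diagonal_counts(crp.recurrent, window_s)
    delays = np.arange(-window_s, window_s + 1)
    rr = counts / (n - np.abs(delays))
    return LosProfile(window_s=window_s, rr_by_delay=rr, counts_by_delay=counts, n=n)


def profile_from_series(
    gesture_tiers: np.ndarray | TierSeries,
    speech_tiers: np.ndarray | TierSeries,
    window_s: int = 60,
) -> LosProfile:
    """Profile computed directly from the tier series, without the O(n^2) plot.

    Equivalent to ``compute_profile(build_crp(g, s), window_s)``; used on
    the permutation-test hot path.
    """
    g = np.asarray(getattr(gesture_tiers, "values", gesture_tiers), dtype=np.int64)
    s = np.asarray(getattr(speech_tiers, "values", speech_tiers), dtype=np.int64)
    if g.size != s.size:
        raise ValueError(f"series lengths differ: {g.size} vs {s.size}")
    n = g.size
    if window_s >= n:
        raise ValueError(f"window_s={window_s} must be smaller than series length {n}")
    counts = np.empty(2 * window_s + 1, dtype=np.int64)
    for k, tau in enumerate(range(-window_s, window_s + 1)):
        if tau >= 0:
            a, b = g[: n - tau], s[tau:]
        else:
            a, b = g[-tau:], s[: n + tau]
        counts[k] = int(np.count_nonzero((a == b) & (a != 0)))
    delays = np.arange(-window_s, window_s + 1)
    rr = counts / (n - np.abs(delays))
    return LosProfile(window_s=window_s, rr_by_delay=rr, counts_by_delay=counts, n=n)


def los_measures(profile: LosProfile) -> LosMeasures:
    """%Sync, RR_peak, tau_peak and Q_LOS of one profile.

    tau_peak ties are broken toward the smallest |tau|, then toward the
    positive delay. Q_LOS uses raw recurrent-point counts within the
    window, excluding tau = 0; it is 0 when only the gesture-leading side
    carries recurrence, and NaN when the gesture-leading side is empty.
    """
    rr = profile.rr_by_delay
    delays = profile.delays
    pct_sync = 100.0 * profile.rr_at(0)
    rr_peak = float(rr.max())
    if profile.counts_by_delay.sum() == 0:
        tau_peak = float("nan")
    else:
        peak_delays = delays[rr == rr_peak]
        # smallest |tau|, positive preferred on an exact +/- tie
        tau_peak = float(min(peak_delays, key=lambda t: (abs(t), t < 0)))
    left = int(profile.counts_by_delay[delays < 0].sum())  # speech leads
    right = int(profile.counts_by_delay[delays > 0].sum())  # gestures lead
    q_los = left / right if right > 0 else float("nan")
    return LosMeasures(pct_sync=pct_sync, rr_peak=rr_peak, tau_peak=tau_peak, q_los=q_los)


def _episode_blocks(values: np.ndarray) -> list[np.ndarray]:
    """Split a series into blocks of one constant nonzero run plus trailing zeros.

    Leading zeros (before any episode) form their own block. Concatenating
    the blocks in order reproduces the series.
    """
    blocks: list[np.ndarray] = []
    n = values.size
    i = 0
    # leading zeros
    j = i
    while j < n and values[j] == 0:
        j += 1
    if j > i:
        blocks.append(values[i:j])
        i = j
    while i < n:
        j = i
        while j < n and values[j] == values[i]:
            j += 1
        while j < n and values[j] == 0:
            j += 1
        blocks.append(values[i:j])
        i = j
    return blocks


def shuffle_series(
    values: np.ndarray, rng: np.random.Generator, mode: str = "episode_shuffle"
) -> np.ndarray:
    """Surrogate series for the RR_peak null.

    ``episode_shuffle`` permutes whole coded episodes (a constant nonzero
    run with its trailing zeros), preserving episode durations, level
    composition and within-episode autocorrelation. ``second_shuffle``
    permutes individual seconds.
    """
    if mode == "second_shuffle":
        return rng.permutation(values)
    if mode != "episode_shuffle":
        raise ValueError(f"unknown shuffle mode {mode!r}")
    blocks = _episode_blocks(np.asarray(values))
    if len(blocks) <= 1:
        return np.asarray(values).copy()
    order = rng.permutation(len(blocks))
    return np.concatenate([blocks[k] for k in order])


def rr_peak_significance(
    gesture_tiers: TierSeries | np.ndarray,
    speech_tiers: TierSeries | np.ndarray,
    window_s: int = 60,
    n_perm: int = 1000,
    seed: int | None = None,
    null: str = "episode_shuffle",
) -> float:
    """Permutation p-value for the observed RR_peak.

    The null is generated by shuffling the gesture stream (see
    :func:`shuffle_series`) ``n_perm`` times; the p-value is
    ``(1 + #{surrogate RR_peak >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    g = np.asarray(getattr(gesture_tiers, "values", gesture_tiers), dtype=np.int64)
    s = np.asarray(getattr(speech_tiers, "values", speech_tiers), dtype=np.int64)
    observed = los_measures(profile_from_series(g, s, window_s)).rr_peak
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        surrogate = shuffle_series(g, rng, mode=null)
        peak = float(profile_from_series(surrogate, s, window_s).rr_by_delay.max())
        if peak >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def export_profile(profile: LosProfile, path: str | Path) -> None:
    """Write the profile as a ``tau,rr`` CSV over the window."""
    pd.DataFrame({"tau": profile.delays, "rr": profile.rr_by_delay}).to_csv(
        path, index=False
    )
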