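"""Independent brute-force oracles: naive cell-by-cell recomputations used to
cross-check the vectorized implementations. Deliberately slow and literal."""

from __future__ import annotations

import numpy as np


def naive_crp(g: np.ndarray, s: np.ndarray) -> np.ndarray:
    n, m = len(g), len(s)
    out = np.zeros((n, m), dtype=np.int64)
    for i in range(n):
        for j in range(m):
            if g[i] != 0 and g[i] == s[j]:
                out[i, j] = g[i]
    return out


def naive_lines(matrix: np.ndarray, orientation: str, min_line: int):
    """(anchor, start, length, tier) of every maximal run >= min_line."""
    m = matrix if orientation == "vertical" else matrix.T
    lines = []
    for anchor in range(m.shape[1]):
        i = 0
        while i < m.shape[0]:
            if m[i, anchor] == 0:
                i += 1
                continue
            start = i
            while i < m.shape[0] and m[i, anchor] != 0:
                i += 1
            length = i - start
            if length >= min_line:
                lines.append((anchor, start, length, int(m[start, anchor])))
    return lines


def _orientation_naive(matrix: np.ndarray, orientation: str, min_line: int):
    all_runs = [ln[2] for ln in naive_lines(matrix, orientation, 1)]
    qual = [ln[2] for ln in naive_lines(matrix, orientation, min_line)]
    points = sum(qual)
    tt = sum(qual) / len(qual) if qual else 0.0
    maxl = max(all_runs) if all_runs else 0
    return points, tt, maxl


def naive_measures(matrix: np.ndarray, min_line: int = 2) -> dict:
    n_rec = int(np.count_nonzero(matrix))
    rr = n_rec / matrix.size
    pv, ttv, mv = _orientation_naive(matrix, "vertical", min_line)
    ph, tth, mh = _orientation_naive(matrix, "horizontal", min_line)
    return {
        "rr": rr,
        "lam_v": pv / n_rec if n_rec else 0.0,
        "lam_h": ph / n_rec if n_rec else 0.0,
        "tt_v": ttv,
        "tt_h": tth,
        "maxl_v": mv,
        "maxl_h": mh,
    }


def naive_tier_measures(matrix: np.ndarray, tier: int, min_line: int = 2) -> dict:
    n_rec_total = int(np.count_nonzero(matrix))
    restricted = np.where(matrix == tier, tier, 0)
    n_tier = int(np.count_nonzero(restricted))
    pv, ttv, mv = _orientation_naive(restricted, "vertical", min_line)
    ph, tth, mh = _orientation_naive(restricted, "horizontal", min_line)
    return {
        "pct_rr": 100.0 * n_tier / n_rec_total if n_rec_total else 0.0,
        "lam_v": pv / n_rec_total if n_rec_total else 0.0,
        "lam_h": ph / n_rec_total if n_rec_total else 0.0,
        "tt_v": ttv,
        "tt_h": tth,
        "maxl_v": mv,
        "maxl_h": mh,
    }


def naive_profile_counts(matrix: np.ndarray, window: int) -> dict[int, int]:
    n = matrix.shape[0]
    counts = {tau: 0 for tau in range(-window, window + 1)}
    for i in range(n):
        for j in range(n):
            tau = j - i
            if abs(tau) <= window and matrix[i, j] != 0:
                counts[tau] += 1
    return counts


def random_tier_series(rng: np.random.Generator, n: int, density: float = 0.6,
                       mean_run: float = 3.0) -> np.ndarray:
    """Episode-structured random tier series (short runs, controllable density)."""
    out = np.zeros(n, dtype=np.int64)
    i = 0
    while i < n:
        if rng.random() < density:
            run = 1 + rng.geometric(1.0 / mean_run)
            out[i : i + run] = rng.integers(1, 4)
            i += run
        else:
            i += 1 + int(rng.geometric(0.5))
    return out[:n]
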