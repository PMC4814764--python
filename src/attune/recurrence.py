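"""Categorical tier-matched cross-recurrence plots and anisotropic measures.

The cross-recurrence plot (CRP) of two tier series puts gesture time on
the rows (vertical axis) and speech time on the columns (horizontal
axis); cell (i, j) holds the shared tier t in {1, 2, 3} when
``gesture_tier[i] == speech_tier[j] == t``, and 0 otherwise.  Seconds in
which either stream shows no leveled behavior are never recurrent.

Measures are computed *anisotropically*: vertical and horizontal line
structures are quantified separately.  A vertical line is a maximal run
of recurrent cells within a column (the gesture stream lingering in a
tier briefly visited by speech); a horizontal line is a run within a
row.  Laminarity (LAM) is the share of recurrent points lying on lines
of length >= ``min_line``; trapping time (TT) is the mean length of
those lines; MaxL is the longest run of any length >= 1.  Isolated
points therefore count toward MaxL but never toward LAM or TT.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .events import TierSeries

Orientation = Literal["vertical", "horizontal"]

TIERS = (1, 2, 3)


@dataclass(frozen=True)
class CrossRecurrencePlot:
    """Tier-labeled recurrence matrix; rows = gesture time, cols = speech time."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int64)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2:
            raise ValueError("CRP matrix must be 2-D")
        if m.min() < 0 or m.max() > 3:
            raise ValueError("CRP cells must be 0 (non-recurrent) or a tier 1..3")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    @property
    def recurrent(self) -> np.ndarray:
        """Boolean mask of recurrent cells."""
        return self.matrix != 0

    def n_recurrent(self) -> int:
        return int(np.count_nonzero(self.matrix))

    def transpose(self) -> "CrossRecurrencePlot":
        return CrossRecurrencePlot(self.matrix.T)

    def restrict_to_tier(self, tier: int) -> "CrossRecurrencePlot":
        """A plot retaining only the cells of one tier."""
        if tier not in TIERS:
            raise ValueError(f"tier must be in {TIERS}, got {tier}")
        return CrossRecurrencePlot(np.where(self.matrix == tier, tier, 0))


@dataclass(frozen=True)
class LineStructure:
    """One maximal run of recurrent cells along one orientation."""

    orientation: Orientation
    anchor: int  # column for vertical lines, row for horizontal
    start: int  # first index along the run
    length: int
    tier: int


@dataclass(frozen=True)
class CrqaMeasures:
    """Global anisotropic CRQA measures of one plot."""

    rr: float
    lam_v: float
    lam_h: float
    tt_v: float
    tt_h: float
    maxl_v: int
    maxl_h: int


@dataclass(frozen=True)
class TierMeasures:
    """CRQA measures restricted to one tier's recurrences.

    ``pct_rr`` and the laminarity values are normalized by the *full*
    plot's recurrent-point count, so that the tier values add up to the
    global ones; TT and MaxL are computed over this tier's lines only.
    """

    tier: int
    pct_rr: float
    lam_v: float
    lam_h: float
    tt_v: float
    tt_h: float
    maxl_v: int
    maxl_h: int


@dataclass(frozen=True)
class AsymmetryScores:
    """Relative vertical-horizontal difference scores; NaN when undefined."""

    vh_lam: float
    vh_tt: float
    vh_maxl: float


def build_crp(gesture_tiers: TierSeries, speech_tiers: TierSeries) -> CrossRecurrencePlot:
    """Cross-recurrence plot of two equal-length tier series.

    Cell (i, j) = shared tier when gesture tier at second i equals the
    speech tier at second j and both are nonzero; 0 otherwise.
    """
    g = np.asarray(gesture_tiers.values, dtype=np.int64)
    s = np.asarray(speech_tiers.values, dtype=np.int64)
    if g.size != s.size:
        raise ValueError(f"series lengths differ: {g.size} vs {s.size}")
    match = (g[:, None] == s[None, :]) & (g[:, None] != 0)
    return CrossRecurrencePlot(np.where(match, g[:, None], 0))


def extract_lines(
    crp: CrossRecurrencePlot, orientation: Orientation, min_line: int = 2
) -> list[LineStructure]:
    """All maximal runs of length >= ``min_line`` along one orientation.

    Runs are tier-pure by construction: every recurrent cell in column j
    carries the speech tier of second j (and symmetrically for rows).
    """
    if min_line < 1:
        raise ValueError("min_line must be >= 1")
    if orientation not in ("vertical", "horizontal"):
        raise ValueError(f"unknown orientation {orientation!r}")
    m = crp.matrix if orientation == "vertical" else crp.matrix.T
    lines: list[LineStructure] = []
    for anchor in range(m.shape[1]):
        col = m[:, anchor]
        nz = col != 0
        # run boundaries via diff of the padded mask
        edges = np.flatnonzero(np.diff(np.concatenate(([False], nz, [False]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            length = int(stop - start)
            if length >= min_line:
                lines.append(
                    LineStructure(
                        orientation=orientation,
                        anchor=int(anchor),
                        start=int(start),
                        length=length,
                        tier=int(col[start]),
                    )
                )
    return lines


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """Lengths of all maximal True runs along axis 0, across all columns."""
    padded = np.zeros((mask.shape[0] + 1, mask.shape[1]), dtype=bool)
    padded[:-1] = mask
    # column-major flatten: columns concatenated, each terminated by False,
    # so runs cannot bleed across column boundaries
    flat = np.concatenate(([False], padded.ravel(order="F")))
    d = np.diff(flat.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return stops - starts


def _orientation_stats(mask: np.ndarray, min_line: int) -> tuple[int, float, int]:
    """(points on qualifying lines, mean qualifying length, longest run >= 1)."""
    if not mask.any():
        return 0, 0.0, 0
    lengths = _run_lengths(mask)
    maxl = int(lengths.max())
    qualifying = lengths[lengths >= min_line]
    if qualifying.size == 0:
        return 0, 0.0, maxl
    return int(qualifying.sum()), float(qualifying.mean()), maxl


def global_measures(crp: CrossRecurrencePlot, min_line: int = 2) -> CrqaMeasures:
    """RR, LAM, TT and MaxL per orientation over the whole plot.

    RR is normalized by the full plot area (``n_rows * n_cols``); LAM by
    the number of recurrent points.  When there is no recurrence at all,
    every measure is 0.
    """
    rec = crp.recurrent
    n_rec = int(rec.sum())
    rr = n_rec / (crp.n_rows * crp.n_cols)
    pts_v, tt_v, maxl_v = _orientation_stats(rec, min_line)
    pts_h, tt_h, maxl_h = _orientation_stats(rec.T, min_line)
    lam_v = pts_v / n_rec if n_rec else 0.0
    lam_h = pts_h / n_rec if n_rec else 0.0
    return CrqaMeasures(
        rr=rr, lam_v=lam_v, lam_h=lam_h, tt_v=tt_v, tt_h=tt_h, maxl_v=maxl_v, maxl_h=maxl_h
    )


def tier_measures(crp: CrossRecurrencePlot, tier: int, min_line: int = 2) -> TierMeasures:
    """CRQA measures over one tier's recurrences.

    ``pct_rr`` (percent) and LAM keep the full plot's recurrent-point
    count as denominator, so tier values sum to the global ones across
    tiers; TT and MaxL are computed on this tier's lines only.
    """
    if tier not in TIERS:
        raise ValueError(f"tier must be in {TIERS}, got {tier}")
    n_rec_total = crp.n_recurrent()
    mask = crp.matrix == tier
    n_tier = int(mask.sum())
    pct_rr = 100.0 * n_tier / n_rec_total if n_rec_total else 0.0
    pts_v, tt_v, maxl_v = _orientation_stats(mask, min_line)
    pts_h, tt_h, maxl_h = _orientation_stats(mask.T, min_line)
    lam_v = pts_v / n_rec_total if n_rec_total else 0.0
    lam_h = pts_h / n_rec_total if n_rec_total else 0.0
    return TierMeasures(
        tier=tier,
        pct_rr=pct_rr,
        lam_v=lam_v,
        lam_h=lam_h,
        tt_v=tt_v,
        tt_h=tt_h,
        maxl_v=maxl_v,
        maxl_h=maxl_h,
    )


def asymmetry(measures: CrqaMeasures | TierMeasures) -> AsymmetryScores:
    """Relative difference scores contrasting vertical and horizontal structure.

    ``vh_lam = lam_v - lam_h`` (proportions are directly comparable);
    ``vh_tt`` and ``vh_maxl`` are normalized differences
    ``(v - h) / (v + h)``, NaN when both operands are 0.
    """
    return AsymmetryScores(
        vh_lam=measures.lam_v - measures.lam_h,
        vh_tt=relative_difference(measures.tt_v, measures.tt_h),
        vh_maxl=relative_difference(measures.maxl_v, measures.maxl_h),
    )


def relative_difference(v: float, h: float) -> float:
    """(v - h) / (v + h); NaN when the denominator is 0."""
    denom = v + h
    if denom == 0:
        return float("nan")
    return (v - h) / denom


def export_crp(crp: CrossRecurrencePlot, path: str | Path, sparse: bool = False) -> None:
    """Write a plot as a dense integer CSV, or as sparse ``i,j,tier`` triplets."""
    path = Path(path)
    if sparse:
        i, j = np.nonzero(crp.matrix)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("i,j,tier\n")
            for a, b in zip(i, j):
                fh.write(f"{a},{b},{crp.matrix[a, b]}\n")
    else:
        np.savetxt(path, crp.matrix, fmt="%d", delimiter=",")
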