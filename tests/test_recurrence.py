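import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import oracles
from attune.events import TierSeries
from attune.recurrence import (
    CrossRecurrencePlot,
    asymmetry,
    build_crp,
    extract_lines,
    global_measures,
    relative_difference,
    tier_measures,
)

tier_series = arrays(np.int64, st.integers(2, 40), elements=st.integers(0, 3))

tier_series_pair = st.integers(2, 40).flatmap(
    lambda n: st.tuples(
        arrays(np.int64, n, elements=st.integers(0, 3)),
        arrays(np.int64, n, elements=st.integers(0, 3)),
    )
)


def _crp(matrix):
    return CrossRecurrencePlot(np.array(matrix, dtype=np.int64))


class TestBuildCrp:
    def test_identical_constant_series(self):
        crp = build_crp(TierSeries(np.array([1, 1, 1])), TierSeries(np.array([1, 1, 1])))
        assert (crp.matrix == 1).all()
        assert global_measures(crp).rr == 1.0

    def test_disjoint_tiers(self):
        crp = build_crp(TierSeries(np.array([1, 1])), TierSeries(np.array([2, 2])))
        assert crp.n_recurrent() == 0

    def test_enumerated_cells(self):
        crp = build_crp(TierSeries(np.array([1, 0, 2])), TierSeries(np.array([2, 1, 0])))
        expected = np.zeros((3, 3), dtype=int)
        expected[0, 1] = 1
        expected[2, 0] = 2
        assert (crp.matrix == expected).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_crp(TierSeries(np.array([1, 1])), TierSeries(np.array([1])))

    def test_zero_seconds_never_recurrent(self):
        crp = build_crp(TierSeries(np.array([0, 0])), TierSeries(np.array([0, 0])))
        assert crp.n_recurrent() == 0

    @given(tier_series_pair)
    @settings(max_examples=60, deadline=None)
    def test_matches_naive(self, pair):
        g, s = pair
        crp = build_crp(TierSeries(g), TierSeries(s))
        assert (crp.matrix == oracles.naive_crp(g, s)).all()


class TestExtractLines:
    def test_single_full_column(self):
        m = np.zeros((5, 5), dtype=int)
        m[:, 2] = 1
        vert = extract_lines(_crp(m), "vertical", min_line=2)
        assert len(vert) == 1
        line = vert[0]
        assert (line.anchor, line.start, line.length, line.tier) == (2, 0, 5, 1)
        assert extract_lines(_crp(m), "horizontal", min_line=2) == []

    def test_all_zero_plot(self):
        assert extract_lines(_crp(np.zeros((4, 4), int)), "vertical") == []

    def test_min_line_one_counts_isolated(self):
        m = np.zeros((3, 3), dtype=int)
        m[1, 1] = 2
        assert len(extract_lines(_crp(m), "vertical", min_line=1)) == 1

    def test_random_plots_match_naive_scanner(self, rng):
        for _ in range(30):
            m = rng.integers(0, 4, size=(8, 8))
            m[rng.random(size=(8, 8)) < 0.5] = 0
            for orientation in ("vertical", "horizontal"):
                got = [
                    (l.anchor, l.start, l.length, l.tier)
                    for l in extract_lines(_crp(m), orientation, min_line=2)
                ]
                assert sorted(got) == sorted(oracles.naive_lines(m, orientation, 2))

    def test_runs_are_maximal_and_tier_pure(self, rng):
        # tier purity is guaranteed for genuine CRPs (one tier per second)
        g = oracles.random_tier_series(rng, 30)
        s = oracles.random_tier_series(rng, 30)
        crp = build_crp(TierSeries(g), TierSeries(s))
        m = crp.matrix
        for line in extract_lines(crp, "vertical", min_line=2):
            col = m[:, line.anchor]
            run = col[line.start : line.start + line.length]
            assert (run == line.tier).all()
            if line.start > 0:
                assert col[line.start - 1] == 0
            if line.start + line.length < len(col):
                assert col[line.start + line.length] == 0


class TestGlobalMeasures:
    def test_full_plot(self):
        m = global_measures(_crp(np.ones((3, 3), int)))
        assert (m.rr, m.lam_v, m.lam_h, m.tt_v, m.tt_h, m.maxl_v, m.maxl_h) == (
            1.0, 1.0, 1.0, 3.0, 3.0, 3, 3,
        )

    def test_isolated_point_counts_for_maxl_only(self):
        m = np.zeros((4, 5), int)
        m[2, 3] = 1
        gm = global_measures(_crp(m))
        assert gm.rr == 1 / 20
        assert gm.lam_v == gm.lam_h == 0.0
        assert gm.tt_v == gm.tt_h == 0.0
        assert gm.maxl_v == gm.maxl_h == 1

    def test_empty_plot_all_zero(self):
        gm = global_measures(_crp(np.zeros((3, 3), int)))
        assert (gm.rr, gm.lam_v, gm.maxl_v) == (0.0, 0.0, 0)

    def test_random_plots_match_oracle(self, rng):
        for _ in range(30):
            m = rng.integers(0, 4, size=(12, 12))
            m[rng.random(size=(12, 12)) < 0.4] = 0
            gm = global_measures(_crp(m))
            expected = oracles.naive_measures(m)
            for key, val in expected.items():
                assert getattr(gm, key) == pytest.approx(val), key

    def test_adding_recurrent_cell_never_decreases_rr(self, rng):
        m = rng.integers(0, 4, size=(10, 10))
        zeros = np.argwhere(m == 0)
        rr0 = global_measures(_crp(m)).rr
        i, j = zeros[0]
        m2 = m.copy()
        m2[i, j] = 1
        assert global_measures(_crp(m2)).rr > rr0

    def test_extending_run_never_decreases_maxl(self):
        m = np.zeros((6, 6), int)
        m[1:3, 2] = 1
        before = global_measures(_crp(m)).maxl_v
        m[3, 2] = 1
        assert global_measures(_crp(m)).maxl_v >= before


class TestTierMeasures:
    def test_definitional_split(self):
        # 10 tier-1 cells in two vertical 5-lines, 10 tier-2 isolated-ish cells
        m = np.zeros((10, 10), int)
        m[0:5, 0] = 1
        m[5:10, 2] = 1
        for k in range(10):
            m[k, 4 + (k % 2) * 2] = 2  # scattered, no vertical adjacency
        t1 = tier_measures(_crp(m), 1)
        assert t1.pct_rr == pytest.approx(50.0)
        assert t1.lam_v == pytest.approx(0.5)

    def test_absent_tier_all_zero(self):
        m = np.zeros((4, 4), int)
        m[0, 0] = 1
        t3 = tier_measures(_crp(m), 3)
        assert (t3.pct_rr, t3.lam_v, t3.tt_v, t3.maxl_v) == (0.0, 0.0, 0.0, 0)

    def test_invalid_tier(self):
        with pytest.raises(ValueError):
            tier_measures(_crp(np.zeros((2, 2), int)), 4)

    def test_matches_naive(self, rng):
        for _ in range(20):
            m = rng.integers(0, 4, size=(12, 12))
            for tier in (1, 2, 3):
                tm = tier_measures(_crp(m), tier)
                expected = oracles.naive_tier_measures(m, tier)
                for key, val in expected.items():
                    assert getattr(tm, key) == pytest.approx(val), (tier, key)

    @given(tier_series_pair)
    @settings(max_examples=60, deadline=None)
    def test_tier_additivity(self, pair):
        g, s = pair
        crp = build_crp(TierSeries(g), TierSeries(s))
        gm = global_measures(crp)
        tms = [tier_measures(crp, t) for t in (1, 2, 3)]
        if crp.n_recurrent():
            assert sum(t.pct_rr for t in tms) == pytest.approx(100.0)
        assert sum(t.lam_v for t in tms) == pytest.approx(gm.lam_v)
        assert sum(t.lam_h for t in tms) == pytest.approx(gm.lam_h)


class TestTransposeDuality:
    @given(tier_series_pair)
    @settings(max_examples=60, deadline=None)
    def test_swap_equals_transpose(self, pair):
        g, s = pair
        a = build_crp(TierSeries(g), TierSeries(s))
        b = build_crp(TierSeries(s), TierSeries(g))
        assert (b.matrix == a.matrix.T).all()
        ma, mb = global_measures(a), global_measures(b)
        assert ma.rr == pytest.approx(mb.rr)
        assert ma.lam_v == pytest.approx(mb.lam_h)
        assert ma.lam_h == pytest.approx(mb.lam_v)
        assert ma.tt_v == pytest.approx(mb.tt_h)
        assert ma.tt_h == pytest.approx(mb.tt_v)
        assert (ma.maxl_v, ma.maxl_h) == (mb.maxl_h, mb.maxl_v)


class TestAsymmetry:
    def test_reference_tt_example(self):
        assert round(relative_difference(7.6, 3.2), 2) == 0.41

    def test_reference_maxl_example(self):
        assert round(relative_difference(21, 7), 2) == 0.50

    def test_equal_tt_gives_zero(self):
        assert relative_difference(4.0, 4.0) == 0.0

    def test_both_zero_is_missing(self):
        assert math.isnan(relative_difference(0.0, 0.0))

    def test_scores_from_measures(self):
        gm = global_measures(_crp(np.ones((3, 3), int)))
        scores = asymmetry(gm)
        assert scores.vh_lam == 0.0
        assert scores.vh_tt == 0.0
        assert scores.vh_maxl == 0.0
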