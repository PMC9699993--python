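"""Score-statistic audit: Jaccard, symmetry, g(rho), thresholds, optimisers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chicaudit.score_eval import (
    fnr_g,
    fwer_score_threshold,
    jaccard,
    percent_reversible,
    replicate_fdr,
    score_symmetry,
    significant_set,
    solve_rho,
    sst_for_fnr,
    sst_minimising_fdr,
)


def scored_frame(rows):
    """rows: (bait, other, score, log_p, bait_bait)"""
    df = pd.DataFrame(rows, columns=["bait_id", "other_id", "score", "log_p",
                                     "bait_bait"])
    df["distance_bp"] = 50_000.0
    df["count"] = 1
    df["weight"] = 1.0
    return df


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard({1, 2}, {1, 2}, {1, 2}) == 1.0

    def test_disjoint_sets(self):
        assert jaccard({1}, {2}) == 0.0

    def test_hand_case(self):
        assert jaccard({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_all_empty_errors(self):
        with pytest.raises(ValueError):
            jaccard(set(), set())

    @settings(deadline=None, max_examples=100)
    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
    )
    def test_replicate_fdr_is_one_minus_jaccard(self, a, b):
        if not (a | b):
            return
        assert replicate_fdr([a, b]) == pytest.approx(1 - jaccard(a, b))


class TestSymmetry:
    def _bb(self, pairs):
        rows = []
        for i, (f, r) in enumerate(pairs):
            a, b = 10 + 2 * i, 11 + 2 * i
            rows.append((a, b, f, -1.0, True))
            rows.append((b, a, r, -1.0, True))
        return scored_frame(rows)

    def test_perfect_symmetry_gives_unit_correlation(self):
        res = score_symmetry(self._bb([(1, 1), (2, 2), (3, 3), (4, 4)]))
        assert res.correlation == pytest.approx(1.0)

    def test_hand_computed_correlation(self):
        pairs = [(1, 2), (2, 4), (3, 6), (0, 5)]
        res = score_symmetry(self._bb(pairs))
        x = np.array([p[0] for p in pairs], dtype=float)
        y = np.array([p[1] for p in pairs], dtype=float)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert res.n_used == 4
        assert res.correlation == pytest.approx(expected)

    def test_all_zero_pairs_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="non-zero"):
            res = score_symmetry(self._bb([(0, 0), (0, 0), (0, 0)]))
        assert res.correlation is None and res.n_used == 0

    def test_top_deviations_are_largest_squared_differences(self):
        pairs = [(10, 0), (5, 5), (1, 2), (8, 1), (3, 3.5), (9, 2), (0, 4)]
        res = score_symmetry(self._bb(pairs))
        devs = sorted(((f - r) ** 2 for f, r in pairs), reverse=True)[:5]
        assert sorted(res.top_deviations["sq_dev"], reverse=True) == (
            pytest.approx(devs)
        )


class TestReversible:
    def test_hand_enumeration(self):
        df = scored_frame(
            [
                (10, 11, 6, -1, True), (11, 10, 7, -1, True),
                (12, 13, 6, -1, True), (13, 12, 2, -1, True),
                (14, 15, 1, -1, True), (15, 14, 0, -1, True),
            ]
        )
        assert percent_reversible(df, threshold=5) == pytest.approx(0.5)

    def test_all_reversible(self):
        df = scored_frame([(10, 11, 6, -1, True), (11, 10, 8, -1, True)])
        assert percent_reversible(df, threshold=5) == 1.0

    def test_none_significant_is_absent(self):
        df = scored_frame([(10, 11, 1, -1, True), (11, 10, 2, -1, True)])
        with pytest.warns(UserWarning):
            assert percent_reversible(df, threshold=5) is None


class TestFnrG:
    def _table(self, scores, log_p=-20.0):
        return scored_frame(
            [(1, 100 + i, s, log_p, False) for i, s in enumerate(scores)]
        )

    def test_all_robust_significant(self):
        assert fnr_g(self._table([6, 7, 8]), rho=-10) == 0.0

    def test_no_robust_significant(self):
        assert fnr_g(self._table([1, 2, 3]), rho=-10) == 1.0

    def test_hand_enumeration(self):
        assert fnr_g(self._table([6, 7, 2, 3, 9]), rho=-10) == pytest.approx(0.4)

    def test_empty_denominator_errors(self):
        with pytest.raises(ValueError, match="-10"):
            fnr_g(self._table([6], log_p=-1.0), rho=-10)


class TestSolveRho:
    def _constructed(self):
        # ~continuous g: 1000 pairs with log p from -0.05 to -50; failure
        # density decreasing with depth so g crosses 0.05 inside the grid
        rows = []
        fails_assigned = 0
        for i in range(1, 1001):
            log_p = -0.05 * i
            if i > 800:
                fail = i % 50 == 0          # deep tail: 2% failures
            elif i > 200:
                fail = i % 4 == 0           # middle: 25% failures
            else:
                fail = i % 2 == 0           # shallow: 50% failures
            score = 1.0 if fail else 10.0
            rows.append((1, i + 10, score, log_p, False))
            fails_assigned += fail
        return scored_frame(rows)

    def test_crossing_found_within_tolerance(self):
        df = self._constructed()
        rho = solve_rho(df, target=0.05)
        assert rho is not None
        assert abs(fnr_g(df, rho) - 0.05) <= 0.005

    def test_monotone_bracket_oracle(self):
        # independent oracle: dense grid scan for the best achievable g
        df = self._constructed()
        grid = np.arange(-50, -1, 0.01)
        gs = []
        for r in grid:
            mask = df["log_p"] < r
            if mask.any():
                gs.append(abs(np.mean(df.loc[mask, "score"] < 5) - 0.05))
            else:
                gs.append(np.inf)
        best = np.min(gs)
        rho = solve_rho(df)
        assert abs(fnr_g(df, rho) - 0.05) <= best + 0.005

    def test_no_crossing_returns_absent(self):
        df = scored_frame([(1, 10 + i, 10.0, -20.0, False) for i in range(10)])
        with pytest.warns(UserWarning, match="never crosses"):
            assert solve_rho(df) is None


class TestFwerThreshold:
    def test_closed_form_single_pair(self):
        assert fwer_score_threshold(1) == pytest.approx(-np.log(0.05), rel=1e-12)

    def test_closed_form_realistic_bin(self):
        # O(1e5) proximal pairs put the threshold at score ~ 15
        assert fwer_score_threshold(163_000) == pytest.approx(15.0, abs=0.01)

    def test_log_additivity(self):
        for n in (1, 7, 1000):
            assert fwer_score_threshold(2 * n) == pytest.approx(
                fwer_score_threshold(n) + np.log(2), rel=1e-12
            )

    def test_zero_pairs_errors(self):
        with pytest.raises(ValueError):
            fwer_score_threshold(0)


def exhaustive_sst_fnr(scores, target, t_max=100):
    """Oracle: integer scan minimising |FNR - target|, ties to smaller t."""
    s = np.asarray(scores, dtype=float)
    best_t, best = 0, np.inf
    for t in range(t_max + 1):
        val = abs(np.mean(s < t) - target)
        if val < best - 1e-12:
            best, best_t = val, t
    return best_t


class TestSstForFnr:
    def _table(self, scores):
        return scored_frame(
            [(1, 100 + i, s, -20.0, False) for i, s in enumerate(scores)]
        )

    @pytest.mark.parametrize(
        "scores,target",
        [
            ([12, 9, 7, 4, 2], 0.2),
            ([12, 9, 7, 4, 2], 1.0),
            ([50] * 6, 0.2),
            ([1, 1, 2, 8, 30, 31, 90], 0.5),
        ],
    )
    def test_matches_exhaustive_scan(self, scores, target):
        got = sst_for_fnr(self._table(scores), target_fnr=target)
        assert got == exhaustive_sst_fnr(scores, target)

    def test_all_equal_scores_floor(self):
        # FNR is 0 for every t <= 50, already the closest to 0.2; smallest wins
        assert sst_for_fnr(self._table([50] * 5), target_fnr=0.2) == 0

    def test_no_robust_pairs_errors(self):
        df = scored_frame([(1, 2, 8.0, -1.0, False)])
        with pytest.raises(ValueError):
            sst_for_fnr(df, rho=-10)


def _replicates_with_plateau():
    """FDR(t) steps finely down to 0 on t in [7.8, 9.5) then jumps to 0.9.

    Three pair classes: strong in both replicates (never discordant),
    rep1-only pairs with scores on a 0.02 grid up to 7.8 (the fine
    staircase a finite-difference gradient can feel), and pairs scoring
    9.5 in rep1 but 100 in rep2, which flip from concordant to
    discordant above 9.5 and make overshooting costly.
    """
    rows1, rows2 = [], []
    oid = 100
    for _ in range(10):
        rows1.append((1, oid, 100.0, -30.0, False))
        rows2.append((1, oid, 100.0, -30.0, False))
        oid += 1
    for k in range(1, 391):  # rep1-only, scores 0.02 .. 7.8
        rows1.append((1, oid, 0.02 * k, -5.0, False))
        rows2.append((1, oid, 0.0, 0.0, False))
        oid += 1
    for _ in range(90):  # intersection members until t > 9.5
        rows1.append((1, oid, 9.5, -12.0, False))
        rows2.append((1, oid, 100.0, -30.0, False))
        oid += 1
    return [scored_frame(rows1), scored_frame(rows2)]


def exhaustive_sst_fdr(replicates, t_max=100):
    best_t, best = 0, np.inf
    for t in range(t_max + 1):
        sets = [significant_set(df, t) for df in replicates]
        val = 1.0 if not any(sets) else replicate_fdr(sets)
        if val < best - 1e-12:
            best, best_t = val, t
    return best_t, best


class TestSstMinimisingFdr:
    def test_both_optimisers_find_the_plateau(self):
        reps = _replicates_with_plateau()
        t_star, fdr_star = exhaustive_sst_fdr(reps)
        assert t_star == 8 and fdr_star == 0.0  # plateau is [7.8, 9.5)
        for optimiser in ("quasi_newton", "simplex"):
            t, fdr = sst_minimising_fdr(reps, optimiser, init=5.0)
            assert t in (8, 9)
            assert fdr == 0.0

    def test_identical_replicates_stay_near_init(self):
        rows = [(1, 100 + i, float(s), -20.0, False)
                for i, s in enumerate([1, 3, 8, 20, 40])]
        reps = [scored_frame(rows), scored_frame(rows)]
        for optimiser in ("quasi_newton", "simplex"):
            t, fdr = sst_minimising_fdr(reps, optimiser, init=5.0)
            assert fdr == 0.0
            assert abs(t - 5) <= 1

    def test_optimisers_may_disagree_but_both_report(self):
        # a distant zero plateau beyond a flat stretch: the simplex may leap
        # to it while the quasi-Newton method stalls on the flat; both must
        # return a valid (threshold, fdr) pair, not necessarily equal
        reps = _replicates_with_plateau()
        results = {
            opt: sst_minimising_fdr(reps, opt, init=2.0)
            for opt in ("quasi_newton", "simplex")
        }
        for t, fdr in results.values():
            assert isinstance(t, int) and 0 <= t <= 10_000
            assert 0.0 <= fdr <= 1.0

    def test_threshold_monotonicity_of_significant_sets(self):
        reps = _replicates_with_plateau()
        prev = significant_set(reps[0], 0)
        for t in range(1, 30):
            cur = significant_set(reps[0], t)
            assert cur <= prev
            prev = cur
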