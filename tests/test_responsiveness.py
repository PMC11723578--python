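"""Circular-shift permutation test: statistics, null repository, p-values.

The brute-force oracle re-implements ranking and shifting with explicit
Python loops and naive O(n^2) midranks, sharing only the seeded draw
order with the production code.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import calshift as cs
from calshift.errors import DataError
from calshift.responsiveness import (
    default_trial_count_cutoff,
    null_calibrated_cutoff,
    observed_statistics,
)

# ---------------------------------------------------------------------- oracle

def naive_midranks(values):
    """O(n^2) midranks: 1 + #less + (#equal - 1)/2."""
    out = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def naive_wrst(pre, post):
    pooled = list(pre) + list(post)
    ranks = naive_midranks(pooled)
    return sum(ranks[len(pre):])


def naive_shift(trace, s):
    return list(trace[s:]) + list(trace[:s])


def small_session(n_neurons=20, n_trials=3, n_tp=60, seed=5):
    """Short-span session for O(n^2) oracle work (6 s trials at 10 Hz)."""
    rng = np.random.default_rng(seed)
    return cs.SessionRecording(
        session_id="small", paradigm="baseline",
        traces=rng.normal(0, 1, (n_neurons, n_trials, n_tp)),
        neuron_ids=[f"n{i}" for i in range(n_neurons)],
        events=cs.EventSchedule(cs_onset_s=0.0, cs_offset_s=1.0, us_onset_s=2.0),
        trial_time_origin=3.0,
    )


SMALL_WINDOWS = cs.AnalysisWindows(
    stimulus="cs",
    isolation_window_s=(-3.0, 3.0),
    pre_window_s=(-2.0, 0.0),
    post_window_s=(0.0, 2.0),
)


# ---------------------------------------------------------------- basic ops

class TestCircularShift:
    def test_definition(self):
        assert list(cs.circular_shift([1, 2, 3, 4, 5], 2)) == [3, 4, 5, 1, 2]

    def test_full_shift_is_identity(self):
        assert list(cs.circular_shift([1, 2, 3, 4, 5], 5)) == [1, 2, 3, 4, 5]

    @pytest.mark.parametrize("s", [0, 6, -1])
    def test_out_of_range_shift_raises(self, s):
        with pytest.raises(DataError):
            cs.circular_shift([1, 2, 3, 4, 5], s)

    def test_composition_matches_modular_arithmetic(self):
        # shifting by s1 then s2 equals a single shift by ((s1+s2-1) mod N)+1
        for n in range(2, 9):
            trace = np.arange(n, dtype=float)
            for s1 in range(1, n + 1):
                for s2 in range(1, n + 1):
                    two = cs.circular_shift(cs.circular_shift(trace, s1), s2)
                    one = cs.circular_shift(trace, ((s1 + s2 - 1) % n) + 1)
                    assert list(two) == list(one)

    @given(st.lists(st.floats(allow_nan=False, allow_infinity=False,
                              width=32), min_size=1, max_size=40),
           st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_preserves_multiset_and_length(self, values, data):
        s = data.draw(st.integers(min_value=1, max_value=len(values)))
        shifted = cs.circular_shift(np.array(values), s)
        assert len(shifted) == len(values)
        assert sorted(shifted) == sorted(values)


class TestWrstStatistic:
    @pytest.mark.parametrize("pre,post,expected", [
        ([1, 2, 3], [4, 5, 6], 15.0),   # post takes ranks 4+5+6
        ([4, 5, 6], [1, 2, 3], 6.0),    # post takes ranks 1+2+3
        ([1, 1], [1, 1], 5.0),          # all midranks 2.5
    ])
    def test_examples(self, pre, post, expected):
        assert cs.wrst_statistic(pre, post) == expected

    def test_empty_input_raises(self):
        with pytest.raises(DataError):
            cs.wrst_statistic([], [1.0])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=15),
           st.lists(st.floats(-100, 100), min_size=1, max_size=15))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rank_conservation(self, pre, post):
        t = len(pre) + len(post)
        total = cs.wrst_statistic(pre, post) + cs.wrst_statistic(post, pre)
        assert total == pytest.approx(t * (t + 1) / 2)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        pre, post = rng.normal(size=12), rng.normal(size=9)
        w = cs.wrst_statistic(pre, post)
        for f in (np.exp, np.arctan, lambda x: x ** 3):
            assert cs.wrst_statistic(f(pre), f(post)) == w

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            pre = rng.integers(0, 5, size=rng.integers(1, 12)).astype(float)
            post = rng.integers(0, 5, size=rng.integers(1, 12)).astype(float)
            assert cs.wrst_statistic(pre, post) == pytest.approx(
                naive_wrst(pre, post))


class TestObservedStatistic:
    def test_constant_neuron_gives_all_midrank_value(self, tiny_session):
        w = cs.AnalysisWindows.for_stimulus("cs")
        n_pre, n_post, n_trials = 200, 100, 2
        expected = n_trials * n_post * (n_pre + n_post + 1) / 2
        assert cs.observed_statistic(tiny_session, "a", w) == expected

    def test_single_trial_reduces_to_wrst(self):
        s = small_session(n_neurons=2, n_trials=1)
        idx_pre, idx_post = slice(10, 30), slice(30, 50)
        direct = cs.wrst_statistic(s.traces[0, 0, idx_pre], s.traces[0, 0, idx_post])
        assert cs.observed_statistic(s, "n0", SMALL_WINDOWS) == direct

    def test_matches_per_trial_brute_force(self):
        s = small_session()
        for nid in s.neuron_ids[:5]:
            i = s.neuron_index(nid)
            expected = sum(
                naive_wrst(s.traces[i, j, 10:30], s.traces[i, j, 30:50])
                for j in range(s.n_trials)
            )
            assert cs.observed_statistic(s, nid, SMALL_WINDOWS) == pytest.approx(expected)

    def test_vectorized_matches_scalar(self):
        s = small_session()
        vec = observed_statistics(s, SMALL_WINDOWS)
        for i, nid in enumerate(s.neuron_ids):
            assert vec[i] == cs.observed_statistic(s, nid, SMALL_WINDOWS)


class TestNullRepository:
    def test_constant_session_gives_constant_null(self):
        s = cs.SessionRecording(
            "const", "baseline", np.ones((4, 3, 60)),
            [f"n{i}" for i in range(4)],
            events=cs.EventSchedule(0.0, 1.0, 2.0), trial_time_origin=3.0,
        )
        repo = cs.build_null_repository(s, SMALL_WINDOWS, B=25, seed=0)
        all_midrank = 3 * 20 * (20 + 20 + 1) / 2
        assert np.all(repo.stats == all_midrank)

    def test_fixed_seed_reproduces(self):
        s = small_session()
        r1 = cs.build_null_repository(s, SMALL_WINDOWS, B=40, seed=9)
        r2 = cs.build_null_repository(s, SMALL_WINDOWS, B=40, seed=9)
        assert np.array_equal(r1.stats, r2.stats)

    def test_empty_session_raises(self):
        empty = cs.SessionRecording(
            "e", "baseline", np.zeros((0, 3, 60)), [],
            events=cs.EventSchedule(0.0, 1.0, 2.0), trial_time_origin=3.0,
        )
        with pytest.raises(DataError):
            cs.build_null_repository(empty, SMALL_WINDOWS, B=10, seed=0)

    def test_bit_exact_against_brute_force_oracle(self):
        """Shared seed stream, independent loops/ranking: bit-exact match."""
        s = small_session(n_neurons=20, n_trials=3, n_tp=60, seed=12)
        B = 30
        repo = cs.build_null_repository(s, SMALL_WINDOWS, B=B, seed=77)
        rng = np.random.default_rng(77)   # documented order: b-major, trial-minor
        n = 60
        expected = []
        for _ in range(B):
            i = int(rng.integers(0, s.n_neurons))
            shifts = rng.integers(1, n + 1, size=s.n_trials)
            w_b = 0.0
            for j, sh in enumerate(shifts):
                iso = list(s.traces[i, j, 0:60])
                shifted = naive_shift(iso, int(sh))
                w_b += naive_wrst(shifted[10:30], shifted[30:50])
            expected.append(w_b)
        np.testing.assert_array_equal(repo.stats, np.array(expected))


class TestEmpiricalPValue:
    def _repo(self, stats_arr):
        return cs.NullRepository(
            stats=np.asarray(stats_arr, dtype=float),
            windows=SMALL_WINDOWS, session_id="x", rng_seed=None,
        )

    def test_worked_example_ten_of_five_hundred(self):
        # 10 of B=500 null statistics >= W_obs
        repo = self._repo(np.concatenate([np.full(490, -1.0), np.full(10, 2.0)]))
        p_plus, p_minus, p_two, direction = cs.empirical_pvalue(1.0, repo)
        assert p_plus == pytest.approx(11 / 501)
        assert round(p_plus, 3) == 0.022
        assert round(p_two, 3) == 0.044
        assert direction == "excited"

    def test_observed_above_all_nulls(self):
        repo = self._repo(np.zeros(500))
        p_plus, _, p_two, _ = cs.empirical_pvalue(1.0, repo)
        assert p_plus == pytest.approx(1 / 501)
        assert p_two == pytest.approx(2 / 501)

    def test_tail_sum_exceeds_one_by_tie_mass(self):
        rng = np.random.default_rng(1)
        repo = self._repo(rng.integers(0, 5, 200).astype(float))
        for w in [-1.0, 0.0, 2.0, 4.0, 10.0]:
            p_plus, p_minus, _, _ = cs.empirical_pvalue(w, repo)
            assert p_plus + p_minus >= (200 + 2) / (200 + 1) - 1e-12

    def test_heavy_ties_cap_at_one(self):
        repo = self._repo(np.zeros(100))
        _, _, p_two, direction = cs.empirical_pvalue(0.0, repo)
        assert p_two == 1.0 and direction == "none"


class TestPopulationTest:
    def test_all_constant_session_is_never_significant(self):
        s = cs.SessionRecording(
            "const", "baseline", np.ones((5, 3, 60)),
            [f"n{i}" for i in range(5)],
            events=cs.EventSchedule(0.0, 1.0, 2.0), trial_time_origin=3.0,
        )
        res = cs.test_population(s, SMALL_WINDOWS, B=50, seed=4)
        assert (res["label"] == "not_significant").all()
        assert (res["p_two_sided"] == 1.0).all()

    def test_determinism_of_full_pipeline(self):
        s = small_session()
        r1 = cs.test_population(s, SMALL_WINDOWS, B=60, seed=13)
        r2 = cs.test_population(s, SMALL_WINDOWS, B=60, seed=13)
        pd.testing.assert_frame_equal(r1, r2)

    def test_strong_excitation_detected(self):
        # injected post-window offset far above noise on every trial
        rng = np.random.default_rng(6)
        traces = rng.normal(0, 1, (30, 4, 60))
        traces[0, :, 30:50] += 25.0
        s = cs.SessionRecording(
            "exc", "baseline", traces, [f"n{i}" for i in range(30)],
            events=cs.EventSchedule(0.0, 1.0, 2.0), trial_time_origin=3.0,
        )
        res = cs.test_population(s, SMALL_WINDOWS, B=300, seed=2)
        assert res.loc[res["neuron_id"] == "n0", "label"].item() == "excited"

    def test_pvalues_not_anticonservative_on_null(self):
        """p two-sided stochastically >= uniform at resolution 1/(B+1)."""
        s = small_session(n_neurons=60, n_trials=5, seed=30)
        res = cs.test_population(s, SMALL_WINDOWS, B=200, seed=31)
        for q in (0.05, 0.1, 0.25, 0.5):
            frac = (res["p_two_sided"] <= q).mean()
            # allow binomial noise at n=60 (3 sigma)
            assert frac <= q + 3 * np.sqrt(q * (1 - q) / 60)

    def test_power_monotone_in_effect_size(self):
        margins = []
        for effect in (0.5, 2.0, 6.0):
            rng = np.random.default_rng(55)   # shared seed across grid
            traces = rng.normal(0, 1, (25, 5, 60))
            traces[:, :, 30:50] += effect
            s = cs.SessionRecording(
                "g", "baseline", traces, [f"n{i}" for i in range(25)],
                events=cs.EventSchedule(0.0, 1.0, 2.0), trial_time_origin=3.0,
            )
            res = cs.test_population(s, SMALL_WINDOWS, B=150, seed=56)
            margins.append((res["label"] == "excited").mean())
        assert margins[0] <= margins[1] <= margins[2]


class TestSignRank:
    def test_binomial_cutoff_is_smallest_valid_k(self):
        for n, alpha in ((20, 0.05), (10, 0.05), (10, 0.2)):
            k = default_trial_count_cutoff(n, alpha)
            assert sps.binom.sf(k - 1, n, alpha / 2) <= 0.05
            assert sps.binom.sf(k - 2, n, alpha / 2) > 0.05

    def test_all_constant_not_significant(self):
        s = cs.SessionRecording(
            "const", "baseline", np.ones((3, 4, 60)),
            [f"n{i}" for i in range(3)],
            events=cs.EventSchedule(0.0, 1.0, 2.0), trial_time_origin=3.0,
        )
        res = cs.signrank_responsiveness(s, SMALL_WINDOWS)
        assert (res["label"] == "not_significant").all()

    def test_extreme_excitation_found_by_both_methods(self):
        rng = np.random.default_rng(14)
        traces = rng.normal(0, 1, (10, 6, 60))
        traces[3, :, 30:50] += 30.0
        s = cs.SessionRecording(
            "exc", "baseline", traces, [f"n{i}" for i in range(10)],
            events=cs.EventSchedule(0.0, 1.0, 2.0), trial_time_origin=3.0,
        )
        circ = cs.test_population(s, SMALL_WINDOWS, B=200, seed=1)
        sign = cs.signrank_responsiveness(s, SMALL_WINDOWS)
        assert circ.loc[circ["neuron_id"] == "n3", "label"].item() == "excited"
        assert sign.loc[sign["neuron_id"] == "n3", "label"].item() == "excited"

    def test_null_calibrated_cutoff_controls_fpr(self):
        null = small_session(n_neurons=80, n_trials=6, seed=41)
        k = null_calibrated_cutoff(null, SMALL_WINDOWS)
        res = cs.signrank_responsiveness(null, SMALL_WINDOWS, trial_count_cutoff=k)
        assert (res["label"] != "not_significant").mean() <= 0.05
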