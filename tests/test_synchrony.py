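"""Quiet-window extraction and max-over-lag correlation, checked against
brute-force oracles (per-millisecond masks; exhaustive lag scans)."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

import synchropipe as sp
from synchropipe.synchrony import LagCorrelation, pair_class


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def quiet_windows_mask_oracle(movements, span_ms, margin_ms, min_window_ms):
    """Per-millisecond boolean mask: blocked = movement plus margin on each side."""
    blocked = np.zeros(span_ms, dtype=bool)
    for on, off in movements:
        lo = max(int(on - margin_ms), 0)
        hi = min(int(off + margin_ms), span_ms)
        blocked[lo:hi] = True
    windows = []
    start = None
    for i, b in enumerate(blocked):
        if not b and start is None:
            start = i
        elif b and start is not None:
            windows.append((start, i))
            start = None
    if start is not None:
        windows.append((start, span_ms))
    return [(a, b) for a, b in windows if b - a >= min_window_ms]


def pearson_oracle(x, y):
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return stats.pearsonr(x, y).statistic


def max_lag_oracle(x, y, max_lag):
    """Exhaustive scan of all lags on a single window, scipy Pearson."""
    best_r, best_lag = -np.inf, 0
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l)):
        n = len(x)
        if n - abs(lag) < 2:
            continue
        if lag >= 0:
            r = pearson_oracle(x[: n - lag], y[lag:])
        else:
            r = pearson_oracle(x[-lag:], y[: n + lag])
        if r > best_r:
            best_r, best_lag = r, lag
    return best_r, best_lag


# ---------------------------------------------------------------------------
# quiet windows
# ---------------------------------------------------------------------------

class TestExtractQuietWindows:
    def test_worked_example(self):
        ep = sp.extract_quiet_windows([(10, 12), (20, 21)], 30, margin_s=1, min_window_s=0)
        assert ep.intervals == ((0, 9), (13, 19), (22, 30))

    def test_no_movements_whole_span(self):
        assert sp.extract_quiet_windows([], 100.0).intervals == ((0.0, 100.0),)

    def test_narrow_gap_dropped(self):
        ep = sp.extract_quiet_windows([(5, 6), (7.5, 9)], 30, margin_s=1, min_window_s=0)
        assert ep.intervals == ((0, 4), (10, 30))

    def test_against_millisecond_mask_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            span = 100_000  # ms
            n_mov = rng.integers(0, 12)
            onsets = np.sort(rng.integers(0, span - 3000, size=n_mov))
            movements = sp.merge_intervals(
                [(int(on), int(on + rng.integers(1, 2500))) for on in onsets]
            )
            got = sp.extract_quiet_windows(movements, span, margin_s=1000, min_window_s=50)
            expected = quiet_windows_mask_oracle(movements, span, 1000, 50)
            assert [(int(a), int(b)) for a, b in got.intervals] == expected

    def test_total_duration(self):
        ep = sp.extract_quiet_windows([(10, 12)], 30, margin_s=1, min_window_s=0)
        assert ep.total_duration_s == pytest.approx(9 + 17)


class TestBinCounts:
    def test_counting(self):
        ep = sp.EpochSet(((0.0, 1.0),))
        counts = sp.bin_counts(np.array([0.1, 0.6, 0.65]), ep, 0.25)
        assert list(counts[0]) == [1, 0, 2, 0]

    def test_trailing_partial_bin_discarded(self):
        ep = sp.EpochSet(((0.0, 0.9),))
        counts = sp.bin_counts(np.array([0.85]), ep, 0.25)
        assert counts[0].size == 3

    def test_empty_train_zero_vectors(self):
        ep = sp.EpochSet(((0.0, 1.0), (2.0, 3.0)))
        counts = sp.bin_counts(np.array([]), ep, 0.25)
        assert all((c == 0).all() and c.size == 4 for c in counts)


# ---------------------------------------------------------------------------
# max-over-lag correlation
# ---------------------------------------------------------------------------

class TestMaxLagCorrelation:
    def test_identity_pair(self):
        x = np.array([1, 0, 2, 0, 1, 3, 0, 1])
        res = sp.max_lag_correlation([x], [x], 3)
        assert res.r_max == pytest.approx(1.0) and res.lag_bins == 0

    def test_shifted_vector_matches_brute_force(self):
        x = np.array([1, 0, 2, 0, 1, 0, 3, 0])
        y = np.concatenate([[0], x[:-1]])  # x delayed by one bin
        res = sp.max_lag_correlation([x], [y], 3)
        r_exp, lag_exp = max_lag_oracle(x, y, 3)
        assert res.r_max == pytest.approx(r_exp, abs=1e-12)
        assert res.lag_bins == lag_exp

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(300):
            n = int(rng.integers(10, 40))
            x = rng.poisson(1.0, n)
            y = rng.poisson(1.0, n)
            res = sp.max_lag_correlation([x], [y], 3)
            r_exp, lag_exp = max_lag_oracle(x, y, 3)
            assert res.r_max == pytest.approx(r_exp, abs=1e-12)
            assert res.lag_bins == lag_exp

    def test_symmetry_under_exchange(self, rng):
        for _ in range(50):
            x = rng.poisson(1.0, 30)
            y = rng.poisson(1.0, 30)
            assert sp.max_lag_correlation([x], [y], 4).r_max == pytest.approx(
                sp.max_lag_correlation([y], [x], 4).r_max, abs=1e-12
            )

    def test_monotone_in_lag_range(self, rng):
        for _ in range(50):
            x = rng.poisson(1.0, 40)
            y = rng.poisson(1.0, 40)
            r1 = sp.max_lag_correlation([x], [y], 1).r_max
            r2 = sp.max_lag_correlation([x], [y], 4).r_max
            assert r2 >= r1 - 1e-12

    def test_rmax_at_least_lag_zero(self, rng):
        x = rng.poisson(2.0, 100)
        y = rng.poisson(2.0, 100)
        r0 = pearson_oracle(x.astype(float), y.astype(float))
        assert sp.max_lag_correlation([x], [y], 4).r_max >= r0 - 1e-12

    def test_zero_variance_contributes_zero(self):
        x = np.ones(20, dtype=int)
        y = np.arange(20)
        assert sp.max_lag_correlation([x], [y], 2).r_max == 0.0

    def test_shifts_never_cross_windows(self):
        # two windows; y equals x within each window, but the windows differ
        x = [np.array([3, 0, 1, 0]), np.array([0, 2, 0, 2])]
        res = sp.max_lag_correlation(x, x, 1)
        assert res.r_max == pytest.approx(1.0)
        # pooled correlation at lag 1 must only pair bins inside windows
        xs = np.concatenate([w[:-1] for w in x])
        ys = np.concatenate([w[1:] for w in x])
        manual = pearson_oracle(xs.astype(float), ys.astype(float))
        got = sp.max_lag_correlation(x, [w.copy() for w in x], 1)
        assert got.r_max >= manual - 1e-12

    def test_no_usable_window_flagged(self):
        res = sp.max_lag_correlation([np.array([1])], [np.array([2])], 2)
        assert not res.defined and np.isnan(res.r_max)


class TestCorrelationMatrix:
    def _session_from_trains(self, trains, duration, depths=None):
        depths = depths or [100.0] * len(trains)
        ts = [
            sp.SpikeTrain(f"u{i}", t, d, sp.assign_region(d))
            for i, (t, d) in enumerate(zip(trains, depths))
        ]
        return sp.Session("m", "WT", duration, trains=ts)

    def test_identical_trains_offdiag_one(self, rng):
        t = np.sort(rng.uniform(0, 120, 200))
        session = self._session_from_trains([t, t.copy(), t.copy()], 120.0)
        ep = sp.EpochSet(((0.0, 120.0),))
        res = sp.correlation_matrix(session, ep)
        off = res.matrix[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_matrix_symmetric_and_unit_diagonal(self, rng):
        trains = [np.sort(rng.uniform(0, 300, 250)) for _ in range(5)]
        session = self._session_from_trains(trains, 300.0)
        res = sp.correlation_matrix(session, sp.EpochSet(((0.0, 300.0),)))
        assert np.array_equal(res.matrix, res.matrix.T)
        assert np.allclose(np.diag(res.matrix), 1.0)

    def test_entries_equal_pairwise_statistic(self, rng):
        trains = [np.sort(rng.uniform(0, 200, 150)) for _ in range(4)]
        session = self._session_from_trains(trains, 200.0)
        ep = sp.EpochSet(((0.0, 200.0),))
        cfg = sp.SynchronyConfig()
        res = sp.correlation_matrix(session, ep, cfg)
        counts = {u: sp.bin_counts(session.train(u).times, ep, cfg.bin_width_s) for u in res.unit_ids}
        for i, j in combinations(range(len(res.unit_ids)), 2):
            direct = sp.max_lag_correlation(
                counts[res.unit_ids[i]], counts[res.unit_ids[j]], cfg.max_lag_bins
            )
            assert res.matrix[i, j] == pytest.approx(direct.r_max, abs=1e-12)

    def test_sparse_units_excluded(self, rng):
        trains = [np.sort(rng.uniform(0, 300, 200)), np.sort(rng.uniform(0, 300, 200)),
                  np.array([10.0, 20.0])]
        session = self._session_from_trains(trains, 300.0)
        res = sp.correlation_matrix(session, sp.EpochSet(((0.0, 300.0),)))
        assert res.excluded_units == ["u2"] and len(res.unit_ids) == 2


class TestPairClassMeans:
    def test_pair_combinatorics(self, rng):
        trains = [np.sort(rng.uniform(0, 100, 80)) for _ in range(4)]
        depths = [100.0, 200.0, 600.0, 700.0]  # 2x L23, 2x L5
        ts = [
            sp.SpikeTrain(f"u{i}", t, d, sp.assign_region(d))
            for i, (t, d) in enumerate(zip(trains, depths))
        ]
        session = sp.Session("m", "WT", 100.0, trains=ts)
        res = sp.correlation_matrix(session, sp.EpochSet(((0.0, 100.0),)))
        table = sp.pair_class_means(res).set_index("class")
        assert table.loc["L23-L23", "n_pairs"] == 1
        assert table.loc["L23-L5", "n_pairs"] == 4
        assert table.loc["L5-L5", "n_pairs"] == 1
        assert set(table.index) == {"L23-L23", "L23-L5", "L5-L5"}  # others missing

    def test_constant_matrix_means(self):
        ids = ["a", "b", "c"]
        regions = {"a": "L23", "b": "L23", "c": "L5"}
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 1.0)
        res = sp.CorrelationResult(ids, regions, m, np.zeros((3, 3), int))
        table = sp.pair_class_means(res).set_index("class")
        assert np.allclose(table["mean"], 0.5)

    def test_borderline_pairs_never_included(self):
        assert pair_class("L23", "BORDERLINE") is None
        assert pair_class("OUT", "STR") is None
        assert pair_class("STR", "L5") == "L5-STR"


class TestQuietRateDissociation:
    def test_equal_quiet_rates_with_different_correlation(self):
        """PD-like and LID-like configs share quiet-time firing rates by
        construction even though injected intra-layer correlation differs;
        the quiet-epoch restriction makes the rates statistically
        indistinguishable despite movement-locked bumps."""
        rates = {}
        for state in ("PD", "LID"):
            vals = []
            for seed in (3, 4, 5):
                cfg = sp.state_preset(state, seed=seed)
                session, _ = sp.emit_session(cfg)
                span = session.injection_time_s or session.duration_s
                blocked = sp.merge_intervals(
                    session.movements + [(span, session.duration_s)]
                ) if span < session.duration_s else session.movements
                ep = sp.extract_quiet_windows(blocked, session.duration_s, 1.0, 0.05)
                n = sum(
                    int(((tr.times >= a) & (tr.times < b)).sum())
                    for tr in session.trains
                    for a, b in ep.intervals
                )
                vals.append(n / (ep.total_duration_s * len(session.trains)))
            rates[state] = vals
        res = sp.paired_t(rates["PD"], rates["LID"], alternative="two-sided")
        assert res.p > 0.05
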