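"""Ground-truth generator: MIP correlation oracle, response templates,
movement schedules, determinism and closure with the analysis stages."""

import hashlib
import json
from dataclasses import replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pytest
from scipy import integrate, stats

import synchropipe as sp
from synchropipe.synthetic_data import _enforce_deadtime


def mean_pairwise_r(trains, duration, bin_s=0.025, max_lag=4):
    ep = sp.EpochSet(((0.0, duration),))
    counts = [sp.bin_counts(t, ep, bin_s) for t in trains]
    rs = [
        sp.max_lag_correlation(counts[i], counts[j], max_lag).r_max
        for i, j in combinations(range(len(counts)), 2)
    ]
    return float(np.mean(rs))


class TestMIPClosedForm:
    def test_matches_numerical_integration(self):
        # gamma = E[(1 - |D|/b)+], D ~ N(0, 2 sigma^2)
        for p, sig, b in [(0.12, 0.002, 0.025), (0.06, 0.005, 0.025), (0.3, 0.01, 0.05)]:
            s = np.sqrt(2) * sig
            gamma_num = integrate.quad(
                lambda d: (1 - abs(d) / b) * stats.norm.pdf(d, scale=s), -b, b
            )[0]
            assert sp.mip_expected_correlation(p, sig, b) == pytest.approx(
                p * gamma_num, rel=1e-9
            )

    def test_no_jitter_equals_copy_prob(self):
        assert sp.mip_expected_correlation(0.12, 0.0, 0.025) == 0.12

    def test_zero_copy_prob_zero(self):
        assert sp.mip_expected_correlation(0.0, 0.002, 0.025) == 0.0


class TestMIPPopulation:
    def test_independent_trains_uncorrelated(self, rng):
        trains = sp.mip_population(11, 1.0, 0.0, 0.0, 600.0, rng)  # 55 pairs
        ep = sp.EpochSet(((0.0, 600.0),))
        counts = np.array([sp.bin_counts(t, ep, 0.025)[0] for t in trains], float)
        cm = np.corrcoef(counts)
        rs = cm[np.triu_indices(11, 1)]
        se = rs.std(ddof=1) / np.sqrt(rs.size)
        assert abs(rs.mean()) <= 3 * se + 1e-3

    def test_full_copy_no_jitter_identical(self, rng):
        trains = sp.mip_population(3, 2.0, 1.0, 0.0, 100.0, rng)
        assert all(np.array_equal(trains[0], t) for t in trains[1:])
        assert mean_pairwise_r(trains, 100.0) == pytest.approx(1.0)

    def test_rate_conservation(self, rng):
        duration = 600.0
        trains = sp.mip_population(30, 1.0, 0.12, 0.002, duration, rng)
        for t in trains:
            rate = t.size / duration
            se = np.sqrt(1.0 / duration)  # Poisson SE of the rate estimate
            assert abs(rate - 1.0) <= 4 * se

    def test_recovers_closed_form(self, rng):
        trains = sp.mip_population(20, 1.0, 0.12, 0.002, 600.0, rng)
        expected = sp.mip_expected_correlation(0.12, 0.002, 0.025)
        assert mean_pairwise_r(trains, 600.0) == pytest.approx(expected, abs=0.02)

    def test_zero_rate_with_copy_prob_rejected(self, rng):
        with pytest.raises(Exception):
            sp.mip_population(2, 0.0, 0.1, 0.0, 10.0, rng)


class TestResponseTrains:
    def test_none_template_flat(self, rng):
        times, profile = sp.response_train("NONE", 1.0, 700.0, 4300.0, rng)
        # empirical rate in coarse 300 s blocks stays within 3 SE of baseline
        counts, _ = np.histogram(times, bins=np.arange(0, 4301, 300))
        se = np.sqrt(300.0)
        assert np.all(np.abs(counts - 300.0) <= 3 * se)

    def test_suppression_rate_ratio(self):
        from synchropipe.synthetic_data import ResponseTemplates
        tmpl = ResponseTemplates(supp_gain=0.2, supp_onset_s=0.0, supp_duration_s=3600.0)
        rng = np.random.default_rng(8)
        times, _ = sp.response_train("SUPP", 2.0, 700.0, 4300.0, rng, templates=tmpl)
        pre = np.sum(times < 700) / 700.0
        post = np.sum(times >= 700) / 3600.0
        assert post / pre == pytest.approx(0.2, abs=0.05)

    def test_multi_has_requested_bumps(self, rng):
        _, profile = sp.response_train("MULTI", 1.0, 700.0, 4300.0, rng, n_bumps=3)
        peaks = (profile[1:-1] > profile[:-2]) & (profile[1:-1] > profile[2:])
        assert (profile > 4.0).any() and peaks.sum() >= 3


class TestMovementSchedule:
    def test_zero_rate_empty(self, rng):
        assert sp.movement_schedule(600.0, 0.0, 3.0, rng) == []

    def test_intervals_within_span(self, rng):
        ivs = sp.movement_schedule(600.0, 0.05, 3.0, rng)
        assert all(0 <= a < b <= 600.0 for a, b in ivs)

    def test_coverage_matches_poisson_formula(self):
        # expected covered fraction = 1 - exp(-rate * bout_duration)
        duration, rate, bout = 2000.0, 0.02, 5.0
        expected = duration * (1 - np.exp(-rate * bout))
        covered = []
        for seed in range(40):
            ivs = sp.movement_schedule(duration, rate, bout, np.random.default_rng(seed))
            covered.append(sum(b - a for a, b in ivs))
        mc_se = np.std(covered, ddof=1) / np.sqrt(len(covered))
        assert abs(np.mean(covered) - expected) <= 4 * mc_se


class TestEmitSession:
    def _dir_hash(self, path: Path) -> str:
        h = hashlib.sha256()
        for f in sorted(path.rglob("*")):
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
        return h.hexdigest()

    def test_deterministic_bundles(self, tmp_path):
        cfg = sp.state_preset("PD", seed=9)
        sp.emit_session(cfg, tmp_path / "a")
        sp.emit_session(cfg, tmp_path / "b")
        assert self._dir_hash(tmp_path / "a") == self._dir_hash(tmp_path / "b")

    def test_different_seeds_differ(self, tmp_path):
        sp.emit_session(sp.state_preset("PD", seed=1), tmp_path / "a")
        sp.emit_session(sp.state_preset("PD", seed=2), tmp_path / "b")
        assert self._dir_hash(tmp_path / "a") != self._dir_hash(tmp_path / "b")

    def test_ground_truth_consistent_with_bundle(self, tmp_path):
        cfg = sp.state_preset("LID", seed=4)
        session, gt = sp.emit_session(cfg, tmp_path / "b")
        on_disk = json.loads((tmp_path / "b" / "ground_truth.json").read_text())
        assert {u["unit_id"] for u in on_disk["units"]} == set(session.units)
        back = sp.read_session_bundle(tmp_path / "b")
        assert back.injection_time_s == session.injection_time_s

    def test_quiet_rate_conservation(self):
        # with no movement gain and no injection the emitted rate is the
        # configured quiet rate (up to the deadtime's ~0.2% thinning)
        cfg = replace(
            sp.state_preset("PD", seed=6), movement_gain=1.0, bout_rate_hz=0.0
        )
        session, gt = sp.emit_session(cfg)
        for u in gt["units"]:
            tr = session.train(u["unit_id"])
            rate = tr.n_spikes / session.duration_s
            se = np.sqrt(u["quiet_rate_hz"] / session.duration_s)
            assert abs(rate - u["quiet_rate_hz"]) <= 4 * se + 0.01

    def test_pd_vs_lid_ordering_recovered(self):
        """Intra-layer pair-class means recover the PD < LID correlation
        ordering in every seeded replicate, at matched quiet rates."""
        from synchropipe.reports import PipelineConfig, analyze_session

        wins = 0
        seeds = (21, 22, 23)
        for seed in seeds:
            means = {}
            for state in ("PD", "LID"):
                cfg = replace(sp.state_preset(state, seed=seed), injection_time_s=None,
                              duration_s=900.0)
                session, _ = sp.emit_session(cfg)
                tables = analyze_session(session, PipelineConfig())
                pcs = tables["pair_class_summary"].set_index("class")
                means[state] = pcs.loc[["L23-L23", "L5-L5"], "mean"].mean()
            wins += means["LID"] > means["PD"]
        assert wins == len(seeds)


class TestDeadtime:
    def test_enforced_spacing(self):
        times = np.array([0.0, 0.001, 0.004, 0.005, 0.010])
        out = _enforce_deadtime(times, 0.0025)
        assert np.all(np.diff(out) >= 0.0025)
        assert out[0] == 0.0
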