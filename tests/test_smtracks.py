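"""Track filtering, event classification, fits and condition comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from motorquant import (
    classify_events,
    compare_conditions,
    filter_tracks,
    gen_trajectories,
    mt_total_length,
    summarize_events,
)
from motorquant.imagedata import BinaryMask, Trajectory, TrajectorySet


def track(track_id, points):
    """points: list of (t, x, y) in s/nm."""
    return Trajectory(track_id, np.array(points, dtype=float))


def tset_of(tracks, duration=60.0, px=100.0):
    return TrajectorySet(list(tracks), movie_duration_s=duration,
                         pixel_size_nm=px)


def displacement_track(track_id, run_nm, duration_s, n=5):
    t = np.linspace(0, duration_s, n)
    x = np.linspace(0, run_nm, n)
    return track(track_id, np.column_stack([t, x, np.zeros(n)]))


class TestFilterTracks:
    def _mask(self):
        v = np.zeros((20, 20), bool)
        v[10, :] = True  # horizontal microtubule at row 10
        return BinaryMask(v)

    def test_short_lifetime_removed(self):
        tr = track("a", [(0.0, 0, 1000), (0.3, 500, 1000)])
        out = filter_tracks(tset_of([tr]), self._mask())
        assert len(out) == 0

    def test_lifetime_at_threshold_kept(self):
        tr = track("a", [(0.0, 0, 1000), (0.5, 500, 1000)])
        out = filter_tracks(tset_of([tr]), self._mask())
        assert len(out) == 1

    def test_off_microtubule_point_removes_track(self):
        tr = track("a", [(0.0, 0, 1000), (1.0, 500, 1500)])  # ends 5 px off
        out = filter_tracks(tset_of([tr]), self._mask(), overlap_tol_px=1)
        assert len(out) == 0

    def test_noiseless_synthetic_tracks_all_retained(self):
        tset, mask, _ = gen_trajectories(
            loc_noise_nm=0.0, mt_length_um=20, duration_min=1,
            landing_rate_per_um_min=3, seed=2)
        survivors = filter_tracks(tset, mask)
        long_enough = [tr for tr in tset if tr.lifetime_s >= 0.5]
        assert len(survivors) == len(long_enough)

    def test_empty_mask_rejected(self):
        tr = track("a", [(0.0, 0, 0), (1.0, 100, 0)])
        with pytest.raises(ValueError):
            filter_tracks(tset_of([tr]), BinaryMask(np.zeros((5, 5), bool)))


class TestClassification:
    @pytest.mark.parametrize("run,dur,expected", [
        (300, 2.0, "motile"),
        (100, 5.0, "immotile"),
        (100, 15.0, "discarded"),  # dwell outside the 2.5-10 s window
        (100, 1.0, "discarded"),
        (250, 5.0, "discarded"),  # exactly at the cutoff
    ])
    def test_forced_rule_table(self, run, dur, expected):
        tr = displacement_track("a", run, dur)
        events = classify_events(tset_of([tr]))
        assert events[0].event_class == expected

    def test_motile_velocity(self):
        events = classify_events(tset_of([displacement_track("a", 300, 2.0)]))
        assert events[0].velocity_nm_s == pytest.approx(150.0)

    def test_out_and_back_run_length_zero(self):
        tr = track("a", [(0.0, 0, 0), (1.0, 1000, 0), (2.0, 0, 0)])
        events = classify_events(tset_of([tr]))
        assert events[0].run_length_nm == pytest.approx(0.0)
        assert events[0].event_class != "motile"

    def test_partition_sums_to_total(self):
        tset, mask, _ = gen_trajectories(seed=6)
        filtered = filter_tracks(tset, mask)
        events = classify_events(filtered)
        counts = {c: sum(e.event_class == c for e in events)
                  for c in ("motile", "immotile", "discarded")}
        assert sum(counts.values()) == len(filtered)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(
        st.tuples(st.floats(-5000, 5000, allow_nan=False),
                  st.floats(-5000, 5000, allow_nan=False)),
        min_size=2, max_size=12))
    def test_run_length_properties_on_arbitrary_paths(self, points):
        """The start-to-end run length ignores intermediate samples and is
        always dominated by the summed path length."""
        samples = np.column_stack([np.arange(len(points), dtype=float),
                                   np.asarray(points)])
        tr = Trajectory("p", samples)
        endpoints = Trajectory("e", samples[[0, -1]]) if len(points) > 2 else tr
        assert tr.start_to_end_nm() == pytest.approx(endpoints.start_to_end_nm())
        assert tr.path_length_nm() >= tr.start_to_end_nm() - 1e-9

    def test_run_length_invariant_to_intermediate_samples(self):
        full = track("a", [(0.0, 0, 0), (0.5, 200, 100), (1.0, 700, 0)])
        sparse = track("a", [(0.0, 0, 0), (1.0, 700, 0)])
        e_full = classify_events(tset_of([full]))[0]
        e_sparse = classify_events(tset_of([sparse]))[0]
        assert e_full.run_length_nm == pytest.approx(e_sparse.run_length_nm)
        # the path-sum always dominates the start-to-end vector
        assert full.path_length_nm() >= full.start_to_end_nm()


class TestMtLength:
    def test_horizontal_bar(self):
        v = np.zeros((20, 120), bool)
        v[10, 5:105] = True  # 100 px long
        L = mt_total_length(BinaryMask(v), pixel_size_nm=100)
        assert 9.9 <= L <= 10.0

    def test_diagonal_bar(self):
        v = np.zeros((120, 120), bool)
        idx = np.arange(5, 105)
        v[idx, idx] = True
        L = mt_total_length(BinaryMask(v), pixel_size_nm=100)
        assert L == pytest.approx(99 * math.sqrt(2) * 0.1, rel=0.01)

    def test_single_pixel_zero_length(self):
        v = np.zeros((10, 10), bool)
        v[5, 5] = True
        assert mt_total_length(BinaryMask(v), 100) == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mt_total_length(BinaryMask(np.zeros((5, 5), bool)), 100)


class TestSummarize:
    def _motile_events(self, runs, duration=2.0):
        tracks = [displacement_track(f"t{i}", r, duration)
                  for i, r in enumerate(runs)]
        return classify_events(tset_of(tracks, duration=600))

    def test_frequency_arithmetic(self):
        events = self._motile_events([1000.0] * 12)
        est = summarize_events(events, mt_length_um=40, duration_min=1.5)
        assert est.freq_motile == pytest.approx(0.2)
        # identity: freq * length * duration = count, exactly
        assert est.freq_motile * 40 * 1.5 == pytest.approx(12)

    def test_cutoff_corrected_exponential_mean(self):
        # observed runs {1250, 2250}: excess mean over the 250 nm cutoff
        # is 1500, the MLE of the underlying exponential mean
        est = summarize_events(self._motile_events([1250.0, 2250.0]), 40, 1.5)
        assert est.mean_run_nm == pytest.approx(1500.0)

    def test_uncorrected_fit_is_sample_mean(self):
        est = summarize_events(self._motile_events([1250.0, 2250.0]), 40, 1.5,
                               cutoff_correction=False)
        assert est.mean_run_nm == pytest.approx(1750.0)

    def test_bootstrap_deterministic_under_seed(self):
        events = self._motile_events(np.linspace(300, 3000, 40))
        a = summarize_events(events, 40, 2, seed=7)
        b = summarize_events(events, 40, 2, seed=7)
        assert a.run_ci95 == b.run_ci95 and a.velocity_ci95 == b.velocity_ci95
        assert a.run_ci95[0] <= a.mean_run_nm <= a.run_ci95[1]

    def test_zero_motile_frequencies_still_reported(self):
        tr = displacement_track("a", 100, 5.0)  # immotile
        est = summarize_events(classify_events(tset_of([tr])), 10, 1)
        assert est.freq_immotile == pytest.approx(0.1)
        assert math.isnan(est.mean_run_nm)

    def test_ci_brackets_point_estimate(self):
        tset, mask, _ = gen_trajectories(landing_rate_per_um_min=5, seed=3)
        events = classify_events(filter_tracks(tset, mask))
        L = mt_total_length(mask, tset.pixel_size_nm)
        est = summarize_events(events, L, 2.0, seed=1)
        assert est.run_ci95[0] <= est.mean_run_nm <= est.run_ci95[1]
        assert est.velocity_ci95[0] <= est.mean_velocity_nm_s <= est.velocity_ci95[1]


def welch_oracle(a, b):
    """Hand-rolled Welch t-test (two-tailed) from the textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * stats.t.sf(abs(t), df)


class TestCompare:
    def test_identical_groups(self):
        comp = compare_conditions([1.0, 2, 3], [1.0, 2, 3],
                                  [1.0, 2, 3], [1.0, 2, 3])
        assert comp.ratio == pytest.approx(1.0)
        assert comp.p_welch == pytest.approx(1.0)
        assert comp.ks_d == 0.0

    def test_ratio_and_welch_match_hand_oracle(self):
        minus = [1.0, 1.2, 0.8]
        plus = [0.1, 0.12, 0.08]
        comp = compare_conditions(minus, plus)
        assert comp.ratio == pytest.approx(0.1)
        assert comp.p_welch == pytest.approx(welch_oracle(plus, minus), rel=1e-10)

    def test_zero_minus_mean_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([0.0, 0.0], [1.0, 2.0])

    def test_synthetic_drug_ratio_recovered(self):
        ratios = []
        for seed in range(3):
            freqs = {}
            for cond, rate in (("minus", 5.0), ("plus", 1.0)):
                per_movie = []
                for rep in range(3):
                    s = 1000 * seed + 10 * rep + (0 if cond == "minus" else 5)
                    tset, mask, _ = gen_trajectories(
                        landing_rate_per_um_min=rate, seed=s)
                    ev = classify_events(filter_tracks(tset, mask))
                    L = mt_total_length(mask, tset.pixel_size_nm)
                    per_movie.append(
                        summarize_events(ev, L, 2.0, n_boot=10).freq_motile)
                freqs[cond] = per_movie
            comp = compare_conditions(freqs["minus"], freqs["plus"])
            ratios.append(comp.ratio)
        assert np.mean(ratios) == pytest.approx(0.2, rel=0.2)
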