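"""Recurrence-plot construction and %REC/%DET/MAXL conventions."""

import numpy as np
import pytest

from phaserqa import (
    RQAParams,
    diagonal_line_lengths,
    distance_matrix,
    embed,
    maxline,
    mdrqa,
    percent_determinism,
    percent_recurrence,
    recurrence_plot,
    region_metrics,
    relative_phase,
)
from phaserqa.phase import TWO_PI, assign_regions
from phaserqa.simulate import archetype_config, simulate_trial

from ._oracles import brute_diagonal_lengths, brute_metrics

from .conftest import make_trial


def circle_points(angles):
    a = np.asarray(angles, dtype=float)
    return np.column_stack([np.cos(a), np.sin(a)])


class TestEmbed:
    def test_unembedded_signal_unchanged(self):
        sig = np.arange(10.0).reshape(5, 2)
        np.testing.assert_array_equal(embed(sig, 1, 1), sig)

    def test_scalar_embedding(self):
        out = embed([1.0, 2.0, 3.0, 4.0], emb=2, delay=1)
        np.testing.assert_array_equal(out, [[1, 2], [2, 3], [3, 4]])

    def test_length_after_embedding(self):
        assert embed(np.arange(5.0), emb=3, delay=2).shape == (1, 3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            embed(np.arange(4.0), emb=3, delay=2)


class TestDistances:
    def test_euclidean_pairs(self):
        d = distance_matrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert d[0, 1] == pytest.approx(np.sqrt(2))
        assert d[0, 0] == 0.0

    def test_chord_length_identity(self):
        # unit-circle points at separation delta are 2*sin(delta/2) apart
        for delta in np.linspace(0.1, np.pi, 12):
            d = distance_matrix(circle_points([0.0, delta]))
            assert d[0, 1] == pytest.approx(2 * np.sin(delta / 2), abs=1e-12)
        assert distance_matrix(circle_points([0.0, np.pi / 3]))[0, 1] == (
            pytest.approx(1.0)
        )

    @pytest.mark.parametrize("norm", ["euclidean", "maximum", "minimum"])
    def test_norm_options_run(self, norm):
        pts = np.random.default_rng(0).normal(size=(20, 2))
        d = distance_matrix(pts, norm)
        assert d.shape == (20, 20)
        assert np.all(d >= 0)


class TestRecurrencePlot:
    def test_constant_series_all_recurrent(self):
        rp = recurrence_plot(np.zeros((6, 6)), radius=1.0)
        assert rp.matrix.all()

    def test_distant_pair_identity_only(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        rp = recurrence_plot(d, radius=1.0)
        np.testing.assert_array_equal(rp.matrix, np.eye(2, dtype=bool))

    def test_circular_continuity_359_vs_1_degree(self):
        # the circular fix: 359 and 1 degree are 2 degrees apart on the
        # circle (chord ~0.0349), recurrent at radius 1, although their
        # naive angular difference is 358 degrees
        angles = np.deg2rad([359.0, 1.0])
        rp = recurrence_plot(distance_matrix(circle_points(angles)), radius=1.0)
        assert rp.matrix.all()
        naive = np.abs(angles[0] - angles[1])
        assert naive > 1.0  # the 1-D distance alone would not recur

    def test_symmetry_and_reflexive_diagonal(self):
        rng = np.random.default_rng(3)
        pts = circle_points(rng.uniform(0, TWO_PI, 30))
        rp = recurrence_plot(distance_matrix(pts), radius=1.0)
        np.testing.assert_array_equal(rp.matrix, rp.matrix.T)
        assert np.diagonal(rp.matrix).all()

    def test_rec_non_decreasing_in_radius(self):
        rng = np.random.default_rng(11)
        d = distance_matrix(circle_points(rng.uniform(0, TWO_PI, 40)))
        recs = [
            percent_recurrence(recurrence_plot(d, r))
            for r in np.linspace(0.05, 2.1, 15)
        ]
        assert all(a <= b for a, b in zip(recs, recs[1:]))


class TestLineStatistics:
    def test_all_ones_4x4_lengths(self):
        rp = recurrence_plot(np.zeros((4, 4)), 1.0)
        assert sorted(diagonal_line_lengths(rp, theiler=1)) == [1, 1, 2, 2, 3, 3]

    def test_identity_plot_has_no_lines(self):
        rp = recurrence_plot(np.where(np.eye(5), 0.0, 9.0), 1.0)
        assert diagonal_line_lengths(rp, theiler=1) == []
        assert maxline([]) == 0

    def test_all_ones_determinism(self):
        rp = recurrence_plot(np.zeros((4, 4)), 1.0)
        lengths = diagonal_line_lengths(rp, theiler=1)
        # (3+3+2+2) points on lines >= 2 out of (3+3+2+2+1+1) off-LOI points
        assert percent_determinism(lengths, lmin=2) == pytest.approx(1000 / 12)

    def test_identity_plot_det_missing(self):
        assert percent_determinism([], lmin=2) is None

    def test_single_long_line_is_fully_deterministic(self):
        assert percent_determinism([5], lmin=2) == 100.0
        assert maxline([5]) == 5

    def test_random_plot_matches_brute_force_scanner(self):
        rng = np.random.default_rng(21)
        mat = rng.random((12, 12)) < 0.4
        mat |= mat.T  # symmetric, like a real recurrence plot
        rp = recurrence_plot(np.where(mat, 0.0, 9.0), 1.0)
        ours = sorted(diagonal_line_lengths(rp, theiler=1))
        oracle = sorted(brute_diagonal_lengths(rp.matrix.astype(int).tolist()))
        assert ours == oracle

    def test_theiler_band_excluded(self):
        rp = recurrence_plot(np.zeros((6, 6)), 1.0)
        assert max(diagonal_line_lengths(rp, theiler=3)) == 3  # offsets >= 3 only


class TestMdrqa:
    def test_in_phase_trial_degenerate_limits(self):
        taps = (np.arange(1, 31) * 0.5).tolist()
        series = relative_phase(make_trial(taps, duration=16.0))
        _, m = mdrqa(series)
        assert m.rec == 100.0
        # all-ones determinism ceiling: the two corner diagonals are
        # single cells below lmin, so det is just under 100
        total = 30 * 30 - 30
        assert m.det == pytest.approx(100.0 * (total - 2) / total)
        assert m.maxl == m.n - 1 == 29

    def test_short_series_metrics_missing(self):
        _, m = mdrqa(circle_points([0.3]))
        assert m.rec is None and m.det is None and m.maxl is None

    def test_linear_ramp_recurrences_form_a_band(self):
        # 0.5 rad/tap: recurrence needs |i-j|*0.5 <= pi/3 => |i-j| <= 2
        psi = np.arange(30) * 0.5
        rp, m = mdrqa(circle_points(psi))
        ii, jj = np.nonzero(rp.matrix)
        band = np.abs(ii - jj)
        # phases also realign every full turn (~12.57 taps is not integer,
        # so only the near-diagonal band recurs within the first turn)
        assert set(band[band <= 3]) == {0, 1, 2}
        rec_o, det_o, maxl_o = brute_metrics(circle_points(psi).tolist())
        assert m.rec == pytest.approx(rec_o)
        assert m.det == pytest.approx(det_o)
        assert m.maxl == maxl_o

    def test_alternating_antiphase_checkerboard(self):
        psi = np.where(np.arange(20) % 2 == 0, 0.0, np.pi)
        rp, m = mdrqa(circle_points(psi))
        expected = (np.add.outer(np.arange(20), np.arange(20)) % 2) == 0
        np.testing.assert_array_equal(rp.matrix, expected)
        rec_o, det_o, maxl_o = brute_metrics(circle_points(psi).tolist())
        assert (m.rec, m.det, m.maxl) == (
            pytest.approx(rec_o),
            pytest.approx(det_o),
            maxl_o,
        )

    def test_angular_criterion_equivalence(self):
        # with defaults, recurrence iff circular |dpsi| <= 2*arcsin(1/2);
        # pairs exactly on the 60-degree boundary are excluded since there
        # the real-valued predicate sits on the float rounding knife-edge
        rng = np.random.default_rng(17)
        psi = rng.uniform(0, TWO_PI, 200)
        rp, _ = mdrqa(circle_points(psi))
        diff = np.abs(psi[:, None] - psi[None, :])
        circ = np.minimum(diff, TWO_PI - diff)
        criterion = 2 * np.arcsin(0.5)
        off_boundary = np.abs(circ - criterion) > 1e-9
        np.testing.assert_array_equal(
            rp.matrix[off_boundary], (circ <= criterion)[off_boundary]
        )

    def test_matches_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(3, 41))
            pts = circle_points(rng.uniform(0, TWO_PI, n))
            _, m = mdrqa(pts)
            rec_o, det_o, maxl_o = brute_metrics(pts.tolist())
            assert m.rec == pytest.approx(rec_o)
            if det_o is None:
                assert m.det is None
            else:
                assert m.det == pytest.approx(det_o)
            assert m.maxl == maxl_o

    def test_det_and_maxl_invariant_to_adding_loi(self):
        rng = np.random.default_rng(5)
        d = distance_matrix(circle_points(rng.uniform(0, TWO_PI, 25)))
        rp = recurrence_plot(d, 1.0)
        no_loi = rp.matrix.copy()
        np.fill_diagonal(no_loi, False)
        rp_no_loi = recurrence_plot(np.where(no_loi, 0.0, 9.0), 1.0)
        l1 = diagonal_line_lengths(rp, theiler=1)
        l2 = diagonal_line_lengths(rp_no_loi, theiler=1)
        assert sorted(l1) == sorted(l2)

    @pytest.mark.parametrize("norm", ["euclidean", "maximum", "minimum"])
    def test_norm_and_zscore_options_do_not_crash(self, norm):
        rng = np.random.default_rng(9)
        pts = circle_points(rng.uniform(0, TWO_PI, 15))
        _, m = mdrqa(pts, RQAParams(norm=norm, zscore=True))
        assert m.n == 15

    def test_embedded_analysis_runs(self):
        rng = np.random.default_rng(2)
        pts = circle_points(rng.uniform(0, TWO_PI, 20))
        rp, m = mdrqa(pts, RQAParams(emb=2, delay=2))
        assert rp.n == m.n == 18

    def test_params_config_round_trip(self, tmp_path):
        path = tmp_path / "params.yaml"
        path.write_text("radius: 0.5\nlmin: 3\n")
        params = RQAParams.from_file(path)
        assert params == RQAParams(radius=0.5, lmin=3)
        bad = tmp_path / "bad.yaml"
        bad.write_text("radius: 0.5\nnot_a_key: 1\n")
        with pytest.raises(ValueError, match="not_a_key"):
            RQAParams.from_file(bad)


class TestRegionMetrics:
    def test_single_region_series_equals_general(self):
        rng = np.random.default_rng(31)
        psi = rng.uniform(np.deg2rad(140), np.deg2rad(220), 25)  # all in r2
        taps = np.arange(1, 26) * 0.5 - psi * 0.5 / TWO_PI
        series = relative_phase(make_trial(np.sort(taps), duration=14.0))
        regions = assign_regions(series.psi_wrapped)
        assert set(regions) == {"r2"}
        per_region = region_metrics(series, regions)
        _, general = mdrqa(series)
        assert per_region["r2"].rec == pytest.approx(general.rec)
        assert per_region["r2"].det == pytest.approx(general.det)
        assert per_region["r2"].maxl == general.maxl
        assert per_region["r1"].is_missing and per_region["r3"].is_missing

    def test_submatrix_equivalence(self):
        # metrics of the extracted subsequence equal metrics of the rows/
        # columns of the full plot at the region's indices
        trial, _ = simulate_trial(archetype_config("successful", 100, seed=8))
        series = relative_phase(trial)
        regions = assign_regions(series.psi_wrapped)
        rp, _ = mdrqa(series)
        per_region = region_metrics(series, regions)
        for label in ("r1", "r2", "r3"):
            idx = np.flatnonzero(regions == label)
            if idx.size < 2:
                continue
            sub = rp.matrix[np.ix_(idx, idx)]
            rec_o = 100.0 * sub.sum() / (idx.size ** 2)
            sub_rp = recurrence_plot(np.where(sub, 0.0, 9.0), 1.0)
            lengths = diagonal_line_lengths(sub_rp, theiler=1)
            got = per_region[label]
            assert got.rec == pytest.approx(rec_o)
            det_o = percent_determinism(lengths)
            if det_o is None:
                assert got.det is None
            else:
                assert got.det == pytest.approx(det_o)
            assert got.maxl == maxline(lengths)

    def test_single_lap_populates_all_regions(self):
        trial, truth = simulate_trial(archetype_config("successful", 110, seed=4))
        series = relative_phase(trial)
        regions = assign_regions(series.psi_wrapped)
        assert truth.lap_count == 1
        counts = {lab: int((regions == lab).sum()) for lab in ("r1", "r2", "r3")}
        assert all(c >= 1 for c in counts.values())
        nonsync = sum(counts.values())
        assert nonsync == int((regions != "sync").sum())

    def test_sparse_region_metrics_missing_not_zero(self):
        psi = np.deg2rad([90.0, 91.0, 180.0])  # r2 has a single tap
        taps = np.arange(1, 4) * 0.5 - psi * 0.5 / TWO_PI
        series = relative_phase(make_trial(taps, duration=3.0))
        per_region = region_metrics(series, assign_regions(series.psi_wrapped))
        assert per_region["r2"].is_missing
        assert per_region["r2"].n == 1
        assert per_region["r2"].rec is None
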