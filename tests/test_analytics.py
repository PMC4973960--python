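import numpy as np
import pytest

from rnum import analytics, codec, fixtures
from rnum.analytics import (
    ResidueTraceMatrix,
    alternation_score,
    class_rcode_matrix,
    density_region,
    motif_landmarks,
    rcode,
    rcode_timeseries,
    residue_trace,
)
from rnum.codec import rama_number


class TestRcode:
    def test_single_value_cluster(self):
        code = rcode([0.355] * 100, normalize=True)
        assert code.counts.sum() == 100
        assert code.counts[35] == 100
        assert code.heights.max() == 1.0
        assert code.peak_center == pytest.approx(0.355)

    def test_conservation(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 1, 1234)
        assert rcode(values).total == 1234

    def test_empty_input(self):
        code = rcode([], normalize=True)
        assert code.total == 0
        assert code.heights is None

    def test_r_equal_one_clamped_into_last_bin(self):
        code = rcode([1.0, 0.999])
        assert code.counts[-1] == 2

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            rcode([-0.1])
        with pytest.raises(ValueError):
            rcode([1.1])

    def test_rejects_bad_bin_width(self):
        with pytest.raises(ValueError):
            rcode([0.5], bin_width=0.03)

    def test_alpha_ensemble_peak_near_closed_form(self):
        spec = fixtures.MotifSpec("alpha", -63.0, -43.0, spread=5.0)
        pairs = fixtures.sample_motif(spec, 10_000, seed=7)
        phi = np.array([p.phi for p in pairs])
        psi = np.array([p.psi for p in pairs])
        code = rcode(rama_number(phi, psi), normalize=True)
        expected = (phi.mean() + psi.mean() + 360.0) / 720.0
        assert abs(code.peak_center - expected) < 0.02
        # single dominant peak: most of the mass sits within 0.03 of it
        near = np.abs(code.centers - code.peak_center) <= 0.03
        assert code.counts[near].sum() > 0.95 * code.total


class TestClassRcodeMatrix:
    def test_identical_classes_identical_columns(self):
        values = np.linspace(0.1, 0.9, 50)
        df = class_rcode_matrix({"a": values, "b": values})
        assert np.array_equal(df["a"].to_numpy(), df["b"].to_numpy())

    def test_columns_peak_normalised(self):
        rng = np.random.default_rng(6)
        df = class_rcode_matrix(
            {"x": rng.uniform(0, 1, 100), "y": rng.uniform(0, 1, 300)}
        )
        assert df["x"].max() == 1.0
        assert df["y"].max() == 1.0

    def test_beta_peaks_above_alpha(self):
        alpha = fixtures.sample_motif(fixtures.motif("alpha", 5.0), 2000, seed=1)
        beta = fixtures.sample_motif(fixtures.motif("beta", 5.0), 2000, seed=2)
        groups = {
            name: rama_number([p.phi for p in ps], [p.psi for p in ps])
            for name, ps in [("all-alpha", alpha), ("all-beta", beta)]
        }
        df = class_rcode_matrix(groups)
        assert df["all-beta"].idxmax() > df["all-alpha"].idxmax()

    def test_empty_class_warns_zero_column(self):
        with pytest.warns(UserWarning, match="no residues"):
            df = class_rcode_matrix({"full": [0.4, 0.4], "empty": []})
        assert (df["empty"] == 0).all()

    def test_rejects_no_classes(self):
        with pytest.raises(ValueError):
            class_rcode_matrix({})


class TestResidueTrace:
    def test_single_model(self):
        frame = [(-63.0, -43.0), (-135.0, 135.0)]
        trace = residue_trace([frame])
        assert trace.values.shape == (2, 1)
        assert trace.values[0, 0] == pytest.approx(254.0 / 720.0, abs=1e-6)

    def test_sigma_chain_alternates_mirrored(self):
        state = (-70.0, -20.0)
        chain = fixtures.make_sigma_chain(state, 9, noise_sd=0.0)
        trace = residue_trace([chain])
        r0 = rama_number(*state)
        col = trace.values[:, 0]
        assert np.allclose(col[::2], r0, atol=1e-6)
        assert np.allclose(col[1::2], 1.0 - r0, atol=1e-6)

    def test_constant_chain_constant_trace(self):
        trace = residue_trace([fixtures.constant_chain((-63, -43), 7)])
        assert np.ptp(trace.values) == 0.0

    def test_undefined_propagates(self):
        from rnum.io import DihedralRecord

        recs = [
            DihedralRecord("A", 1, "", "GLY", None, -43.0),
            DihedralRecord("A", 2, "", "GLY", -63.0, -43.0),
        ]
        trace = residue_trace([recs])
        assert np.isnan(trace.values[0, 0])
        assert np.isfinite(trace.values[1, 0])

    def test_mismatched_frames_rejected(self):
        with pytest.raises(ValueError, match="conformers"):
            residue_trace([[(-60, -40)] * 3, [(-60, -40)] * 4])


class TestRcodeTimeseries:
    def test_single_window_equals_global(self):
        rng = np.random.default_rng(8)
        trace = ResidueTraceMatrix(values=rng.uniform(0, 1, (6, 10)))
        (code,) = rcode_timeseries(trace, frame_bin=10)
        assert code.total == 60
        assert np.array_equal(code.counts, rcode(trace.values.ravel()).counts)

    def test_counts_conserved_per_window(self):
        rng = np.random.default_rng(9)
        trace = ResidueTraceMatrix(values=rng.uniform(0, 1, (5, 12)))
        codes = rcode_timeseries(trace, frame_bin=4)
        assert [c.total for c in codes] == [20, 20, 20]

    def test_trailing_partial_window_kept(self):
        trace = ResidueTraceMatrix(values=np.full((3, 7), 0.5))
        codes = rcode_timeseries(trace, frame_bin=3)
        assert [c.total for c in codes] == [9, 9, 3]

    def test_switch_detected(self):
        state = (-65.0, -25.0)
        frames = fixtures.make_trajectory(
            lambda rng: fixtures.constant_chain(state, 12),
            n_frames=8,
            seed=3,
            switch_frame=4,
            frame_fn_after=lambda rng: fixtures.make_sigma_chain(state, 12, 0.0, rng),
        )
        trace = residue_trace(frames)
        codes = rcode_timeseries(trace, frame_bin=1)
        n_peaks = [int((c.counts > 0).sum()) for c in codes]
        assert n_peaks[:4] == [1, 1, 1, 1]
        assert n_peaks[4:] == [2, 2, 2, 2]

    def test_rejects_bad_frame_bin(self):
        trace = ResidueTraceMatrix(values=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            rcode_timeseries(trace, frame_bin=0)


class TestAlternationScore:
    def test_perfect_alternation(self):
        r0 = 0.3
        seq = [r0 if i % 2 == 0 else 1 - r0 for i in range(10)]
        assert alternation_score(seq) == 1.0

    def test_constant(self):
        assert alternation_score([0.4] * 8) == 0.0

    def test_monotone_ramp(self):
        assert alternation_score(np.arange(0.1, 1.0, 0.1)) == 0.0

    def test_small_wiggle_below_threshold(self):
        seq = [0.4, 0.41, 0.4, 0.41, 0.4]
        assert alternation_score(seq, delta=0.05) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            alternation_score([0.1, 0.9])
        with pytest.raises(ValueError):
            alternation_score([0.1, np.nan, 0.9, np.nan, 0.2])


class TestDensityRegion:
    def _cloud(self, n=500, seed=10):
        rng = np.random.default_rng(seed)
        return -63 + 8 * rng.standard_normal(n), -43 + 8 * rng.standard_normal(n)

    def test_mass_one_returns_all_occupied(self):
        phi, psi = self._cloud()
        region = density_region(phi, psi, mass=1.0)
        counts, _, _ = np.histogram2d(
            phi, psi, bins=[region.phi_edges, region.psi_edges]
        )
        assert set(region.cells) == {tuple(ij) for ij in np.argwhere(counts > 0)}

    def test_recount_reaches_requested_mass(self):
        phi, psi = self._cloud()
        region = density_region(phi, psi, mass=0.7)
        counts, _, _ = np.histogram2d(phi, psi, bins=[region.phi_edges, region.psi_edges])
        assert counts[region.mask].sum() / counts.sum() >= 0.7
        assert region.contained_fraction >= 0.7

    def test_monotone_in_mass(self):
        phi, psi = self._cloud()
        n70 = len(density_region(phi, psi, mass=0.7).cells)
        n90 = len(density_region(phi, psi, mass=0.9).cells)
        assert n70 <= n90

    def test_rejects_small_sample_and_bad_mass(self):
        with pytest.raises(ValueError):
            density_region([0.0] * 5, [0.0] * 5)
        phi, psi = self._cloud()
        with pytest.raises(ValueError):
            density_region(phi, psi, mass=0.0)


class TestMotifLandmarks:
    def test_paper_landmark_values(self):
        by_name = {m.name: m for m in motif_landmarks()}
        assert by_name["alpha"].r_center == pytest.approx(0.36)
        assert by_name["beta"].r_center == pytest.approx(0.52)
        assert by_name["loop"].r_center == pytest.approx(0.62)

    def test_derived_landmarks_match_centers(self):
        by_name = {m.name: m for m in motif_landmarks()}
        for name in ("ppII", "alphaL"):
            m = by_name[name]
            assert m.r_center == pytest.approx(rama_number(*m.phi_psi_center), abs=1e-5)

    def test_sigma_states_mirror_about_half(self):
        marks = motif_landmarks(sigma_state=codec.DihedralPair(-70.0, -20.0))
        by_name = {m.name: m for m in marks}
        s1, s2 = by_name["sigma_state_1"], by_name["sigma_state_2"]
        assert s1.r_center + s2.r_center == pytest.approx(1.0, abs=1e-5)

    def test_ordering_along_r(self):
        by_name = {m.name: m for m in motif_landmarks()}
        assert by_name["alpha"].r_center < by_name["beta"].r_center < by_name["loop"].r_center


def test_plot_helpers_smoke(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    code = rcode(np.random.default_rng(1).uniform(0, 1, 100), normalize=True)
    ax = analytics.plot_rcode(code)
    trace = ResidueTraceMatrix(values=np.random.default_rng(2).uniform(0, 1, (4, 5)))
    analytics.plot_trace_heatmap(trace)
    ax.figure.savefig(tmp_path / "x.png")
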