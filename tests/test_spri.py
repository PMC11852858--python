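"""Sensorgram I/O, response extraction, control subtraction, plasmon QC."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from evchip.errors import ConfigurationError, FormatError, QCError, StatisticsError, WindowError
from evchip.simulate import BindingParams, LigandBinding, SynthConfig, simulate_sensorgram
from evchip.spri import (
    PlasmonCurve,
    ROIResponse,
    Sensorgram,
    aggregate_ligand,
    extract_response,
    ligand_response_table,
    plasmon_shift,
    read_sensorgram,
    specificity_ratio,
    subtract_negative_control,
    write_sensorgram,
)

NOISE_FREE = SynthConfig(seed=0, noise_sd_pct=0.0, drift_pct_per_min=0.0)


def _constant_sg(value=3.0, n_rois=2):
    t = np.arange(0.0, 30.0, 0.5)
    refl = np.full((t.size, n_rois), value)
    return Sensorgram(t, refl, [f"roi{i}" for i in range(n_rois)], 5.0, 20.0)


class TestIO:
    def test_roundtrip(self, tmp_path, small_layout):
        params = BindingParams(
            ligands={"Anti-CD36": LigandBinding(1.0), "Anti-CD44": LigandBinding(0.5)}
        )
        sg, _ = simulate_sensorgram(small_layout, params, SynthConfig(seed=1))
        path = tmp_path / "exp.csv"
        write_sensorgram(sg, path)
        back = read_sensorgram(path, small_layout)
        assert back.roi_ids == sg.roi_ids
        np.testing.assert_allclose(back.reflectivity_pct, sg.reflectivity_pct, rtol=1e-6)
        assert back.injection_start_min == sg.injection_start_min

    def test_missing_roi_column_reported(self, tmp_path, small_layout):
        params = BindingParams(
            ligands={"Anti-CD36": LigandBinding(1.0), "Anti-CD44": LigandBinding(0.5)}
        )
        sg, _ = simulate_sensorgram(small_layout, params, SynthConfig(seed=1))
        path = tmp_path / "exp.csv"
        write_sensorgram(sg, path)
        text = path.read_text().splitlines()
        cols = text[0].split(",")
        drop = cols.index("r00c00")
        trimmed = "\n".join(
            ",".join(v for i, v in enumerate(line.split(",")) if i != drop)
            for line in text
        )
        path.write_text(trimmed)
        with pytest.raises(FormatError, match="r00c00"):
            read_sensorgram(path, small_layout)

    def test_non_monotonic_time_rejected(self):
        t = np.array([0.0, 1.0, 0.5, 2.0, 25.0])
        with pytest.raises(FormatError, match="increasing"):
            Sensorgram(t, np.zeros((5, 1)), ["a"], 1.0, 20.0)

    def test_missing_manifest_rejected(self, tmp_path):
        path = tmp_path / "exp.csv"
        path.write_text("time_min,a\n0,0\n")
        with pytest.raises(FormatError, match="manifest"):
            read_sensorgram(path)


class TestExtraction:
    def test_constant_trace_gives_zero_response(self):
        responses = extract_response(_constant_sg(3.0))
        assert all(r.raw_response == 0.0 for r in responses)

    def test_noise_free_simulation_recovered_exactly(self, small_layout):
        """Noise- and drift-free simulated responses match the
        generator's ground truth to <= 1e-9 relative error."""
        params = BindingParams(
            ligands={
                "Anti-CD36": LigandBinding(1.2, 0.3, 0.0),
                "Anti-CD44": LigandBinding(0.7, 0.5, 0.05),
            },
            spot_cv=0.1,
            nonspecific_rmax_pct=0.05,
        )
        sg, truth = simulate_sensorgram(small_layout, params, NOISE_FREE)
        got = {r.roi_id: r.raw_response for r in extract_response(sg)}
        for _, row in truth.iterrows():
            assert got[row["roi_id"]] == pytest.approx(
                row["true_response_pct"], rel=1e-9
            )

    @given(offset=st.floats(-50, 50, allow_nan=False))
    def test_shift_invariance(self, offset):
        """Adding a constant to a whole trace leaves the response
        unchanged (end minus start cancels any offset)."""
        sg = _constant_sg(1.0)
        sg_shifted = Sensorgram(
            sg.time_min,
            sg.reflectivity_pct + offset,
            sg.roi_ids,
            sg.injection_start_min,
            sg.injection_end_min,
        )
        base = extract_response(sg)
        shifted = extract_response(sg_shifted)
        for a, b in zip(base, shifted):
            assert b.raw_response == pytest.approx(a.raw_response, abs=1e-9)

    def test_windows_must_respect_injection(self):
        sg = _constant_sg()
        with pytest.raises(WindowError):
            extract_response(sg, baseline_window=(0.0, 6.0))  # overlaps injection
        with pytest.raises(WindowError):
            extract_response(sg, plateau_window=(15.0, 18.0))  # inside injection

    def test_empty_window_rejected(self):
        sg = _constant_sg()
        with pytest.raises(WindowError, match="no samples"):
            extract_response(sg, baseline_window=(4.6, 4.9))


class TestControlSubtraction:
    def test_arithmetic(self, small_layout):
        responses = []
        for r, c, name in sorted(small_layout.spots):
            roi = small_layout.roi_id(r, c)
            raw = 0.1 if name == "Anti-OVA" else 0.5
            responses.append(ROIResponse(roi, raw, 0.0, raw))
        adjusted = subtract_negative_control(responses, small_layout)
        by_id = {a.roi_id: a for a in adjusted}
        for r, c, name in small_layout.spots:
            expected = 0.0 if name == "Anti-OVA" else 0.4
            assert by_id[small_layout.roi_id(r, c)].adjusted_response == pytest.approx(expected)

    def test_control_mean_is_zero_after_adjustment(self, small_layout):
        rng = np.random.default_rng(0)
        responses = [
            ROIResponse(small_layout.roi_id(r, c), float(rng.normal()), 0.0, 0.0)
            for r, c, _ in sorted(small_layout.spots)
        ]
        adjusted = subtract_negative_control(responses, small_layout)
        control_ids = {
            small_layout.roi_id(r, c)
            for r, c, name in small_layout.spots
            if name == "Anti-OVA"
        }
        vals = [a.adjusted_response for a in adjusted if a.roi_id in control_ids]
        assert np.mean(vals) == pytest.approx(0.0, abs=1e-12)

    def test_all_equal_responses_adjust_to_zero(self, small_layout):
        responses = [
            ROIResponse(small_layout.roi_id(r, c), 0.7, 0.0, 0.7)
            for r, c, _ in sorted(small_layout.spots)
        ]
        adjusted = subtract_negative_control(responses, small_layout)
        assert all(a.adjusted_response == pytest.approx(0.0) for a in adjusted)


class TestAggregation:
    def test_mean_and_sample_sd(self, small_layout):
        cd36 = [
            small_layout.roi_id(r, c)
            for r, c, name in sorted(small_layout.spots)
            if name == "Anti-CD36"
        ]
        vals = [0.8, 1.0, 1.2, 1.0, 1.0]
        responses = [
            ROIResponse(roi, v, 0.0, v, adjusted_response=v)
            for roi, v in zip(cd36, vals)
        ]
        lr = aggregate_ligand(responses, small_layout, "Anti-CD36")
        assert lr.mean_response == pytest.approx(1.0)
        assert lr.sd_response == pytest.approx(np.std(vals, ddof=1))
        assert lr.n_spots == 5

    def test_hand_computed_sample_sd(self, small_layout):
        cd36 = [
            small_layout.roi_id(r, c)
            for r, c, name in sorted(small_layout.spots)
            if name == "Anti-CD36"
        ][:3]
        responses = [
            ROIResponse(roi, v, 0.0, v, adjusted_response=v)
            for roi, v in zip(cd36, [0.8, 1.0, 1.2])
        ]
        lr = aggregate_ligand(responses, small_layout, "Anti-CD36")
        assert lr.mean_response == pytest.approx(1.0)
        assert lr.sd_response == pytest.approx(0.2)
        assert lr.n_spots == 3

    def test_single_roi_logs_and_reports_zero_sd(self, small_layout, caplog):
        roi = next(
            small_layout.roi_id(r, c)
            for r, c, name in sorted(small_layout.spots)
            if name == "Anti-CD36"
        )
        with caplog.at_level("WARNING"):
            lr = aggregate_ligand(
                [ROIResponse(roi, 1.0, 0.0, 1.0, 1.0)], small_layout, "Anti-CD36"
            )
        assert lr.sd_response == 0.0
        assert "single ROI" in caplog.text

    def test_table_mean_equals_roi_mean(self, small_layout):
        """Aggregation consistency through the full per-experiment chain."""
        params = BindingParams(
            ligands={"Anti-CD36": LigandBinding(1.0), "Anti-CD44": LigandBinding(0.5)},
            spot_cv=0.1,
        )
        sg, _ = simulate_sensorgram(small_layout, params, SynthConfig(seed=4))
        responses = subtract_negative_control(
            extract_response(sg), small_layout
        )
        table = ligand_response_table(sg, small_layout).set_index("ligand")
        cd36_ids = {
            small_layout.roi_id(r, c)
            for r, c, name in small_layout.spots
            if name == "Anti-CD36"
        }
        manual = np.mean(
            [r.adjusted_response for r in responses if r.roi_id in cd36_ids]
        )
        assert table.loc["Anti-CD36", "mean_response_pct"] == pytest.approx(manual)


class TestPlasmon:
    @staticmethod
    def _parabola(center, angles):
        return PlasmonCurve(angles, 10.0 + 4.0 * (angles - center) ** 2, "roi")

    def test_identical_curves_zero_shift(self):
        angles = np.linspace(60, 64, 200)
        c = self._parabola(62.0, angles)
        assert plasmon_shift(c, c) == pytest.approx(0.0, abs=1e-9)

    def test_known_parabola_shift(self):
        angles = np.linspace(60, 64, 200)
        before = self._parabola(61.8, angles)
        after = self._parabola(61.95, angles)
        assert plasmon_shift(before, after) == pytest.approx(0.15, abs=1e-6)

    def test_monotonic_curve_is_qc_error(self):
        angles = np.linspace(60, 64, 50)
        mono = PlasmonCurve(angles, angles * 2.0, "roi")
        with pytest.raises(QCError, match="edge"):
            plasmon_shift(mono, mono)


class TestSpecificity:
    def test_percent_difference(self):
        assert specificity_ratio(3.0, 1.0) == pytest.approx(200.0)
        assert specificity_ratio(1.0, 1.0) == pytest.approx(0.0)

    def test_nonpositive_control_errors(self):
        with pytest.raises(StatisticsError):
            specificity_ratio(1.0, 0.0)
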