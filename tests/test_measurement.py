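"""Measurement and parameter-estimation tests: image moments, regression
recovery, and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from skimage import draw as skdraw

from lilymorph import (
    EstimatedParams,
    FlowerParams,
    MeasurementTable,
    estimate_params,
    measure_organ_sheet,
    read_measurement_csv,
    summarize_measurements,
    synth_measurement_table,
    write_measurement_csv,
)
from lilymorph.measurement import PARAM_COLUMNS
from lilymorph.synthetic import REFERENCE_CLASS_STATS, NoiseModel


def make_table(lengths_t, lengths_l, r_b=10.0, **kwargs):
    organs = pd.DataFrame(
        {
            "organ_index": np.arange(len(lengths_t)),
            "transverse_mm": lengths_t,
            "longitudinal_mm": lengths_l,
        }
    )
    return MeasurementTable(flower_id="t", organs=organs, r_b=r_b, **kwargs)


class TestEstimateParams:
    def test_noiseless_round_trip_is_exact(self, defaults):
        table = synth_measurement_table(defaults, NoiseModel(0.0))
        _, est = estimate_params(table, tepal_count=20)
        assert est.x_0 == pytest.approx(defaults.x_0, rel=1e-9)
        assert est.y_0 == pytest.approx(defaults.y_0, rel=1e-9)
        assert est.s_x1 == pytest.approx(defaults.s_x1, rel=1e-9)
        assert est.s_y1 == pytest.approx(defaults.s_y1, rel=1e-9)

    def test_scale_invariance(self, defaults):
        table = synth_measurement_table(defaults, NoiseModel(0.0), r_b_mm=10.0)
        scaled = synth_measurement_table(defaults, NoiseModel(0.0), r_b_mm=73.0)
        _, a = estimate_params(table, tepal_count=20)
        _, b = estimate_params(scaled, tepal_count=20)
        assert a.to_dict() == pytest.approx(b.to_dict(), rel=1e-9)

    def test_constant_lengths_give_zero_slope(self):
        fit, est = estimate_params(make_table([8.0] * 10, [20.0] * 10))
        assert est.s_x1 == 0.0 and est.s_y1 == 0.0
        assert fit.r2_x == 1.0
        assert est.x_0 == pytest.approx(0.4)  # 8 mm full / (2 * r_b)

    def test_full_length_convention(self, defaults):
        """Full-length regression halves intercepts but not slopes."""
        table = synth_measurement_table(defaults, NoiseModel(0.0))
        _, semi = estimate_params(table, tepal_count=20, convention="semi")
        _, full = estimate_params(table, tepal_count=20, convention="full")
        assert full.x_0 == pytest.approx(semi.x_0, rel=1e-9)
        assert full.y_0 == pytest.approx(semi.y_0, rel=1e-9)
        assert full.s_x1 == pytest.approx(2 * semi.s_x1, rel=1e-9)
        assert full.s_y1 == pytest.approx(2 * semi.s_y1, rel=1e-9)

    def test_shortening_rates_reported_as_magnitudes(self):
        growing = make_table(np.linspace(5, 10, 8), np.linspace(10, 30, 8))
        _, est = estimate_params(growing)
        assert est.s_x1 > 0 and est.s_y1 > 0

    def test_requires_positive_ovary_radius(self, defaults):
        table = synth_measurement_table(defaults, NoiseModel(0.0))
        table.r_b = float("nan")
        with pytest.raises(ValueError, match="ovary radius"):
            estimate_params(table)
        with pytest.raises(ValueError, match="ovary radius"):
            estimate_params(table, r_b=-1.0)

    def test_requires_three_organs_in_range(self):
        with pytest.raises(ValueError, match="at least 3"):
            estimate_params(make_table([5.0, 4.0], [9.0, 8.0]))

    def test_monte_carlo_recovery_under_noise(self, rng):
        """Mean estimates over replicates stay within 2 SE of the truth."""
        truth = FlowerParams(n=20, t_x=1.0, t_y=1.0)
        reps = []
        for _ in range(200):
            table = synth_measurement_table(truth, NoiseModel(0.05), rng=rng)
            _, est = estimate_params(table)
            reps.append(est.to_dict())
        frame = pd.DataFrame(reps)
        for name in ("x_0", "y_0", "s_x1", "s_y1"):
            bias = frame[name].mean() - getattr(truth, name)
            se = frame[name].std(ddof=1) / np.sqrt(len(frame))
            assert abs(bias) < 2 * se, f"{name}: bias {bias} vs SE {se}"


class TestMeasureOrganSheet:
    def test_single_circle_recovers_diameter(self):
        image = np.zeros((200, 200), dtype=np.uint8)
        rr, cc = skdraw.disk((100, 100), 50)
        image[rr, cc] = 255
        table = measure_organ_sheet(image, scale=0.1)
        assert table.n == 1
        assert table.organs["longitudinal_mm"][0] == pytest.approx(10.0, rel=0.02)
        assert table.organs["transverse_mm"][0] == pytest.approx(10.0, rel=0.02)

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError, match="no organs"):
            measure_organ_sheet(np.zeros((100, 100), dtype=np.uint8), scale=0.1)

    def test_min_area_filter_drops_specks(self):
        image = np.zeros((300, 300), dtype=np.uint8)
        rr, cc = skdraw.disk((150, 150), 40)
        image[rr, cc] = 255
        image[10:13, 10:13] = 255  # 9-px speck
        table = measure_organ_sheet(image, scale=0.1, min_area=100)
        assert table.n == 1

    def test_border_touching_component_flagged(self):
        image = np.zeros((200, 400), dtype=np.uint8)
        rr, cc = skdraw.disk((100, 100), 40)
        image[rr, cc] = 255
        rr, cc = skdraw.disk((0, 300), 40, shape=image.shape)
        image[rr, cc] = 255
        table = measure_organ_sheet(image, scale=0.1)
        assert table.organs["touches_border"].sum() == 1

    def test_row_major_reading_order(self):
        """Components are returned top row first, left to right."""
        image = np.zeros((400, 400), dtype=np.uint8)
        sizes = {(100, 100): 20, (110, 300): 30, (300, 100): 25, (290, 300): 35}
        for (r, c), radius in sizes.items():
            rr, cc = skdraw.disk((r, c), radius)
            image[rr, cc] = 255
        table = measure_organ_sheet(image, scale=1.0)
        diameters = table.organs["longitudinal_mm"].round(-1).tolist()
        assert diameters == [40, 60, 50, 70]

    def test_rgb_input_accepted(self):
        image = np.zeros((200, 200, 3), dtype=np.uint8)
        rr, cc = skdraw.disk((100, 100), 50)
        image[rr, cc, :] = 255
        assert measure_organ_sheet(image, scale=0.1).n == 1


class TestSummaries:
    def make_estimates(self, rows):
        return pd.DataFrame(rows, columns=["flower_id", "shape_class", *PARAM_COLUMNS])

    def test_single_flower_degenerate_stats(self):
        est = self.make_estimates([["f1", "stellate", 0.9, 0.3, 3.7, 1.0]])
        report = summarize_measurements(est)
        row = report.summary.loc[("stellate", "mean")]
        assert row.tolist() == [0.9, 0.3, 3.7, 1.0]
        assert (report.summary.loc[("stellate", "std")] == 0).all()
        assert report.summary.loc[("stellate", "min")].tolist() == row.tolist()

    def test_identical_flowers_have_undefined_correlations(self):
        est = self.make_estimates(
            [["f1", "cup-like", 0.8, 0.4, 3.0, 1.0], ["f2", "cup-like", 0.8, 0.4, 3.0, 1.0]]
        )
        report = summarize_measurements(est)
        assert (report.summary.loc[("cup-like", "std")] == 0).all()
        off_diag = report.correlations.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.isnan(off_diag).all()

    def test_total_row_aggregates_all_classes(self):
        est = self.make_estimates(
            [["a", "stellate", 1.0, 0.2, 4.0, 1.0], ["b", "cup-like", 0.6, 0.4, 3.0, 0.9]]
        )
        report = summarize_measurements(est)
        assert report.summary.loc[("total", "mean"), "s_y1"] == pytest.approx(0.8)
        assert report.summary.loc[("total", "max"), "y_0"] == 4.0

    def test_table_layout_column_order(self):
        est = self.make_estimates([["a", "other", 0.5, 0.2, 3.2, 0.8]])
        assert list(summarize_measurements(est).summary.columns) == ["s_y1", "s_x1", "y_0", "x_0"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_measurements(pd.DataFrame(columns=["shape_class", *PARAM_COLUMNS]))

    def test_pairs_accepts_table_estimate_tuples(self, defaults):
        table = synth_measurement_table(defaults, NoiseModel(0.0), shape_class="stellate")
        _, est = estimate_params(table, tepal_count=20)
        report = summarize_measurements([(table, est)])
        assert report.summary.loc[("stellate", "mean"), "x_0"] == pytest.approx(1.0)

    def test_class_means_lie_in_observed_parameter_ranges(self):
        """Every cohort-generator class mean sits inside the observed spans
        of the real 100-specimen survey (s_x1 in [0.091, 0.627], s_y1 in
        [0.048, 1.588])."""
        for stats in REFERENCE_CLASS_STATS.values():
            assert 0.091 <= stats["s_x1"][0] <= 0.627
            assert 0.048 <= stats["s_y1"][0] <= 1.588


class TestCsvSchema:
    def test_round_trip(self, tmp_path, defaults):
        t1 = synth_measurement_table(defaults, NoiseModel(0.0), flower_id="a", shape_class="stellate")
        t2 = synth_measurement_table(
            defaults.replace(x_0=2.0), NoiseModel(0.0), flower_id="b", shape_class="cup-like"
        )
        path = tmp_path / "measurements.csv"
        write_measurement_csv([t1, t2], path)
        back = read_measurement_csv(path)
        assert [t.flower_id for t in back] == ["a", "b"]
        assert back[0].shape_class == "stellate"
        assert back[0].r_b == t1.r_b
        assert np.allclose(back[1].organs["transverse_mm"], t2.organs["transverse_mm"])

    def test_invalid_shape_class_rejected(self):
        with pytest.raises(ValueError, match="shape_class"):
            make_table([5.0] * 3, [9.0] * 3, shape_class="spiky")

    def test_non_consecutive_indices_rejected(self):
        organs = pd.DataFrame(
            {"organ_index": [0, 2, 3], "transverse_mm": [5, 4, 3], "longitudinal_mm": [9, 8, 7]}
        )
        with pytest.raises(ValueError, match="consecutive"):
            MeasurementTable(flower_id="x", organs=organs, r_b=10.0)
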