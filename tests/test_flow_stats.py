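"""Binned fields, mean speed, v_rms, wall profiles, downstream components, QC."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from pvsflow import flow_stats
from pvsflow.flow_stats import (VelocityField, backflow_percent, bin_velocities,
                                downstream_component, mean_flow_speed,
                                qc_nonstagnant_bins, speed_profile, vrms_series)


def _df(x, y, ux, uy, frame=None):
    n = len(x)
    return pd.DataFrame({
        "frame": frame if frame is not None else np.zeros(n, int),
        "x_px": x, "y_px": y,
        "x_um": np.asarray(x, float), "y_um": np.asarray(y, float),
        "ux_um_s": ux, "uy_um_s": uy,
    })


class TestBinning:
    def test_uniform_flow_mean_is_exact(self):
        rng = np.random.default_rng(0)
        df = _df(rng.uniform(0, 7.4, 100), rng.uniform(0, 7.4, 100),
                 np.full(100, 10.0), np.zeros(100))
        field = bin_velocities(df, box_px=7.5, min_count=20)
        assert field.mean_ux[0, 0] == pytest.approx(10.0, abs=1e-12)
        assert field.mean_speed[0, 0] == pytest.approx(10.0, abs=1e-12)

    def test_box_below_min_count_flagged_invalid(self):
        df = _df(np.full(19, 3.0), np.full(19, 3.0), np.ones(19), np.zeros(19))
        field = bin_velocities(df, box_px=7.5, min_count=20)
        assert not field.valid[0, 0]
        assert np.isnan(field.mean_ux[0, 0])
        # one more measurement flips it valid
        field = bin_velocities(pd.concat([df, df.iloc[:1]]), 7.5, 20)
        assert field.valid[0, 0]

    def test_unit_vector_field_is_unit(self):
        rng = np.random.default_rng(1)
        df = _df(rng.uniform(0, 30, 500), rng.uniform(0, 30, 500),
                 rng.normal(5, 1, 500), rng.normal(-3, 1, 500))
        field = bin_velocities(df, 7.5, 20)
        mags = np.hypot(field.u_hat[..., 0], field.u_hat[..., 1])
        assert np.allclose(mags[np.isfinite(mags)], 1.0)


class TestMeanFlowSpeed:
    def _field(self, speeds, valid=None):
        speeds = np.asarray(speeds, float)[None, :]
        valid = (np.ones_like(speeds, bool) if valid is None
                 else np.asarray(valid, bool)[None, :])
        return VelocityField(box_px=7.5, mean_ux=speeds, mean_uy=np.zeros_like(speeds),
                             mean_speed=np.abs(speeds), count=np.full(speeds.shape, 99),
                             valid=valid, min_count=20)

    def test_mean_of_valid_boxes(self):
        assert mean_flow_speed(self._field([10.0, 20.0])) == pytest.approx(15.0)

    def test_all_invalid_raises(self):
        with pytest.raises(ValueError):
            mean_flow_speed(self._field([10.0], valid=[False]))

    def test_nearly_stagnant_boxes_excludable(self):
        field = self._field([1.0, 10.0, 20.0])
        assert mean_flow_speed(field, min_box_speed=2.0) == pytest.approx(15.0)


class TestVrms:
    def test_root_mean_square_arithmetic(self):
        df = _df([1, 2], [1, 1], [3.0, 4.0], [0.0, 0.0], frame=[0, 0])
        series = vrms_series(df, n_frames=2, frame_rate=30.0)
        assert series.vrms[0] == pytest.approx(np.sqrt(12.5))
        assert np.isnan(series.vrms[1]) and series.count[1] == 0

    def test_constant_speeds_give_that_constant(self):
        df = _df(np.arange(5.0), np.ones(5), np.full(5, 7.0), np.zeros(5))
        assert vrms_series(df, 1, 30.0).vrms[0] == pytest.approx(7.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        ux = rng.normal(size=50)
        df1 = _df(np.arange(50.0), np.ones(50), ux, np.zeros(50))
        perm = rng.permutation(50)
        df2 = df1.iloc[perm].reset_index(drop=True)
        assert vrms_series(df1, 1, 30.0).vrms[0] == pytest.approx(
            vrms_series(df2, 1, 30.0).vrms[0])

    def test_cardiac_frequency_dominates_spectrum(self, std_run):
        from pvsflow.physio_sync import dominant_frequency
        scenario, result, _ = std_run
        v = result.vrms.vrms
        f = dominant_frequency(np.nan_to_num(v, nan=np.nanmean(v)),
                               scenario.frame_rate)
        df_bin = scenario.frame_rate / len(v)
        assert abs(f - scenario.cardiac_frequency) <= df_bin + 1e-9


class TestSpeedProfile:
    def test_uniform_flow_flat_profile(self):
        rng = np.random.default_rng(3)
        df = _df(rng.uniform(0, 50, 2000), rng.uniform(0, 20, 2000),
                 np.full(2000, 8.0), np.zeros(2000))
        prof = speed_profile(df, wall=np.array([[0.0, 0.0], [50.0, 0.0]]), bin_um=2.0)
        filled = prof.mean_speed[np.isfinite(prof.mean_speed)]
        assert np.allclose(filled, 8.0)

    def test_poiseuille_profile_parabolic_with_no_slip(self, std_run):
        """Cross-channel profile: quadratic, R² ≥ 0.95, zeros at both walls."""
        scenario, result, truth = std_run
        df = result.measurements
        # registration pads the canvas, so locate the bottom wall from the
        # measurements themselves (particles fill the channel to the walls)
        wall_y = df["y_um"].min() - 0.5
        wall = np.array([[df["x_um"].min(), wall_y], [df["x_um"].max(), wall_y]])
        prof = speed_profile(df, wall, bin_um=3.0)
        ok = np.isfinite(prof.mean_speed) & (prof.count > 50)
        d, v = prof.bin_centers[ok], prof.mean_speed[ok]
        coef = np.polyfit(d, v, 2)
        fit = np.polyval(coef, d)
        r2 = 1 - np.sum((v - fit) ** 2) / np.sum((v - v.mean()) ** 2)
        assert r2 >= 0.95
        roots = np.sort(np.roots(coef))
        w = scenario.channel_width
        assert roots[0] == pytest.approx(0.0, abs=0.15 * w)
        assert roots[1] == pytest.approx(w, rel=0.15)

    def test_degenerate_wall_rejected(self):
        df = _df([1.0], [1.0], [1.0], [0.0])
        with pytest.raises(ValueError):
            speed_profile(df, wall=np.array([[0.0, 0.0]]))


class TestDownstream:
    def _uniform_field(self, ux=1.0, uy=0.0):
        shape = (2, 2)
        return VelocityField(box_px=7.5,
                             mean_ux=np.full(shape, ux), mean_uy=np.full(shape, uy),
                             mean_speed=np.full(shape, np.hypot(ux, uy)),
                             count=np.full(shape, 99),
                             valid=np.ones(shape, bool), min_count=20)

    def test_projection_arithmetic(self):
        df = _df([1.0], [1.0], [3.0], [4.0])
        comps, skipped = downstream_component(df, self._uniform_field(1.0, 0.0))
        assert comps[0] == pytest.approx(3.0) and skipped == 0

    def test_antiparallel_gives_negative_speed(self):
        df = _df([1.0], [1.0], [-5.0], [0.0])
        comps, _ = downstream_component(df, self._uniform_field(1.0, 0.0))
        assert comps[0] == pytest.approx(-5.0)

    def test_projection_bounded_by_speed(self):
        # oracle: Cauchy–Schwarz over 10⁴ random vectors
        rng = np.random.default_rng(4)
        n = 10_000
        theta = rng.uniform(0, 2 * np.pi)
        field = self._uniform_field(np.cos(theta), np.sin(theta))
        df = _df(rng.uniform(0, 14, n), rng.uniform(0, 14, n),
                 rng.normal(0, 5, n), rng.normal(0, 5, n))
        comps, _ = downstream_component(df, field)
        speeds = np.hypot(df["ux_um_s"], df["uy_um_s"])
        assert np.all(np.abs(comps) <= speeds + 1e-9)

    def test_undefined_boxes_skipped_and_counted(self):
        field = self._uniform_field()
        field.mean_ux[1, 1] = np.nan
        field.mean_uy[1, 1] = np.nan
        df = _df([1.0, 10.0], [1.0, 10.0], [1.0, 1.0], [0.0, 0.0])
        comps, skipped = downstream_component(df, field)
        assert skipped == 1 and np.isnan(comps[1])


class TestBackflow:
    def test_percent_arithmetic(self):
        assert backflow_percent([-1, 2, 3, -2, 5]) == pytest.approx(40.0)

    def test_all_positive_zero_percent(self):
        assert backflow_percent([1.0, 2.0]) == 0.0

    def test_zero_counts_as_forward(self):
        assert backflow_percent([0.0, -1.0]) == pytest.approx(50.0)

    @settings(max_examples=50, deadline=None)
    @given(hnp.arrays(np.float64, st.integers(1, 60),
                      elements=st.floats(-1e3, 1e3).filter(lambda v: abs(v) > 1e-9)))
    def test_antisymmetry(self, comps):
        assert backflow_percent(-comps) == pytest.approx(100.0 - backflow_percent(comps))

    def test_generator_imposed_backflow_difference(self):
        """Downstream-component backflow on ground-truth velocities tracks the
        generator's imposed negative-velocity fraction for a condition pair."""
        from pvsflow import synthetic
        percents = {}
        for label, amp in (("normal", 0.0), ("hypertensive", 0.15)):
            sc = synthetic.FlowScenario(seed=6, duration=10.0, stuck_fraction=0.0,
                                        backflow_amplitude=amp)
            _, truth = synthetic.generate_flow_movie(sc)
            tt = truth.true_tracks
            margin = truth.params["margin_px"]
            df = _df(tt["x_um"] + margin, tt["y_um"] + margin,
                     tt["ux_um_s"], tt["uy_um_s"], frame=tt["frame"])
            field = bin_velocities(df, 7.5, 20)
            comps, _ = downstream_component(df, field)
            percents[label] = backflow_percent(comps)
        assert percents["hypertensive"] > percents["normal"]
        diff = percents["hypertensive"] - percents["normal"]
        assert diff == pytest.approx(15.0, abs=3.0)


class TestQC:
    def _field(self, n_valid, shape=(15, 15)):
        valid = np.zeros(shape, bool)
        valid.flat[:n_valid] = True
        zeros = np.zeros(shape)
        return VelocityField(7.5, zeros, zeros, zeros,
                             np.where(valid, 99, 0), valid, 20)

    @pytest.mark.parametrize("n,expected", [(79, False), (200, True), (0, False)])
    def test_bin_count_rule(self, n, expected):
        count, ok = qc_nonstagnant_bins(self._field(n), min_bins=80)
        assert count == n and ok is expected

    def test_stagnant_boxes_removed_from_count(self):
        field = self._field(100)
        mask = np.zeros((120, 120), bool)
        mask[:8, :] = True          # covers the first row of boxes
        count, _ = qc_nonstagnant_bins(field, mask, min_bins=80)
        assert count < 100
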