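import numpy as np
import pandas as pd
import pytest

from dbsrecruit import synth, widefield as wf


@pytest.fixture(scope="module")
def random_stack():
    stack_data, masks, tt, rate = synth.generate_widefield_stack(
        n_trials=2, trial_len_s=30.0, dbs_len_s=15.0, height=32, width=32,
        suppressed_region=None, seed=21,
    )
    return wf.WidefieldStack(stack_data, rate, tt, masks)


class TestMotionCorrection:
    def test_planted_integer_shifts_recovered(self, rng):
        shifts = np.zeros((30, 2), dtype=int)
        shifts[5:] = rng.integers(-10, 11, size=(25, 2))
        stack_data, masks, tt, rate = synth.generate_widefield_stack(
            n_trials=1, trial_len_s=1.5, dbs_len_s=0.5, dbs_onset_s=0.5,
            height=48, width=48, shifts=shifts, suppressed_region=None,
            noise_sd=0.0, activity_sd=0.0, seed=1,
        )
        st = wf.WidefieldStack(stack_data, rate, tt.iloc[:0], {})
        corrected, rec = wf.motion_correct_rigid(st)
        np.testing.assert_array_equal(rec, shifts)
        # circular shifts are exactly undone
        assert np.max(np.abs(corrected.data - corrected.data[0][None])) < 1e-9

    def test_identical_frames_zero_shift(self):
        data = np.tile(np.random.default_rng(0).random((16, 16)), (5, 1, 1))
        st = wf.WidefieldStack(data, 20.0, pd.DataFrame(), {})
        _, shifts = wf.motion_correct_rigid(st)
        np.testing.assert_array_equal(shifts, 0)

    def test_all_zero_frame_errors(self):
        data = np.zeros((3, 8, 8))
        with pytest.raises(ValueError):
            wf.motion_correct_rigid(wf.WidefieldStack(data, 20.0, pd.DataFrame(), {}))


class TestDff:
    def test_constant_stack_gives_zero(self):
        tt = pd.DataFrame(
            [{"block": 0, "trial": 0, "dbs_on_frame": 200, "dbs_off_frame": 400}]
        )
        st = wf.WidefieldStack(np.full((500, 8, 8), 7.0), 20.0, tt, {})
        out = wf.dff(st)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_ten_percent_step(self):
        tt = pd.DataFrame(
            [{"block": 0, "trial": 0, "dbs_on_frame": 200, "dbs_off_frame": 400}]
        )
        data = np.ones((500, 4, 4))
        data[200:400] = 1.10
        st = wf.WidefieldStack(data, 20.0, tt, {})
        out = wf.dff(st)
        np.testing.assert_allclose(out.data[250], 0.10, atol=1e-12)
        np.testing.assert_allclose(out.data[100], 0.0, atol=1e-12)

    def test_matches_per_pixel_oracle(self, random_stack):
        out = wf.dff(random_stack)
        rate = random_stack.frame_rate_hz
        off0, blen = int(9 * rate), int(0.5 * rate)
        onsets = random_stack.trial_table["dbs_on_frame"].astype(int).to_numpy()
        starts = onsets - off0
        bounds = np.r_[0, starts[1:], random_stack.n_frames]
        expected = np.empty_like(random_stack.data)
        for i, on in enumerate(onsets):
            f0 = random_stack.data[on - off0 : on - off0 + blen].mean(axis=0)
            s0 = 0 if i == 0 else bounds[i]
            for t in range(s0, bounds[i + 1]):
                expected[t] = (random_stack.data[t] - f0) / f0
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_zero_baseline_pixel_masked(self):
        tt = pd.DataFrame(
            [{"block": 0, "trial": 0, "dbs_on_frame": 200, "dbs_off_frame": 300}]
        )
        data = np.ones((400, 4, 4))
        data[:, 0, 0] = 0.0
        out = wf.dff(wf.WidefieldStack(data, 20.0, tt, {}))
        assert np.all(np.isnan(out.data[:, 0, 0]))
        assert not np.any(np.isnan(out.data[:, 1, 1]))


class TestRegionCurves:
    def test_zscored_mean_zero_sd_one(self, random_stack):
        curves = wf.region_zscore_curves(random_stack)
        np.testing.assert_allclose(curves.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(curves.std(axis=1, ddof=0), 1.0, atol=1e-10)

    def test_matches_oracle_on_random_stack(self, random_stack):
        from scipy.ndimage import gaussian_filter

        curves = wf.region_zscore_curves(random_stack)
        for name, mask in random_stack.region_masks.items():
            sm = np.stack(
                [gaussian_filter(f, 2.0) for f in random_stack.data]
            )
            series = sm[:, mask].mean(axis=1)
            z = (series - series.mean()) / series.std()
            np.testing.assert_allclose(curves.loc[name].to_numpy(), z, atol=1e-10)

    def test_smoothing_identity_on_uniform_image(self):
        tt = pd.DataFrame()
        data = np.full((3, 40, 40), 5.0)
        data += np.random.default_rng(0).normal(0, 1e-9, data.shape)  # avoid zero variance
        masks = {"A": np.zeros((40, 40), dtype=bool)}
        masks["A"][15:25, 15:25] = True  # interior region
        st = wf.WidefieldStack(data, 20.0, tt, masks)
        curves = wf.region_zscore_curves(st)
        assert curves.shape == (1, 3)

    def test_empty_mask_errors(self, random_stack):
        with pytest.raises(ValueError):
            wf.region_zscore_curves(random_stack, {"X": np.zeros((32, 32), dtype=bool)})


class TestSustainedSuppression:
    def test_window_selection_matches_frame_oracle(self, random_stack):
        curves = wf.region_zscore_curves(random_stack)
        out = wf.sustained_suppression(
            curves, random_stack.trial_table, random_stack.frame_rate_hz, window_s=10.0
        )
        n_win = int(10 * random_stack.frame_rate_hz)
        row = random_stack.trial_table.iloc[0]
        off = int(row["dbs_off_frame"])
        for region in curves.index:
            expected = np.mean(
                [
                    curves.loc[region].to_numpy()[int(r["dbs_off_frame"]) - n_win : int(r["dbs_off_frame"])].mean()
                    for _, r in random_stack.trial_table.iterrows()
                ]
            )
            got = out[(out["region"] == region) & (out["block"] == 0)]["score"].iloc[0]
            assert got == pytest.approx(expected)

    def test_planted_suppression_negative_and_dose_ordered(self):
        stack_data, masks, tt, rate = synth.generate_widefield_stack(
            n_blocks=3, suppression_depth=(0.1, 0.25, 0.5), seed=13,
        )
        st = wf.WidefieldStack(stack_data, rate, tt, masks)
        curves = wf.region_zscore_curves(wf.dff(st))
        out = wf.sustained_suppression(curves, tt, rate, window_s=10.0)
        fc = out[out["region"] == "FC"].sort_values("block")["score"].to_numpy()
        assert np.all(np.diff(fc) < 0)  # deeper suppression at higher dose
        assert fc[-1] < -1.0
        null_scores = out[out["region"] != "FC"]["score"].abs()
        assert null_scores.max() < abs(fc[-1])

    def test_short_dbs_period_errors(self, random_stack):
        curves = wf.region_zscore_curves(random_stack)
        with pytest.raises(ValueError):
            wf.sustained_suppression(
                curves, random_stack.trial_table, random_stack.frame_rate_hz, window_s=100.0
            )


def test_dff_region_average_commutes_on_uniform_baseline():
    # with a spatially uniform baseline, averaging then dff equals
    # dff then averaging
    tt = pd.DataFrame([{"block": 0, "trial": 0, "dbs_on_frame": 200, "dbs_off_frame": 350}])
    rng = np.random.default_rng(3)
    temporal = 1.0 + 0.1 * rng.random(400)
    data = np.tile(temporal[:, None, None], (1, 8, 8))
    mask = np.ones((8, 8), dtype=bool)
    st = wf.WidefieldStack(data, 20.0, tt, {"R": mask})
    d = wf.dff(st)
    region_then = d.data[:, mask].mean(axis=1)
    series = data[:, mask].mean(axis=1)
    f0 = series[200 - 180 : 200 - 170].mean()
    then_region = (series - f0) / f0
    np.testing.assert_allclose(region_then, then_region, atol=1e-10)


def test_tiff_and_mask_round_trip(tmp_path, random_stack):
    wf.write_stack(random_stack, tmp_path / "s.tif")
    back = wf.read_stack(
        tmp_path / "s.tif", random_stack.frame_rate_hz, random_stack.trial_table,
        random_stack.region_masks,
    )
    np.testing.assert_allclose(back.data, random_stack.data, atol=1e-4)
    wf.write_masks_json(random_stack.region_masks, tmp_path / "m.json")
    masks = wf.read_masks_json(tmp_path / "m.json")
    for name, m in random_stack.region_masks.items():
        np.testing.assert_array_equal(masks[name], m)
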