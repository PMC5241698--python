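"""Reference localizer: detection, fitting, rejection, stack processing, sweep."""

import numpy as np
import pytest

import smlmkit as sk
from conftest import render_single


def render_pair_frame(optics, camera, separation_nm):
    fw, fh = optics.field_nm
    traces = sk.EmitterTraces(
        positions=np.array(
            [[fw / 2 - separation_nm / 2, fh / 2], [fw / 2 + separation_nm / 2, fh / 2]]
        ),
        n_frames=1,
        active_frame=np.array([0, 0]),
        active_emitter=np.array([0, 1]),
        on_fraction=np.array([1.0, 1.0]),
    )
    return sk.render_frames(traces, optics, camera, 0, shot_noise=False)


class TestDetect:
    def test_single_psf_one_candidate(self, optics, quiet_camera):
        fw, fh = optics.field_nm
        stack = render_single(optics, quiet_camera, fw / 2 + 20, fh / 2 - 40)
        cand = sk.detect_candidates(stack.data[0])
        assert len(cand) == 1
        r, c = cand[0]
        assert abs((c + 0.5) * 110 - (fw / 2 + 20)) < 110
        assert abs((r + 0.5) * 110 - (fh / 2 - 40)) < 110

    def test_blank_frame_no_candidates(self, optics):
        img = np.full((16, 16), 100.0)
        assert len(sk.detect_candidates(img)) == 0

    def test_two_psfs_at_8px_two_candidates(self, quiet_camera):
        optics = sk.OpticsConfig(field_px=(24, 24))
        stack = render_pair_frame(optics, quiet_camera, 8 * 110.0)
        assert len(sk.detect_candidates(stack.data[0])) == 2

    def test_min_distance_respected(self, strand_bundle, strand_table):
        cfg = sk.LocalizerConfig()
        for f, grp in strand_table.groupby("frame"):
            p = grp[["x_nm", "y_nm"]].to_numpy() / 110.0
            if len(p) > 1:
                d = np.sqrt(((p[:, None] - p[None]) ** 2).sum(-1))
                np.fill_diagonal(d, np.inf)
                assert d.min() >= cfg.min_distance_px - 1  # fits refine by <1 px

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            sk.detect_candidates(np.empty((0, 0)))


class TestFit:
    def test_noise_free_subnanometre_accuracy(self, optics, quiet_camera):
        fw, fh = optics.field_nm
        x, y = fw / 2 + 37.3, fh / 2 - 81.9
        stack = render_single(optics, quiet_camera, x, y)
        (cand,) = sk.detect_candidates(stack.data[0])
        rec = sk.fit_emitter(stack.data[0], tuple(cand), optics, quiet_camera)
        assert abs(rec["x_nm"] - x) < 1.0
        assert abs(rec["y_nm"] - y) < 1.0
        assert rec["sigma_nm"] == pytest.approx(optics.sigma_nm, rel=0.02)
        assert rec["intensity_photon"] == pytest.approx(450, rel=0.01)

    def test_uncertainty_scale(self, optics, quiet_camera):
        fw, fh = optics.field_nm
        stack = render_single(optics, quiet_camera, fw / 2, fh / 2)
        (cand,) = sk.detect_candidates(stack.data[0])
        rec = sk.fit_emitter(stack.data[0], tuple(cand), optics, quiet_camera)
        # shot-noise-limited precision ~ sigma/sqrt(N) ~ 3.4 nm; contract x2
        expected = optics.sigma_nm / np.sqrt(450)
        assert expected / 2 < rec["uncertainty_nm"] < expected * 2

    def test_border_candidate_raises(self, optics, quiet_camera):
        img = np.zeros((16, 16))
        with pytest.raises(ValueError, match="border"):
            sk.fit_emitter(img, (1, 1), optics, quiet_camera)


class TestReject:
    def test_merged_pair_rejected_clean_single_kept(self, quiet_camera):
        optics = sk.OpticsConfig(field_px=(24, 24))
        # 300 nm pair: detector merges them, fit width inflates past 1.5x
        stack = render_pair_frame(optics, quiet_camera, 300.0)
        table = sk.localize_stack(stack, optics, quiet_camera, keep_rejected=True)
        merged = table[table["rejected"]]
        assert len(merged) >= 1
        assert (merged["sigma_nm"] > 1.5 * optics.sigma_nm).any() or (
            (merged["sigma_x_nm"] - merged["sigma_y_nm"]).abs() / merged["sigma_nm"]
            > sk.LocalizerConfig().asymmetry_bound
        ).any()
        fw, fh = optics.field_nm
        single = render_single(optics, quiet_camera, fw / 2, fh / 2)
        kept = sk.localize_stack(single, optics, quiet_camera)
        assert len(kept) == 1

    def test_all_rejected_empty_kept(self, optics):
        import pandas as pd

        recs = pd.DataFrame(
            {
                "sigma_nm": [300.0],
                "sigma_x_nm": [400.0],
                "sigma_y_nm": [200.0],
            }
        )
        kept, rejected = sk.reject_fits(recs, optics)
        assert len(kept) == 0 and len(rejected) == 1

    def test_empty_input_ok(self, optics):
        import pandas as pd

        kept, rejected = sk.reject_fits(pd.DataFrame(), optics)
        assert len(kept) == 0 and len(rejected) == 0


class TestLocalizeStack:
    def test_one_activation_per_frame_recovered(self, default_camera):
        optics = sk.OpticsConfig(field_px=(16, 16))
        fw, fh = optics.field_nm
        rng = np.random.default_rng(9)
        n = 100
        pos = np.column_stack(
            [rng.uniform(0.36 * fw, 0.64 * fw, n), rng.uniform(0.36 * fh, 0.64 * fh, n)]
        )
        traces = sk.EmitterTraces(
            pos, n, np.arange(n), np.arange(n), np.ones(n)
        )
        stack = sk.render_frames(traces, optics, default_camera, rng)
        table = sk.localize_stack(stack, optics, default_camera)
        assert len(table) >= 95
        errs = []
        for _, rec in table.iterrows():
            true = pos[int(rec["frame"])]
            errs.append(np.hypot(rec["x_nm"] - true[0], rec["y_nm"] - true[1]))
        rmse = np.sqrt(np.mean(np.square(errs)))
        assert rmse < 2 * table["uncertainty_nm"].mean()

    def test_empty_stack(self, optics, default_camera):
        stack = sk.FrameStack(np.zeros((0, 16, 16)), 110.0)
        assert len(sk.localize_stack(stack, optics, default_camera)) == 0

    def test_more_photons_less_uncertainty(self, default_camera):
        meds = []
        for photons in (450.0, 1800.0):
            optics = sk.OpticsConfig(field_px=(16, 16), photons_full_frame=photons)
            fw, fh = optics.field_nm
            rng = np.random.default_rng(10)
            n = 40
            pos = np.column_stack(
                [rng.uniform(0.4 * fw, 0.6 * fw, n), rng.uniform(0.4 * fh, 0.6 * fh, n)]
            )
            traces = sk.EmitterTraces(pos, n, np.arange(n), np.arange(n), np.ones(n))
            stack = sk.render_frames(traces, optics, default_camera, rng)
            table = sk.localize_stack(stack, optics, default_camera)
            meds.append(table["uncertainty_nm"].median())
        assert meds[1] < meds[0]


@pytest.fixture(scope="module")
def sweep():
    return sk.separation_sweep(np.arange(120.0, 901.0, 40.0))


class TestSeparationSweep:
    def test_three_contiguous_regimes(self, sweep):
        regimes = sweep.regimes
        order = {"merged": 0, "biased": 1, "accurate": 2}
        codes = [order[r] for r in regimes]
        assert codes == sorted(codes)
        assert set(regimes) == {"merged", "biased", "accurate"}

    def test_large_separation_accurate(self, sweep):
        assert sweep.regimes[-1] == "accurate"
        assert sweep.n_localizations[-1] == 2

    def test_small_separation_merged(self, sweep):
        assert sweep.regimes[0] == "merged"
        assert sweep.n_localizations[0] <= 1

    def test_bias_decays_in_biased_regime(self, sweep):
        idx = [i for i, r in enumerate(sweep.regimes) if r == "biased"]
        if len(idx) > 1:
            biases = sweep.midpoint_bias_nm[idx]
            assert np.all(np.diff(biases) <= 1e-9)

    def test_exclusion_radius_brackets(self, sweep):
        merge_t, acc_t, rec = sk.estimate_exclusion_radius(sweep)
        assert merge_t < acc_t == rec
        assert 150 <= acc_t <= 700

    def test_wider_psf_raises_thresholds(self, sweep):
        wide = sk.OpticsConfig(psf_sigma_nm=1.5 * sk.OpticsConfig().sigma_nm)
        sweep_wide = sk.separation_sweep(np.arange(120.0, 1201.0, 40.0), optics=wide)
        m0, a0, _ = sk.estimate_exclusion_radius(sweep)
        m1, a1, _ = sk.estimate_exclusion_radius(sweep_wide)
        assert m1 >= m0
        assert a1 >= a0

    def test_unsorted_separations_rejected(self):
        with pytest.raises(ValueError):
            sk.separation_sweep([500.0, 300.0])

    def test_unbracketed_sweep_raises(self):
        res = sk.separation_sweep(np.arange(700.0, 901.0, 50.0))
        with pytest.raises(ValueError, match="bracket"):
            sk.estimate_exclusion_radius(res)
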