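import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skewgait.features_tsr import (
    CORNERS,
    IsoBlockSeries,
    TSRFit,
    compute_tar_bar,
    compute_velocity,
    extract_features,
    extract_isoblock,
    fit_tsr,
)
from skewgait.pose_io import PoseSequence, sample_frames
from skewgait.synthetic_gait import WalkerParams, generate_walk

from conftest import make_sequence


def ols_normal_equations(x, y):
    """Independent closed-form least-squares oracle."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = np.sum((x - x.mean()) ** 2)
    beta = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    alpha = y.mean() - beta * x.mean()
    return alpha, beta


def _series_from_lines(coeffs, n=10):
    """Build an IsoBlockSeries whose corners follow y = a + b x exactly."""
    t = np.arange(n, dtype=float)
    corners = {}
    for corner, (a, b) in coeffs.items():
        x = t + (100.0 if corner in ("rt", "rb") else 0.0)
        y = a + b * x + (1000.0 if corner in ("lt", "rt") else 0.0)
        corners[corner] = np.column_stack([x, y])
    return IsoBlockSeries(corners=corners, timestamps=t / 30, image_height=1080)


def _fits(b_lt, b_rt, b_lb, b_rb):
    return {
        "lt": TSRFit("lt", 0.0, b_lt, 0.0, 10),
        "rt": TSRFit("rt", 0.0, b_rt, 0.0, 10),
        "lb": TSRFit("lb", 0.0, b_lb, 0.0, 10),
        "rb": TSRFit("rb", 0.0, b_rb, 0.0, 10),
    }


class TestExtractIsoblock:
    def test_definition_example(self):
        # keypoints at (0,0), (2,1), (1,3) image convention, image height 10
        seq = make_sequence([[(0, 0.0, 0.0), (1, 2.0, 1.0), (2, 1.0, 3.0)]])
        series = extract_isoblock(seq, image_height=10)
        np.testing.assert_allclose(series.corners["lt"][0], (0, 10))
        np.testing.assert_allclose(series.corners["rt"][0], (2, 10))
        np.testing.assert_allclose(series.corners["lb"][0], (0, 7))
        np.testing.assert_allclose(series.corners["rb"][0], (2, 7))

    def test_low_confidence_keypoint_excluded(self):
        seq = make_sequence([[(0, 0.0, 0.0), (1, 2.0, 1.0), (2, 1.0, 3.0)]])
        seq.frames[0].keypoints[3] = (9999.0, 9999.0, 0.0)  # extreme but missing
        series = extract_isoblock(seq, image_height=10)
        assert series.corners["rt"][0, 0] == 2.0
        assert series.corners["rb"][0, 1] == 7.0

    def test_matches_brute_force_on_synthetic_walk(self, straight_walk):
        sampled = sample_frames(straight_walk, 0.3)
        series = extract_isoblock(sampled)
        kp = sampled.keypoint_array()
        for i in range(series.n):
            visible = kp[i][kp[i, :, 2] >= 0.1]
            assert series.corners["lt"][i, 0] == pytest.approx(visible[:, 0].min())
            assert series.corners["rt"][i, 0] == pytest.approx(visible[:, 0].max())
            assert series.corners["lt"][i, 1] == pytest.approx(1080 - visible[:, 1].min())
            assert series.corners["lb"][i, 1] == pytest.approx(1080 - visible[:, 1].max())

    def test_sparse_frames_dropped_with_warning(self, caplog):
        good = [(0, 0.0, 0.0), (1, 2.0, 1.0), (2, 1.0, 3.0)]
        sparse = [(0, 5.0, 5.0)]  # single keypoint: no box
        seq = make_sequence([good, sparse, good, good])
        with caplog.at_level("WARNING"):
            series = extract_isoblock(seq, image_height=10)
        assert series.n == 3
        assert series.n_dropped == 1
        assert any("dropped" in r.message for r in caplog.records)

    def test_mostly_dropped_is_error(self):
        good = [(0, 0.0, 0.0), (1, 2.0, 1.0)]
        sparse = [(0, 5.0, 5.0)]
        seq = make_sequence([good, sparse, sparse, sparse])
        with pytest.raises(ValueError, match="50%"):
            extract_isoblock(seq, image_height=10)


class TestFitTsr:
    def test_exact_line_through_origin(self):
        series = _series_from_lines({c: (0.0, 1.0) for c in CORNERS}, n=3)
        fits = fit_tsr(series)
        for c in CORNERS:
            assert fits[c].beta == pytest.approx(1.0, abs=1e-12)
            assert fits[c].residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_exact_affine_line(self):
        # y = 1 + 2x sampled at x = 0, 1, 2
        series = _series_from_lines({c: (1.0, 2.0) for c in CORNERS}, n=3)
        fits = fit_tsr(series)
        # offsets used to keep corner ordering shift alpha, never beta
        assert fits["lb"].alpha == pytest.approx(1.0, abs=1e-9)
        assert fits["lb"].beta == pytest.approx(2.0, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        x = np.sort(rng.uniform(0, 100, n))
        corners = {}
        expected = {}
        for i, c in enumerate(CORNERS):
            y = rng.normal(50 * (i + 1), 5, n) + rng.uniform(-3, 3) * x
            xs = x + 200 * (c in ("rt", "rb"))
            ys = y + 2000 * (c in ("lt", "rt"))
            corners[c] = np.column_stack([xs, ys])
            expected[c] = ols_normal_equations(xs, ys)
        series = IsoBlockSeries(
            corners=corners, timestamps=np.arange(n) / 30, image_height=1080
        )
        fits = fit_tsr(series)
        for c in CORNERS:
            alpha, beta = expected[c]
            assert fits[c].alpha == pytest.approx(alpha, rel=1e-9, abs=1e-9)
            assert fits[c].beta == pytest.approx(beta, rel=1e-9, abs=1e-12)

    def test_degenerate_corner_is_error(self):
        corners = {c: np.column_stack([np.zeros(5), np.arange(5.0)]) for c in CORNERS}
        corners["rt"] = corners["rt"] + [1.0, 0.0]
        corners["rb"] = corners["rb"] + [1.0, 0.0]
        series = IsoBlockSeries(
            corners=corners, timestamps=np.arange(5) / 30, image_height=1080
        )
        with pytest.raises(ValueError, match="degenerate trajectory.*lt"):
            fit_tsr(series)

    def test_too_few_frames(self):
        series = _series_from_lines({c: (0.0, 1.0) for c in CORNERS}, n=2)
        with pytest.raises(ValueError, match=">= 3"):
            fit_tsr(series)


class TestTarBar:
    def test_equal_slopes_give_unit_ratios(self):
        feats = compute_tar_bar(_fits(1.0, 1.0, 1.0, 1.0))
        assert feats.tar == 1.0
        assert feats.bar == 1.0
        assert feats.valid

    def test_mixed_sign_example(self):
        # tar = [sign(-2) atan(-2)] / [sign(0.5) atan(0.5)] = atan(2) / atan(0.5)
        feats = compute_tar_bar(_fits(-2.0, 0.5, 1.0, 1.0))
        assert feats.tar == pytest.approx(math.atan(2) / math.atan(0.5), rel=1e-12)

    def test_sign_of_zero_is_positive(self):
        # numerator slope 0: angle is +1 * atan(0) = 0, so tar = 0 (valid)
        feats = compute_tar_bar(_fits(0.0, 1.0, 1.0, 1.0))
        assert feats.valid
        assert feats.tar == 0.0

    def test_zero_denominator_marks_invalid(self):
        feats = compute_tar_bar(_fits(1.0, 0.0, 1.0, 1.0))
        assert not feats.valid
        assert "rt" in feats.reason
        assert math.isnan(feats.tar)

    def test_missing_fit_is_error(self):
        fits = _fits(1.0, 1.0, 1.0, 1.0)
        del fits["lb"]
        with pytest.raises(ValueError, match="lb"):
            compute_tar_bar(fits)

    def test_ratios_scale_invariant(self):
        rng = np.random.default_rng(0)
        n = 20
        levels = {"lt": 1500.0, "rt": 1600.0, "lb": 400.0, "rb": 300.0}
        corners = {
            c: np.column_stack(
                [
                    np.linspace(0, 50, n) + 100 * (c in ("rt", "rb")),
                    rng.normal(levels[c], 3, n),
                ]
            )
            for c in CORNERS
        }
        base = IsoBlockSeries(
            corners=corners, timestamps=np.arange(n) / 30, image_height=1080
        )
        scaled = IsoBlockSeries(
            corners={c: 3.7 * corners[c] for c in CORNERS},
            timestamps=np.arange(n) / 30,
            image_height=1080,
        )
        f0 = compute_tar_bar(fit_tsr(base))
        f1 = compute_tar_bar(fit_tsr(scaled))
        assert f1.tar == pytest.approx(f0.tar, rel=1e-9)
        assert f1.bar == pytest.approx(f0.bar, rel=1e-9)

    @pytest.mark.parametrize("skew", [0.0, 0.8, -0.8])
    def test_mirror_reflection_inverts_ratios(self, skew):
        params = WalkerParams(skew_deg=skew, noise_sd_px=0.0, dropout_rate=0.0, seed=2)
        seq = generate_walk(params, "away")
        width = params.image_size[0]
        mirrored = PoseSequence(
            frames=[
                type(f)(
                    frame_index=f.frame_index,
                    timestamp=f.timestamp,
                    keypoints=np.column_stack(
                        [width - f.keypoints[:, 0], f.keypoints[:, 1], f.keypoints[:, 2]]
                    ),
                )
                for f in seq.frames
            ],
            fps=seq.fps,
        )
        f_orig = extract_features(seq, 0.3)
        f_mirror = extract_features(mirrored, 0.3)
        assert f_mirror.tar == pytest.approx(1.0 / f_orig.tar, rel=1e-9)
        assert f_mirror.bar == pytest.approx(1.0 / f_orig.bar, rel=1e-9)


class TestVelocity:
    def test_arithmetic_examples(self):
        frame = [(0, 0.0, 0.0), (1, 2.0, 1.0), (2, 1.0, 3.0)]
        fps = 10.0
        # 5 m over 7.4 s span -> 0.6757 m/s
        seq = make_sequence([frame] * 75, fps=fps)  # span = 74 / 10 = 7.4 s
        assert compute_velocity(seq) == pytest.approx(5.0 / 7.4, abs=1e-4)
        seq = make_sequence([frame] * 51, fps=fps)  # span = 5.0 s
        assert compute_velocity(seq) == pytest.approx(1.0)

    def test_recovers_generator_speed(self, straight_walk):
        v = compute_velocity(straight_walk)
        assert v == pytest.approx(0.68, rel=0.02)

    def test_zero_duration_is_error(self):
        frame = [(0, 0.0, 0.0), (1, 2.0, 1.0)]
        seq = make_sequence([frame])
        with pytest.raises(ValueError):
            compute_velocity(seq)


class TestGroupDirection:
    def test_cohort_mean_tar_ordering(self):
        from skewgait.pipeline import features_table
        from skewgait.synthetic_gait import CohortSpec, generate_cohort

        cohort = generate_cohort(CohortSpec(n_subjects=6, walks_per_subject=6, seed=13))
        table = features_table(cohort, 0.3)
        means = table[table["valid"]].groupby("label")["tar"].mean()
        assert means["skew_left"] > 1.0 > means["skew_right"]
        assert means["skew_left"] > means["straight"] > means["skew_right"]
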