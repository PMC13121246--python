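"""Grad-CAM correctness (closed form + occlusion oracle), averaging, reports."""

import numpy as np
import pytest

from drgrade.backbones import BackboneContract
from drgrade.ensemble import EnsemblePrediction, combine, quality_factor, rank_classes, softmax
from drgrade.explain import (
    Heatmap,
    compose_report,
    ensemble_heatmap,
    explanation_heatmaps,
    grad_cam,
    member_heatmap,
    overlay,
    stage_average,
)
from drgrade.io import FundusImage
from drgrade.nn import Conv2d, ReLU


class MeanScoreMember(BackboneContract):
    """Identity network: the feature map is the (scaled) grayscale input and
    every class score is its global mean. Grad-CAM has the closed form
    minmax(ReLU(map)) because alpha = 1/Z exactly."""

    def __init__(self, scale=1.0, constant=None, input_side=16):
        self.name = "identity"
        self.input_side = input_side
        self.target_layers = ["features"]
        self.scale = scale
        self.constant = constant

    def _map(self, x):
        if self.constant is not None:
            return np.full((x.shape[0], 1, x.shape[2], x.shape[3]), self.constant)
        gray = x.mean(axis=1, keepdims=True) - 0.3  # signed map: ReLU matters
        return self.scale * gray

    def forward(self, x):
        a = self._map(x)
        logits = np.repeat(a.mean(axis=(2, 3)), 5, axis=1)
        return {"features": a}, logits

    def class_gradients(self, x, class_idx):
        n, _, h, w = x.shape
        return {"features": np.full((n, 1, h, w), 1.0 / (h * w))}


def _rand_image(rng, side=16):
    return FundusImage(pixels=rng.integers(0, 256, (side, side, 3), dtype=np.uint8), id="r")


def _minmax(a):
    if a.max() <= 0:
        return np.zeros_like(a)
    return (a - a.min()) / (a.max() - a.min())


class TestGradCam:
    def test_mean_score_identity_closed_form(self, rng):
        member = MeanScoreMember()
        img = _rand_image(rng)
        hm = grad_cam(member, img, target_class=2)
        x = member.preprocess(img.pixels)[None]
        expected = _minmax(np.maximum(member._map(x)[0, 0], 0.0))
        np.testing.assert_allclose(hm.values, expected, atol=1e-10)

    def test_constant_feature_maps_give_zero_heatmap(self, rng):
        member = MeanScoreMember(constant=-1.0)
        hm = grad_cam(member, _rand_image(rng), target_class=0)
        assert not hm.values.any() and not hm.upsampled.any()

    def test_invariant_to_positive_logit_rescaling(self, rng):
        img = _rand_image(rng)
        a = grad_cam(MeanScoreMember(scale=1.0), img, 0)
        b = grad_cam(MeanScoreMember(scale=7.5), img, 0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_unknown_layer_rejected(self, rng):
        with pytest.raises(ValueError):
            grad_cam(MeanScoreMember(), _rand_image(rng), 0, layer="nope")

    def test_values_within_unit_interval(self, rng):
        hm = grad_cam(MeanScoreMember(), _rand_image(rng), 1)
        assert 0 <= hm.values.min() and hm.values.max() <= 1


class FixedConvMember(BackboneContract):
    """Two-layer toy net with fixed weights: conv + ReLU, score = global mean.

    The class score is linear in the rectified responses, so the score drop
    under patch occlusion concentrates where the heatmap is large.
    """

    def __init__(self, seed=0, input_side=32):
        self.name = "toy"
        self.input_side = input_side
        self.target_layers = ["features"]
        rng = np.random.default_rng(seed)
        self.conv = Conv2d(3, 4, rng=rng)
        # bias kernels toward a bright-blob detector so responses are sparse
        self.conv.w[:] = np.abs(self.conv.w) * 0.5
        self.conv.b[:] = -0.4
        self.relu = ReLU()

    def forward(self, x):
        a = self.relu.forward(self.conv.forward(x))
        logits = np.repeat(a.mean(axis=(1, 2, 3))[:, None], 5, axis=1)
        return {"features": a}, logits

    def class_gradients(self, x, class_idx):
        maps, _ = self.forward(x)
        n, c, h, w = maps["features"].shape
        return {"features": np.full((n, c, h, w), 1.0 / (c * h * w))}


class TestOcclusionOracle:
    def test_heatmap_peak_matches_occlusion_peak(self):
        """Brute-force occlusion sensitivity (score drop when masking each
        4x4 patch) peaks on the same patch as the Grad-CAM heatmap."""
        member = FixedConvMember(seed=1)
        side, patch = member.input_side, 4
        pixels = np.full((side, side, 3), 20, dtype=np.uint8)
        pixels[18:24, 6:12] = 250  # one bright blob
        img = FundusImage(pixels=pixels, id="blob")
        hm = grad_cam(member, img, target_class=0)

        x = member.preprocess(pixels)[None]
        _, logits = member.forward(x)
        base = logits[0, 0]
        drops = np.zeros((side // patch, side // patch))
        for i in range(side // patch):
            for j in range(side // patch):
                masked = x.copy()
                masked[:, :, i * patch:(i + 1) * patch, j * patch:(j + 1) * patch] = 0.0
                _, occluded = member.forward(masked)
                drops[i, j] = base - occluded[0, 0]
        occ_peak = np.unravel_index(drops.argmax(), drops.shape)
        heat_patches = hm.upsampled.reshape(side // patch, patch, side // patch, patch).mean(axis=(1, 3))
        cam_peak = np.unravel_index(heat_patches.argmax(), heat_patches.shape)
        assert cam_peak == occ_peak


def _heatmap(arr, target_class=0, source="member_A"):
    arr = np.asarray(arr, dtype=float)
    return Heatmap(values=arr, upsampled=arr, target_class=target_class, source=source)


class TestAveraging:
    def test_identical_stages_unchanged(self, rng):
        m = _minmax(rng.random((8, 8)))
        out = stage_average([_heatmap(m, source="member_B:stage1"),
                             _heatmap(m, source="member_B:stage2")])
        np.testing.assert_allclose(out.values, m, atol=1e-12)

    def test_zero_plus_map_equals_normalized_map(self, rng):
        m = _minmax(rng.random((8, 8)))
        out = stage_average([_heatmap(np.zeros((8, 8))), _heatmap(m)])
        np.testing.assert_allclose(out.values, _minmax(m / 2.0), atol=1e-12)

    def test_random_pair_matches_brute_force_mean(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        out = ensemble_heatmap([_heatmap(a), _heatmap(b, source="member_B")])
        np.testing.assert_allclose(out.values, _minmax((a + b) / 2.0), atol=1e-12)

    def test_disjoint_single_hot_maps_give_two_equal_peaks(self):
        a, b = np.zeros((4, 4)), np.zeros((4, 4))
        a[0, 0] = 1.0
        b[3, 3] = 1.0
        out = ensemble_heatmap([_heatmap(a), _heatmap(b)])
        assert out.values[0, 0] == out.values[3, 3] == 1.0

    def test_single_member_ensemble_is_identity(self, rng):
        m = _minmax(rng.random((8, 8)))
        out = ensemble_heatmap([_heatmap(m)])
        np.testing.assert_allclose(out.values, m, atol=1e-12)

    def test_class_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ensemble_heatmap([_heatmap(rng.random((4, 4)), target_class=0),
                              _heatmap(rng.random((4, 4)), target_class=1)])

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            stage_average([_heatmap(rng.random((4, 4))), _heatmap(rng.random((8, 8)))])


class TestOverlay:
    def test_opacity_zero_is_identity(self, rng):
        img = _rand_image(rng)
        hm = _heatmap(_minmax(rng.random((16, 16))))
        np.testing.assert_array_equal(overlay(img, hm, opacity=0.0).pixels, img.pixels)

    def test_half_opacity_matches_direct_blend(self, rng):
        import matplotlib

        img = _rand_image(rng)
        heat = _minmax(rng.random((16, 16)))
        out = overlay(img, _heatmap(heat), opacity=0.5, colormap="inferno")
        mapped = matplotlib.colormaps["inferno"](heat)[:, :, :3] * 255.0
        expected = np.clip(np.rint((img.pixels.astype(float) + mapped) / 2.0), 0, 255)
        np.testing.assert_array_equal(out.pixels, expected.astype(np.uint8))

    def test_misaligned_sizes_rejected(self, rng):
        with pytest.raises(ValueError):
            overlay(_rand_image(rng), _heatmap(np.zeros((4, 4))), opacity=0.5)


def _prediction(probs):
    probs = np.asarray(probs, dtype=float)
    ranking, top1, top2 = rank_classes(probs)
    return EnsemblePrediction(member_probs={"member_A": probs}, combined_probs=probs,
                              ranking=ranking, top1=top1, top2=top2,
                              Q=quality_factor(probs))


class TestComposeReport:
    def _heatmaps(self, rng):
        return {name: _heatmap(_minmax(rng.random((16, 16))), source=name)
                for name in ("ensemble", "member_A", "member_B")}

    def test_confident_prediction_text_and_q(self, rng):
        rep = compose_report(_prediction([0.8, 0.2, 0, 0, 0]), self._heatmaps(rng))
        assert rep.Q == 4
        assert rep.top1[0] == "No DR" and rep.top2[0] == "Mild"
        assert not rep.low_confidence

    def test_selection_controls_panel_count(self, rng):
        rep = compose_report(_prediction([0.6, 0.3, 0.1, 0, 0]), self._heatmaps(rng),
                             selection=["ensemble", "member_A"])
        assert len(rep.panels) == 2
        assert rep.panels[0][0].startswith("M: 0")

    def test_empty_selection_defaults_to_ensemble_with_warning(self, rng):
        with pytest.warns(UserWarning):
            rep = compose_report(_prediction([0.5, 0.3, 0.2, 0, 0]), self._heatmaps(rng),
                                 selection=[])
        assert len(rep.panels) == 1

    def test_near_tied_misclassification_flags_low_q(self, rng):
        """A proliferative case predicted severe with a top-2 ratio under
        2.5 is reported with Q <= 2 and a low-confidence warning."""
        probs = softmax([0.0, 0.0, 0.1, 1.2, 0.5])  # top1=Severe, ratio < 2.5
        rep = compose_report(_prediction(probs), self._heatmaps(rng))
        assert rep.top1[0] == "Severe"
        assert rep.Q <= 2 and rep.low_confidence
        assert "review" in rep.confidence_line

    def test_report_renders_to_png(self, rng, tmp_path):
        out = tmp_path / "report.png"
        compose_report(_prediction([0.7, 0.2, 0.1, 0, 0]), self._heatmaps(rng),
                       selection=["ensemble", "member_A"], out_path=out)
        assert out.exists() and out.stat().st_size > 0


class TestTrainedEnsembleExplanations(object):
    def test_heatmaps_localize_lesions_on_proliferative_images(self, desk_run):
        """On grade-4 synthetic images the ensemble heatmap should be higher
        inside lesion ground-truth disks than outside (>= 70 % of 50 images)."""
        from drgrade.preprocess import BlurSpec, gaussian_blend
        from drgrade.synthetic import SyntheticSpec, generate_fundus

        members = desk_run.members
        spec = SyntheticSpec(side=256)
        blur = BlurSpec.for_side(256)
        wins = 0
        for seed in range(50):
            img, lesions = generate_fundus(4, spec, seed=10_000 + seed)
            # same enhancement the members were trained on
            img = gaussian_blend(img, blur.sigmas[1], blur)
            maps = explanation_heatmaps(members, img, target_class=4)
            heat = maps["ensemble"].upsampled
            mask = np.zeros(heat.shape, dtype=bool)
            yy, xx = np.mgrid[: heat.shape[0], : heat.shape[1]]
            for lesion in lesions:
                r, c = lesion.center
                mask |= (yy - r) ** 2 + (xx - c) ** 2 <= lesion.radius**2
            if heat[mask].mean() > heat[~mask].mean():
                wins += 1
        assert wins >= 35

    def test_dual_stage_member_heatmap_is_stage_average(self, desk_run):
        from drgrade.synthetic import SyntheticSpec, generate_fundus

        member_b = desk_run.members[1]
        img, _ = generate_fundus(3, SyntheticSpec(side=256), seed=77)
        stages = [grad_cam(member_b, img, 3, layer) for layer in member_b.target_layers]
        merged = member_heatmap(member_b, img, 3)
        expected = stage_average(stages)
        np.testing.assert_allclose(merged.values, expected.values, atol=1e-12)
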