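"""Phantom generator: determinism, registration, artifacts, label signal."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import binom

from veus.clinical_eval import auc_ci
from veus.codec import decode_pure_color, extract_pure_color
from veus.phantom import (CaseRecord, PhantomParams, generate_case,
                          generate_dataset, inject_attenuation_artifact,
                          load_dataset)
from veus.quantify import RoiBox, select_reference_region, strain_ratio


def _sr_of(levels, roi, size=12):
    box = RoiBox(*roi)
    ref = select_reference_region(np.asarray(levels), box, size=size)
    return strain_ratio(np.asarray(levels), box, ref).sr


class TestGenerateCase:
    def test_depth_convention_and_roi(self, tiny_params, rng):
        case = generate_case(tiny_params, "malignant", rng)
        r, c, h, w = case.roi
        assert case.tumor_depth_mm == pytest.approx(r * tiny_params.pixel_spacing)
        assert case.bus.shape == (64, 64)
        assert case.eus.shape == (64, 64, 3)
        assert case.stiffness_truth.min() >= 1
        assert case.stiffness_truth.max() <= 256

    def test_zero_artifact_probability_never_flags(self, deep_params, rng):
        cases = [generate_case(deep_params, "benign", rng) for _ in range(20)]
        assert not any(c.artifact_flag for c in cases)

    def test_lesion_hypoechoic_and_darker_when_stiffer(self, tiny_params):
        # malignant (stiff) lesions must be darker on BUS than benign (soft)
        # ones: that monotone coupling is the signal the model learns
        rng = np.random.default_rng(7)
        contrast = {}
        for label in ("benign", "malignant"):
            vals = []
            for _ in range(10):
                c = generate_case(tiny_params, label, rng)
                sl = c.bus[RoiBox(*c.roi).slices()].mean()
                vals.append(sl / max(c.bus.mean(), 1e-9))
            contrast[label] = np.mean(vals)
        assert contrast["malignant"] < contrast["benign"] < 1.0

    def test_equal_lesion_and_background_stiffness_gives_unit_sr(self):
        params = PhantomParams(
            image_size=64, pixel_spacing=0.6, lesion_axes_range=(4.0, 8.0),
            lesion_depth_range=(8.0, 25.0), stiffness_background=110,
            stiffness_benign_range=(109, 111), artifact_prob_deep=0.0,
        )
        rng = np.random.default_rng(3)
        case = generate_case(params, "benign", rng)
        assert _sr_of(case.stiffness_truth, case.roi) == pytest.approx(1.0, abs=0.06)

    def test_unplaceable_lesion_raises(self):
        params = PhantomParams(
            image_size=64, pixel_spacing=0.1,  # only 6.4 mm of depth
            lesion_depth_range=(30.0, 40.0), artifact_prob_deep=0.0,
        )
        with pytest.raises(RuntimeError, match="place a lesion"):
            generate_case(params, "benign", np.random.default_rng(0))

    def test_deep_artifact_rate_within_binomial_interval(self, deep_params):
        params = dataclasses.replace(deep_params, artifact_prob_deep=0.259)
        rng = np.random.default_rng(99)
        n = 1000
        flags = sum(
            generate_case(params, "benign", rng).artifact_flag for _ in range(n)
        )
        lo, hi = binom.ppf([0.025, 0.975], n, 0.259)
        assert lo <= flags <= hi


class TestRegistration:
    def test_decode_recovers_truth_exactly_on_artifact_free_cases(
            self, small_cases, bar, tiny_params):
        scaled = bar.scaled(tiny_params.overlay_weight)
        for case in small_cases:
            levels = decode_pure_color(
                extract_pure_color(case.eus, case.bus), scaled)
            assert (levels == case.stiffness_truth).all()

    def test_truth_sr_perfectly_ranks_labels(self, tiny_params):
        cases = generate_dataset(tiny_params, 60, 0.5, seed=8)
        scores = [_sr_of(c.stiffness_truth, c.roi) for c in cases]
        labels = [1 if c.label == "malignant" else 0 for c in cases]
        assert auc_ci(scores, labels).auc == 1.0


class TestDataset:
    def test_byte_identical_on_repeat(self, tiny_params, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(tiny_params, 10, 0.5, seed=7, out_dir=d1)
        generate_dataset(tiny_params, 10, 0.5, seed=7, out_dir=d2)
        for f in sorted(d1.iterdir()):
            assert (d2 / f.name).read_bytes() == f.read_bytes(), f.name

    def test_exact_label_allocation(self, tiny_params):
        cases = generate_dataset(tiny_params, 100, 0.5, seed=1)
        assert sum(c.label == "malignant" for c in cases) == 50

    def test_round_trip_through_disk(self, tiny_params, tmp_path):
        cases = generate_dataset(tiny_params, 4, 0.5, seed=2, out_dir=tmp_path)
        loaded = load_dataset(tmp_path)
        for a, b in zip(cases, loaded):
            assert (a.bus == b.bus).all()
            assert (a.eus == b.eus).all()
            assert (a.stiffness_truth == b.stiffness_truth).all()
            assert a.roi == b.roi and a.label == b.label
            assert a.birads == b.birads

    def test_sr_separates_labels_with_disjoint_intervals(self, tiny_params, bar):
        cases = generate_dataset(tiny_params, 500, 0.5, seed=31)
        scaled = bar.scaled(tiny_params.overlay_weight)
        scores, labels = [], []
        for c in cases:
            levels = decode_pure_color(extract_pure_color(c.eus, c.bus), scaled)
            scores.append(_sr_of(levels, c.roi))
            labels.append(1 if c.label == "malignant" else 0)
        assert auc_ci(scores, labels).auc > 0.9


class TestArtifact:
    def test_artifact_changes_sr_but_not_truth(self, deep_params, bar):
        rng = np.random.default_rng(4)
        case = generate_case(deep_params, "malignant", rng)
        corrupted = inject_attenuation_artifact(case, rng, params=deep_params)
        assert corrupted.artifact_flag
        assert (corrupted.stiffness_truth == case.stiffness_truth).all()
        scaled = bar.scaled(deep_params.overlay_weight)
        sr_cor = _sr_of(decode_pure_color(
            extract_pure_color(corrupted.eus, corrupted.bus), scaled), case.roi)
        sr_truth = _sr_of(case.stiffness_truth, case.roi)
        assert sr_cor != pytest.approx(sr_truth, rel=1e-3)

    def test_shallow_lesion_is_noop_with_warning(self, tiny_params):
        rng = np.random.default_rng(5)
        shallow = PhantomParams(
            image_size=64, pixel_spacing=0.6, lesion_axes_range=(4.0, 8.0),
            lesion_depth_range=(8.0, 12.0), artifact_prob_deep=0.0)
        case = generate_case(shallow, "benign", rng)
        with pytest.warns(UserWarning, match="shallower"):
            out = inject_attenuation_artifact(case, rng, params=shallow)
        assert (out.eus == case.eus).all() and not out.artifact_flag

    def test_corrupted_tumor_levels_biased_low(self, deep_params, bar):
        rng = np.random.default_rng(6)
        scaled = bar.scaled(deep_params.overlay_weight)
        diffs = []
        for _ in range(10):
            case = generate_case(deep_params, "malignant", rng)
            cor = inject_attenuation_artifact(case, rng, params=deep_params)
            levels = decode_pure_color(
                extract_pure_color(cor.eus, cor.bus), scaled)
            sl = RoiBox(*case.roi).slices()
            diffs.append(levels[sl].mean() - case.stiffness_truth[sl].mean())
        assert np.mean(diffs) < -20  # decoded stiffness far below truth
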