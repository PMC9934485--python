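"""Tests for the ground-truth generator: geometry, rendering, traces."""

import numpy as np
import pytest

from mitomorph import synthgen
from mitomorph.imgproc import binarize, membrane_potential, otsu_threshold
from mitomorph.respirometry import partition

SQRT2 = np.sqrt(2.0)


@pytest.fixture
def ideal(noise_free_params):
    return noise_free_params


class TestGenerateNetwork:
    def test_unbranched_structure_is_individual_with_exact_length(self, ideal):
        truth = synthgen.generate_network(
            1,
            synthgen.BranchLengthDist(kind="fixed", value=10.0),
            synthgen.JunctionDist(probs=(1.0,)),
            seed=5,
            params=ideal,
        )
        (s,) = truth.structures
        assert s.n_junctions == 0 and not s.is_network
        assert len(s.branches) == 1
        # orientation is quantized to 45°, so the realized length is the
        # requested one up to a half pixel-step of rounding
        assert s.branch_lengths[0] == pytest.approx(10.0, abs=ideal.pixel_size * SQRT2 / 2)
        assert s.summed_length == s.branch_lengths[0]

    def test_single_junction_structure_is_three_armed_network(self, ideal):
        truth = synthgen.generate_network(
            1,
            synthgen.BranchLengthDist(kind="fixed", value=5.0),
            synthgen.JunctionDist(probs=(0.0, 1.0)),
            seed=6,
            params=ideal,
        )
        (s,) = truth.structures
        assert s.n_junctions == 1 and s.is_network
        assert len(s.branches) == 3
        assert np.mean(s.branch_lengths) == pytest.approx(5.0, rel=0.02)
        assert s.summed_length == pytest.approx(15.0, rel=0.02)

    def test_lognormal_mean_recovered_at_scale(self):
        """Monte-Carlo branch-length mean agrees with the analytic mean.

        Uses a sparse field so placement rejection (which preferentially
        discards long structures in crowded fields) is negligible.
        """
        sparse = synthgen.ImagingParams(psf_sigma=0, noise_sd=0,
                                        image_shape=(320, 320))
        dist = synthgen.BranchLengthDist(kind="lognormal",
                                         mu=float(np.log(1.5)), sigma=0.35)
        lengths = []
        for seed in range(100):
            t = synthgen.generate_network(2, dist, seed=seed, params=sparse)
            lengths.extend(t.all_branch_lengths())
        lengths = np.array(lengths)
        se = lengths.std(ddof=1) / np.sqrt(lengths.size)
        assert abs(lengths.mean() - dist.mean()) < 3 * se

    def test_structures_kept_disjoint(self, ideal):
        from shapely.geometry import LineString
        from shapely.ops import unary_union
        truth = synthgen.generate_network(8, seed=42, params=ideal)
        geoms = [
            unary_union([LineString(b / ideal.pixel_size) for b in s.branches])
            for s in truth.structures
        ]
        min_sep_px = max(3 * ideal.psf_sigma, 3 * ideal.pixel_size) / ideal.pixel_size
        for i in range(len(geoms)):
            for j in range(i + 1, len(geoms)):
                assert geoms[i].distance(geoms[j]) >= min_sep_px - 1e-9

    def test_impossible_placement_raises(self):
        tiny = synthgen.ImagingParams(psf_sigma=0, noise_sd=0,
                                      image_shape=(40, 40))
        with pytest.raises(synthgen.PlacementError):
            synthgen.generate_network(
                60,
                synthgen.BranchLengthDist(kind="fixed", value=2.0),
                seed=1,
                params=tiny,
            )

    def test_branch_scaling(self):
        d = synthgen.BranchLengthDist(kind="lognormal", mu=0.0, sigma=0.3)
        assert d.scaled(0.5).mean() == pytest.approx(0.5 * d.mean())


class TestRenderImage:
    def test_noise_free_foreground_is_exact(self, ideal):
        truth = synthgen.generate_network(3, seed=7, params=ideal)
        img = synthgen.render_image(truth, ideal, seed=0)
        fg = synthgen.rasterize(truth)
        assert (img.pixels[fg] == truth.mito_intensity_mean).all()
        assert (img.pixels[~fg] == truth.background_intensity_mean).all()

    def test_empty_truth_is_pure_background(self):
        p = synthgen.ImagingParams(psf_sigma=0, noise_sd=4.0, image_shape=(64, 64))
        truth = synthgen.NetworkTruth([], 150.0, 30.0, p)
        img = synthgen.render_image(truth, p, seed=3)
        assert abs(img.pixels.mean() - 30.0) < 1.0  # noise around background

    def test_same_seed_is_bit_identical(self):
        p = synthgen.ImagingParams()
        truth = synthgen.generate_network(4, seed=9, params=p)
        a = synthgen.render_image(truth, p, seed=11)
        b = synthgen.render_image(truth, p, seed=11)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        c = synthgen.render_image(truth, p, seed=12)
        assert (a.pixels != c.pixels).any()

    def test_measured_contrast_equals_truth(self, ideal):
        truth = synthgen.generate_network(4, seed=21, params=ideal)
        img = synthgen.render_image(truth, ideal, seed=2)
        mask = binarize(img, otsu_threshold(img))
        assert membrane_potential(img, mask) == truth.contrast

    def test_unrepresentable_intensity_rejected(self, ideal):
        truth = synthgen.generate_network(1, seed=1, params=ideal,
                                          mito_intensity_mean=300.0)
        with pytest.raises(ValueError, match="bit depth|representable"):
            synthgen.render_image(truth, ideal, seed=0)

    def test_rasterized_length_matches_truth_within_pixel_diag(self, ideal):
        """Re-measuring the unblurred raster agrees with truth lengths."""
        from mitomorph.morphometrics import extract_graph, skeletonize
        from mitomorph.imgproc import BinaryMask
        truth = synthgen.generate_network(6, seed=33, params=ideal)
        mask = BinaryMask(synthgen.rasterize(truth), 0.0, ideal.pixel_size)
        g = extract_graph(skeletonize(mask))
        got = np.sort(g.branch_lengths())
        want = np.sort(truth.all_branch_lengths())
        assert got.size == want.size
        assert np.abs(got - want).max() <= SQRT2 * ideal.pixel_size + 1e-9


class TestDoseStudy:
    def test_deterministic_and_labelled(self):
        spec = synthgen.DoseEffectSpec(cells_per_dose=2, seed=4)
        a = [(t.mean_branch_length(), img.cell_id, img.group_label)
             for t, img in synthgen.generate_dose_study(spec)]
        b = [(t.mean_branch_length(), img.cell_id, img.group_label)
             for t, img in synthgen.generate_dose_study(spec)]
        assert a == b
        assert len(a) == 6
        assert {lbl for _, _, lbl in a} == {"control", "zn5", "zn50"}

    def test_truth_branch_means_follow_scales(self):
        spec = synthgen.DoseEffectSpec(cells_per_dose=8, seed=10)
        means = {}
        for t, img in synthgen.generate_dose_study(spec):
            means.setdefault(img.group_label, []).append(t.mean_branch_length())
        m = [np.mean(means[g]) for g in spec.dose_labels]
        assert m[0] > m[1] > m[2]

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            synthgen.DoseEffectSpec(branch_length_scale=(1.0, 0.5))
        with pytest.raises(ValueError):
            synthgen.DoseEffectSpec(cells_per_dose=1)
        with pytest.raises(ValueError):
            synthgen.DoseEffectSpec(potential_scale=(1.0, 0.8, -0.1))


class TestOCRTraceGeneration:
    def test_plateaus_by_construction(self):
        tr = synthgen.generate_ocr_trace(60, 30, 10, 20)
        df = tr.measurements
        for phase, level in [("basal", 100), ("oligomycin", 40),
                             ("fccp", 120), ("rot_aa", 10)]:
            vals = df.loc[df["phase"] == phase, "ocr"]
            assert (vals == level).all()

    def test_zero_components_give_flat_zero_trace(self):
        tr = synthgen.generate_ocr_trace(0, 0, 0, 0)
        assert (tr.measurements["ocr"] == 0).all()

    def test_noisy_phase_means_within_3_se(self):
        n = 1000
        tr = synthgen.generate_ocr_trace(60, 30, 10, 20,
                                         n_measurements_per_phase=n,
                                         noise_sd=5.0, seed=8)
        df = tr.measurements
        se = 5.0 / np.sqrt(n)
        for phase, level in [("basal", 100), ("oligomycin", 40),
                             ("fccp", 120), ("rot_aa", 10)]:
            m = df.loc[df["phase"] == phase, "ocr"].mean()
            assert abs(m - level) < 3 * se

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            synthgen.generate_ocr_trace(60, 30, 10, 20, n_measurements_per_phase=0)
        with pytest.raises(ValueError):
            synthgen.generate_ocr_trace(-1, 30, 10, 20)

    def test_roundtrip_through_partition_is_exact(self):
        tr = synthgen.generate_ocr_trace(60, 30, 10, 20, cell_count=1)
        r = partition(tr)
        assert (r.atp_linked, r.leak, r.nonmito, r.spare) == (60, 30, 10, 20)
        assert r.basal == 90 and r.maximal == 110

    def test_csv_roundtrip(self, tmp_path):
        traces = synthgen.generate_trace_study(
            {"a": (60, 30, 10, 20), "b": (40, 25, 10, 15)},
            wells_per_group=2, noise_sd=2.0, seed=3, cell_count=100,
        )
        path = tmp_path / "traces.csv"
        synthgen.traces_to_csv(traces, path)
        back = synthgen.traces_from_csv(path)
        assert len(back) == 4
        np.testing.assert_allclose(
            back[0].measurements["ocr"], traces[0].measurements["ocr"]
        )
        assert back[0].cell_count == 100
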