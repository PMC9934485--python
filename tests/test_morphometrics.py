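"""Unit and property tests for skeletonization and network morphometrics."""

import numpy as np
import pytest

from mitomorph.imgproc import BinaryMask
from mitomorph.morphometrics import (
    compute_morphometrics,
    extract_graph,
    skeletonize,
)
from mitomorph import synthgen
from oracles import branch_lengths_by_walk

SQRT2 = np.sqrt(2.0)


def as_mask(arr, pixel_size=1.0):
    return BinaryMask(np.asarray(arr, bool), 0.0, pixel_size)


def blank(shape=(24, 24)):
    return np.zeros(shape, dtype=bool)


class TestSkeletonize:
    def test_thick_bar_thins_to_midline(self):
        m = blank((12, 30))
        m[4:7, 4:24] = True  # 3 px wide, 20 long
        skel = skeletonize(as_mask(m)).mask
        assert skel.sum() > 0
        assert (skel & ~m).sum() == 0  # subset of input
        # one pixel wide: no 2x2 block
        assert not (skel[:-1, :-1] & skel[:-1, 1:] & skel[1:, :-1] & skel[1:, 1:]).any()
        # same connectivity: single component
        from scipy import ndimage
        assert ndimage.label(skel, np.ones((3, 3)))[1] == 1
        # one pixel per column and essentially the midline row
        cols = np.argwhere(skel)[:, 1]
        assert len(cols) == len(np.unique(cols))
        rows = np.argwhere(skel)[:, 0]
        assert np.median(rows) == 5 and np.abs(rows - 5).max() <= 1

    def test_single_pixel_survives(self):
        m = blank()
        m[5, 5] = True
        skel = skeletonize(as_mask(m)).mask
        assert skel.sum() == 1 and skel[5, 5]

    def test_filled_disc_keeps_topology(self):
        from scipy import ndimage
        yy, xx = np.mgrid[:24, :24]
        m = (yy - 12) ** 2 + (xx - 12) ** 2 <= 25
        skel = skeletonize(as_mask(m)).mask
        # one component, no holes (Euler number preserved)
        assert ndimage.label(skel, np.ones((3, 3)))[1] == 1
        holes = ndimage.label(~skel)[1]
        assert holes == 1  # only the outer background region

    def test_empty_mask_gives_empty_skeleton(self):
        skel = skeletonize(as_mask(blank()))
        assert not skel.mask.any()


class TestExtractGraph:
    def test_straight_horizontal_line(self):
        m = blank()
        m[10, 5:16] = True  # 11 pixels
        g = extract_graph(as_mask(m, pixel_size=1.0))
        assert len(g.branches) == 1
        assert g.n_endpoints == 2 and g.n_junctions == 0
        assert g.branches[0].length == pytest.approx(10.0)

    def test_straight_diagonal_line(self):
        m = blank()
        for i in range(11):
            m[5 + i, 5 + i] = True
        g = extract_graph(as_mask(m))
        assert len(g.branches) == 1
        assert g.branches[0].length == pytest.approx(10 * SQRT2)

    def test_t_shape_matches_walk_oracle(self):
        m = blank()
        m[4:13, 8] = True       # vertical 9 px
        m[8, 9:13] = True       # 4 px horizontal arm from its center
        g = extract_graph(as_mask(m))
        assert g.n_junctions == 1
        assert g.n_endpoints == 3
        assert len(g.branches) == 3
        got = sorted(b.length for b in g.branches)
        expected = sorted(branch_lengths_by_walk(set(map(tuple, np.argwhere(m)))))
        np.testing.assert_allclose(got, expected)

    def test_pixel_size_scales_lengths(self):
        m = blank()
        m[3, 2:13] = True
        g = extract_graph(as_mask(m, pixel_size=0.2))
        assert g.branches[0].length == pytest.approx(2.0)

    def test_thick_input_rejected(self):
        m = blank()
        m[4:9, 4:9] = True  # solid 5x5 blob
        with pytest.raises(ValueError, match="skeletonize"):
            extract_graph(as_mask(m))

    def test_isolated_cycle_is_single_circular_branch(self):
        m = blank()
        # 8-connected diamond ring
        ring = [(5, 7), (6, 6), (7, 5), (8, 6), (9, 7), (8, 8), (7, 9), (6, 8)]
        for p in ring:
            m[p] = True
        g = extract_graph(as_mask(m))
        assert g.n_structures == 1
        assert len(g.branches) == 1
        assert g.branches[0].nodes[0] == g.branches[0].nodes[1]
        assert g.branches[0].length == pytest.approx(8 * SQRT2)

    def test_sum_of_component_lengths_is_conserved(self, rng):
        truth = synthgen.generate_network(
            6, seed=99,
            params=synthgen.ImagingParams(psf_sigma=0, noise_sd=0),
        )
        skel = as_mask(synthgen.rasterize(truth), truth.params.pixel_size)
        g = extract_graph(skel)
        total = g.branch_lengths().sum()
        per_structure = sum(
            g.branch_lengths(s).sum() for s in range(g.n_structures)
        )
        assert per_structure == pytest.approx(total)
        assert sum(
            len([b for b in g.branches if b.structure == s])
            for s in range(g.n_structures)
        ) == len(g.branches)


class TestComputeMorphometrics:
    def test_single_line_is_individual_without_network_size(self):
        m = blank()
        m[10, 5:16] = True
        mask = as_mask(m)
        g = extract_graph(mask)
        rec = compute_morphometrics(g, mask)
        assert rec.mean_branch_length == pytest.approx(10.0)
        assert rec.n_individuals == 1 and rec.n_networks == 0
        assert np.isnan(rec.mean_summed_branch_length)
        assert "no_networks" in rec.flags

    def test_t_network_arithmetic(self):
        m = blank()
        m[4:13, 8] = True   # two 4-px arms from the junction
        m[8, 9:14] = True   # one 5-px arm
        mask = as_mask(m)
        rec = compute_morphometrics(extract_graph(mask), mask)
        assert rec.n_networks == 1 and rec.n_individuals == 0
        assert rec.mean_branch_length == pytest.approx(13.0 / 3.0)
        assert rec.mean_summed_branch_length == pytest.approx(13.0)

    def test_mixed_networks_and_individual(self):
        m = blank((30, 40))
        # network 1: T with arms 4, 4, 4 -> summed 12
        m[2:11, 5] = True
        m[6, 6:10] = True
        # network 2: T with arms 3, 3, 2 -> summed 8
        m[15:22, 5] = True
        m[18, 6:8] = True
        # individual: straight 3
        m[26, 20:24] = True
        mask = as_mask(m)
        rec = compute_morphometrics(extract_graph(mask), mask)
        assert rec.n_networks == 2 and rec.n_individuals == 1
        assert rec.mean_summed_branch_length == pytest.approx(10.0)
        assert rec.mean_branch_length == pytest.approx(23.0 / 7.0)

    def test_empty_skeleton_flagged(self):
        mask = as_mask(blank())
        rec = compute_morphometrics(extract_graph(mask), mask)
        assert rec.n_branches == 0
        assert np.isnan(rec.mean_branch_length)
        assert "empty_skeleton" in rec.flags


class TestGeometricInvariance:
    def _mean_branch_length(self, m):
        mask = as_mask(m)
        return compute_morphometrics(extract_graph(mask), mask).mean_branch_length

    def test_translation_and_rotation_invariant(self):
        m = blank((40, 40))
        m[10:19, 12] = True
        m[14, 13:18] = True
        base = self._mean_branch_length(m)
        assert self._mean_branch_length(np.roll(m, (7, 5), axis=(0, 1))) == \
            pytest.approx(base)
        assert self._mean_branch_length(np.rot90(m)) == pytest.approx(base)


class TestEndToEndRecovery:
    def test_noise_free_topology_and_lengths_recovered(self, noise_free_params):
        """Render → threshold → thin → graph recovers the generated truth."""
        from mitomorph.imgproc import binarize, otsu_threshold
        from scipy import ndimage

        truth = synthgen.generate_network(5, seed=12345,
                                          params=noise_free_params)
        img = synthgen.render_image(truth, noise_free_params, seed=1)
        mask = binarize(img, otsu_threshold(img))
        g = extract_graph(skeletonize(mask))

        assert g.n_structures == len(truth.structures)
        assert g.n_junctions == sum(s.n_junctions for s in truth.structures)
        assert g.n_endpoints == sum(s.n_endpoints for s in truth.structures)
        got = np.sort(g.branch_lengths())
        want = np.sort(truth.all_branch_lengths())
        np.testing.assert_allclose(got, want, atol=1e-9)
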