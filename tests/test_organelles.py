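"""Per-cell organelle statistics: counting rules, flux, distances, intensities."""

import numpy as np
import pandas as pd
import pytest

from mitoquant.image_core import BinaryMask, Image2D, LabeledMask
from mitoquant.organelles import (
    classify_depolarized,
    compute_flux,
    count_mitolysosomes,
    count_touching_puncta,
    cytoplasmic_mean_intensity,
    lysosome_distribution,
    mean_intensity_in_mask,
    mito_mass,
    mito_morphology,
    nuclear_mean_intensity,
    touching_object_ids,
)

from conftest import grid_cells, make_image, make_labels, make_mask
from oracles import percentile_by_sort, touching_ids_brute


def one_cell_seg(shape=(12, 12), px=1.0):
    from mitoquant.segmentation import CellSegmentation

    cells = np.ones(shape, dtype=np.int32)
    nuclei = np.zeros(shape, dtype=np.int32)
    nuclei[1:3, 1:3] = 1
    return CellSegmentation(
        nuclei=LabeledMask(nuclei, px, 1), cells=LabeledMask(cells, px, 1)
    )


class TestTouchingPredicate:
    def test_toy_overlap_adjacent_isolated(self):
        # GFP mask: a vertical bar; puncta: overlapping, 8-adjacent, isolated
        gfp = np.zeros((12, 12), dtype=bool)
        gfp[2:10, 5] = True
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[3, 5] = 1  # overlaps the bar
        labels[6, 6] = 2  # 8-adjacent (diagonal neighbor is [5..] col 5)
        labels[3, 9] = 3  # isolated
        lab = make_labels(labels)
        mask = make_mask(gfp)
        assert touching_object_ids(lab, mask) == {1, 2}
        assert touching_ids_brute(labels, gfp) == {1, 2}

    def test_matches_brute_force_on_random_fields(self, rng):
        for _ in range(25):
            mask = rng.random((15, 15)) < 0.2
            labels = np.zeros((15, 15), dtype=np.int32)
            n = 0
            for _k in range(6):
                y, x = rng.integers(0, 15, 2)
                if labels[y, x] == 0:
                    n += 1
                    labels[y, x] = n
            lab = LabeledMask(labels, 1.0, n)
            assert touching_object_ids(lab, make_mask(mask)) == touching_ids_brute(
                labels, mask
            )


class TestCountMitolysosomes:
    def test_empty_labeling_all_zero(self):
        seg = one_cell_seg()
        out = count_mitolysosomes(
            seg,
            make_mask(np.zeros((12, 12), dtype=bool)),
            LabeledMask(np.zeros((12, 12), dtype=np.int32), 1.0, 0),
        )
        assert out["n_mitolysosomes"].tolist() == [0]

    def test_toy_counts_exclude_touching(self):
        seg = one_cell_seg()
        gfp = np.zeros((12, 12), dtype=bool)
        gfp[2:10, 5] = True
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[3, 5] = 1
        labels[6, 6] = 2
        labels[3, 9] = 3
        out = count_mitolysosomes(seg, make_mask(gfp), make_labels(labels))
        row = out.iloc[0]
        assert row["n_puncta"] == 3
        assert row["n_touching_gfp"] == 2
        assert row["n_mitolysosomes"] == 1

    def test_partition_property(self, rng):
        seg = one_cell_seg()
        mask = rng.random((12, 12)) < 0.25
        labels = np.zeros((12, 12), dtype=np.int32)
        n = 0
        for _k in range(8):
            y, x = rng.integers(0, 12, 2)
            if labels[y, x] == 0:
                n += 1
                labels[y, x] = n
        out = count_mitolysosomes(seg, make_mask(mask), LabeledMask(labels, 1.0, n))
        row = out.iloc[0]
        assert row["n_puncta"] == row["n_touching_gfp"] + row["n_mitolysosomes"]

    def test_no_retained_cells_is_error(self):
        from mitoquant.segmentation import CellSegmentation

        seg = CellSegmentation(
            nuclei=LabeledMask(np.zeros((5, 5), dtype=np.int32), 1.0, 0),
            cells=LabeledMask(np.zeros((5, 5), dtype=np.int32), 1.0, 0),
        )
        with pytest.raises(ValueError, match="no retained cells"):
            count_mitolysosomes(
                seg,
                make_mask(np.zeros((5, 5), dtype=bool)),
                LabeledMask(np.zeros((5, 5), dtype=np.int32), 1.0, 0),
            )


class TestComputeFlux:
    def test_equal_means_ratio_one(self):
        assert compute_flux([6, 6], [6, 6]).flux_ratio == pytest.approx(1.0)

    def test_arithmetic(self):
        res = compute_flux([2, 4, 6], [8, 8, 8])
        assert res.flux_ratio == pytest.approx(2.0)
        assert (res.mean_minus, res.mean_plus) == (4.0, 8.0)

    def test_scale_equivariance(self, rng):
        a = rng.poisson(6, 40)
        b = rng.poisson(12, 40)
        r1 = compute_flux(a, b).flux_ratio
        r2 = compute_flux(3 * a, 3 * b).flux_ratio
        assert r1 == pytest.approx(r2)

    def test_zero_minus_mean_undefined(self):
        res = compute_flux([0, 0], [3, 5])
        assert not res.defined
        assert np.isnan(res.flux_ratio)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            compute_flux([], [1, 2])


class TestMitoMass:
    def test_empty_mask_zero(self):
        seg = grid_cells(n=3)
        out = mito_mass(seg, make_mask(np.zeros(seg.cells.shape, dtype=bool)))
        assert (out == 0).all()

    def test_area_arithmetic(self):
        seg = one_cell_seg(px=0.3)
        mask = np.zeros((12, 12), dtype=bool)
        mask.ravel()[:100] = True
        out = mito_mass(seg, BinaryMask(mask, 0.3))
        assert out.loc[1] == pytest.approx(100 * 0.09)

    def test_matches_per_pixel_accumulation(self, rng):
        seg = grid_cells(n=4, px=0.5)
        mask = rng.random(seg.cells.shape) < 0.4
        out = mito_mass(seg, BinaryMask(mask, 0.5))
        for cid in seg.retained_ids:
            expected = (mask & (seg.cells.labels == cid)).sum() * 0.25
            assert out.loc[cid] == pytest.approx(expected)


class TestClassifyDepolarized:
    @staticmethod
    def build_field(px=0.5):
        """One cell; 2 large + 3 small mass objects, 1 small with dark TMRE."""
        seg = one_cell_seg(shape=(30, 30), px=px)
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[5:10, 5:10] = 1   # large (25 px = 6.25 um^2)
        labels[5:10, 15:20] = 2  # large
        labels[15, 5] = 3        # small, polarized
        labels[15, 15] = 4       # small, depolarized (below background)
        labels[20, 20] = 5       # small, polarized
        tmre = np.full((30, 30), 10.0)
        tmre[labels == 1] = 200.0
        tmre[labels == 2] = 200.0
        tmre[labels == 3] = 200.0
        tmre[labels == 4] = 9.0
        tmre[labels == 5] = 180.0
        return seg, LabeledMask(labels, px, 5), Image2D(tmre, px)

    def test_counts_small_and_depolarized(self):
        seg, labels, tmre = self.build_field()
        res = classify_depolarized(seg, labels, tmre, area_cutoff_um2=1.0, bg_k=3.0)
        row = res.per_cell.iloc[0]
        assert row["n_individualized_small"] == 3
        assert row["n_depolarized"] == 1

    def test_all_large_objects_zero_counts(self):
        seg, labels, tmre = self.build_field()
        res = classify_depolarized(seg, labels, tmre, area_cutoff_um2=0.01)
        row = res.per_cell.iloc[0]
        assert row["n_individualized_small"] == 0
        assert row["n_depolarized"] == 0

    def test_additive_tmre_offset_invariance(self):
        seg, labels, tmre = self.build_field()
        base = classify_depolarized(seg, labels, tmre).per_cell
        shifted = classify_depolarized(
            seg, labels, Image2D(tmre.pixels + 37.5, tmre.pixel_size_um)
        ).per_cell
        pd.testing.assert_frame_equal(base, shifted)

    def test_relabeling_invariance(self):
        seg, labels, tmre = self.build_field()
        base = classify_depolarized(seg, labels, tmre).per_cell
        perm = np.array([0, 3, 5, 1, 4, 2])  # permute object ids
        relabeled = LabeledMask(perm[labels.labels], labels.pixel_size_um, 5)
        out = classify_depolarized(seg, relabeled, tmre).per_cell
        pd.testing.assert_frame_equal(base, out)

    def test_full_coverage_mask_is_error(self):
        seg = one_cell_seg(shape=(8, 8))
        labels = LabeledMask(np.ones((8, 8), dtype=np.int32), 1.0, 1)
        with pytest.raises(ValueError, match="background"):
            classify_depolarized(seg, labels, Image2D(np.zeros((8, 8)), 1.0))


class TestCountTouchingPuncta:
    def test_disjoint_with_gap_zero(self):
        seg = one_cell_seg()
        mask = np.zeros((12, 12), dtype=bool)
        mask[0:3, 0:3] = True
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[8:10, 8:10] = 1
        out = count_touching_puncta(seg, make_labels(labels), make_mask(mask))
        assert out.iloc[0]["n_touching"] == 0

    def test_partial_overlap_counts(self):
        seg = one_cell_seg()
        mask = np.zeros((12, 12), dtype=bool)
        mask[:, 0:6] = True
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[2, 5:8] = 1   # overlaps
        labels[5, 6] = 2     # 8-adjacent to column 5
        labels[8, 9:11] = 3  # away
        labels[10, 2:4] = 4  # inside
        labels[0, 10] = 5    # away
        out = count_touching_puncta(seg, make_labels(labels), make_mask(mask))
        assert out.iloc[0]["n_touching"] == 3  # objects 1, 2, 4

    def test_containment_counts_once(self):
        seg = one_cell_seg()
        mask = np.ones((12, 12), dtype=bool)
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[4:6, 4:6] = 1
        out = count_touching_puncta(seg, make_labels(labels), make_mask(mask))
        assert out.iloc[0]["n_vesicles"] == 1
        assert out.iloc[0]["n_touching"] == 1


class TestLysosomeDistribution:
    @staticmethod
    def seg_with_vesicles(distances_px, px=1.0, shape=(40, 60)):
        """One cell, nucleus block, vesicles at given x-offsets from nucleus."""
        from mitoquant.segmentation import CellSegmentation

        cells = np.ones(shape, dtype=np.int32)
        nuclei = np.zeros(shape, dtype=np.int32)
        nuclei[18:22, 0:4] = 1
        labels = np.zeros(shape, dtype=np.int32)
        for i, d in enumerate(distances_px, start=1):
            # rows stay within the nucleus rows so the nearest nucleus pixel
            # is on the same row and the distance equals the column offset
            labels[18 + ((i - 1) % 4), 3 + int(d)] = i
        seg = CellSegmentation(
            nuclei=LabeledMask(nuclei, px, 1), cells=LabeledMask(cells, px, 1)
        )
        return seg, LabeledMask(labels, px, len(distances_px))

    def test_tie_rule_zero_peripheral(self):
        seg, labels = self.seg_with_vesicles([5, 5, 5, 5])
        areas = pd.Series({1: 10.0})
        res = lysosome_distribution(seg, labels, seg.nuclei, areas)
        assert res.percentile_threshold_um == pytest.approx(5.0)
        assert res.per_cell.iloc[0]["peripheral_count"] == 0

    def test_quartet_matches_sort_percentile(self):
        seg, labels = self.seg_with_vesicles([1, 2, 3, 4])
        areas = pd.Series({1: 2.0})
        res = lysosome_distribution(seg, labels, seg.nuclei, areas)
        assert res.percentile_threshold_um == pytest.approx(3.25)
        assert res.percentile_threshold_um == pytest.approx(
            percentile_by_sort(res.distances_um["distance_um"].to_numpy(), 75)
        )
        assert res.per_cell.iloc[0]["peripheral_count"] == 1
        assert res.per_cell.iloc[0]["peripheral_per_mito_area"] == pytest.approx(0.5)

    def test_self_reference_marks_at_most_quarter(self, rng):
        # exact bound under the linear-interpolation percentile convention
        d = rng.uniform(1, 30, 120).astype(int)
        seg, labels = self.seg_with_vesicles(sorted(set(d.tolist())), shape=(40, 80))
        areas = pd.Series({1: 1.0})
        res = lysosome_distribution(seg, labels, seg.nuclei, areas)
        dd = res.distances_um["distance_um"].to_numpy()
        n_peripheral = int((dd > res.percentile_threshold_um).sum())
        assert n_peripheral <= np.ceil(0.25 * (dd.size - 1))

    def test_reference_distances_override_threshold(self):
        seg, labels = self.seg_with_vesicles([1, 2, 3, 4])
        areas = pd.Series({1: 1.0})
        res = lysosome_distribution(
            seg, labels, seg.nuclei, areas, reference_distances=np.array([0.5, 1.0]),
            reference_condition="control",
        )
        assert res.percentile_threshold_um == pytest.approx(0.875)
        assert res.per_cell.iloc[0]["peripheral_count"] == 4
        assert res.reference_condition == "control"

    def test_cell_without_nucleus_is_error(self):
        from mitoquant.segmentation import CellSegmentation

        cells = np.ones((10, 10), dtype=np.int32)
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[5, 5] = 1
        seg = CellSegmentation(
            nuclei=LabeledMask(np.zeros((10, 10), dtype=np.int32), 1.0, 0),
            cells=LabeledMask(cells, 1.0, 1),
        )
        with pytest.raises(ValueError, match="no nucleus"):
            lysosome_distribution(
                seg, LabeledMask(labels, 1.0, 1), seg.nuclei, pd.Series({1: 1.0})
            )


class TestIntensityStats:
    def test_constant_image_mean(self):
        img = make_image(np.full((6, 6), 7.0))
        mask = make_mask(np.ones((6, 6), dtype=bool))
        assert mean_intensity_in_mask(img, mask) == pytest.approx(7.0)

    def test_two_pixel_mean(self):
        img = make_image([[2.0, 4.0], [0.0, 0.0]])
        mask = make_mask([[True, True], [False, False]])
        assert mean_intensity_in_mask(img, mask) == pytest.approx(3.0)

    def test_empty_mask_is_nan(self):
        img = make_image(np.zeros((4, 4)))
        assert np.isnan(mean_intensity_in_mask(img, make_mask(np.zeros((4, 4), dtype=bool))))

    def test_matches_loop_mean(self, rng):
        img = rng.uniform(0, 10, (10, 10))
        mask = rng.random((10, 10)) < 0.5
        expected = np.mean([img[y, x] for y in range(10) for x in range(10) if mask[y, x]])
        assert mean_intensity_in_mask(make_image(img), make_mask(mask)) == pytest.approx(expected)

    def test_nuclear_mean_zero_marker(self):
        seg = grid_cells(n=3)
        out = nuclear_mean_intensity(seg, make_image(np.zeros(seg.nuclei.shape)))
        assert (out == 0).all()

    def test_uniform_marker_nuclear_equals_cyto(self):
        seg = grid_cells(n=3)
        img = make_image(np.full(seg.cells.shape, 11.0))
        nuc = nuclear_mean_intensity(seg, img)
        cyt = cytoplasmic_mean_intensity(seg, img)
        assert nuc.tolist() == pytest.approx(cyt.tolist())

    def test_permutation_invariance_of_per_cell_stats(self, rng):
        seg = grid_cells(n=5)
        img = make_image(rng.uniform(0, 50, seg.cells.shape))
        base = nuclear_mean_intensity(seg, img)
        assert sorted(base.index) == list(range(1, 6))
        # values do not depend on iteration order of ids
        again = nuclear_mean_intensity(seg, img)
        pd.testing.assert_series_equal(base, again)


class TestMitoMorphology:
    def test_empty_labeling(self):
        out = mito_morphology(LabeledMask(np.zeros((5, 5), dtype=np.int32), 1.0, 0))
        assert out["n_objects"] == 0
        assert out["total_area_um2"] == 0.0

    def test_counts_and_total_area(self):
        arr = np.zeros((10, 10), dtype=np.int32)
        arr[1:3, 1:5] = 1
        arr[6:9, 6:9] = 2
        out = mito_morphology(LabeledMask(arr, 0.5, 2))
        assert out["n_objects"] == 2
        assert out["total_area_um2"] == pytest.approx((8 + 9) * 0.25)
        assert out["aspect_ratio_weighted"] >= 1.0
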