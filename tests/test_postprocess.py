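"""The six-parameter refinement chain and its GA tuning."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from nucseg import (
    InstanceSet,
    PostprocessParams,
    ProbabilityMap,
    dsb_score,
    merge_surrounded,
    optimize_params,
    postprocess_chain,
    remove_contained,
    remove_low_confidence,
    remove_small,
    unet_correct,
)
from nucseg.postprocess import STRUCTURE


def rect(r0, c0, h, w):
    yy, xx = np.mgrid[r0 : r0 + h, c0 : c0 + w]
    return np.stack([yy.ravel(), xx.ravel()], axis=1)


def raster_prob(s: InstanceSet) -> ProbabilityMap:
    return ProbabilityMap((s.to_label_image() > 0).astype(float))


class TestRemoveContained:
    def test_disjoint_unchanged(self):
        s = InstanceSet(20, 20, [rect(0, 0, 5, 5), rect(10, 10, 5, 5)])
        assert len(remove_contained(s)) == 2

    def test_nested_object_removed(self):
        s = InstanceSet(20, 20, [rect(0, 0, 10, 10), rect(3, 3, 3, 3)])
        out = remove_contained(s)
        assert len(out) == 1 and out.objects[0].shape[0] == 100

    def test_idempotent(self):
        s = InstanceSet(20, 20, [rect(0, 0, 10, 10), rect(3, 3, 3, 3), rect(12, 12, 4, 4)])
        once = remove_contained(s)
        twice = remove_contained(once)
        assert [o.shape[0] for o in once.objects] == [o.shape[0] for o in twice.objects]


class TestMergeSurrounded:
    def test_isolated_objects_unchanged(self):
        s = InstanceSet(30, 30, [rect(0, 0, 5, 5), rect(20, 20, 5, 5)])
        assert len(merge_surrounded(s, 0.17)) == 2

    def test_heavily_surrounded_object_merges(self):
        # small object sharing most of its boundary with a big neighbor
        big = np.argwhere(~(np.zeros((12, 12), dtype=bool)))
        big_mask = np.zeros((20, 20), dtype=bool)
        big_mask[0:12, 0:12] = True
        big_mask[4:8, 4:8] = False  # cavity
        small = rect(4, 4, 4, 4)  # sits inside the cavity, fully surrounded
        s = InstanceSet(20, 20, [np.argwhere(big_mask), small])
        out = merge_surrounded(s, 0.17)
        assert len(out) == 1
        assert out.labels == [1]  # union keeps the surrounding object's label
        assert out.objects[0].shape[0] == 144

    def test_p1_one_blocks_merging(self):
        big_mask = np.zeros((20, 20), dtype=bool)
        big_mask[0:12, 0:12] = True
        big_mask[4:8, 4:8] = False
        s = InstanceSet(20, 20, [np.argwhere(big_mask), rect(4, 4, 4, 4)])
        assert len(merge_surrounded(s, 1.0)) == 2


class TestRemoveSmall:
    def test_zero_threshold_identity(self):
        s = InstanceSet(20, 20, [rect(0, 0, 2, 5), rect(10, 0, 5, 5)])
        assert len(remove_small(s, 0)) == 2

    def test_strictly_smaller_removed(self):
        s = InstanceSet(30, 30, [rect(0, 0, 2, 5), rect(5, 5, 4, 11), rect(15, 15, 10, 10)])
        out = remove_small(s, 44)  # areas 10, 44, 100 -> strict '<' keeps 44
        assert sorted(o.shape[0] for o in out.objects) == [44, 100]

    def test_huge_threshold_empties(self):
        s = InstanceSet(20, 20, [rect(0, 0, 5, 5)])
        assert len(remove_small(s, 1e9)) == 0


class TestUnetCorrect:
    def test_zero_margins_identity(self):
        s = InstanceSet(20, 20, [rect(5, 5, 6, 6)])
        out = unet_correct(s, ProbabilityMap(np.zeros((20, 20))), 0.5, 0, 0)
        np.testing.assert_array_equal(out.objects[0], s.objects[0])

    def test_prob_one_dilates(self):
        s = InstanceSet(30, 30, [rect(10, 10, 6, 6)])
        out = unet_correct(s, ProbabilityMap(np.ones((30, 30))), 0.9, 1, 1)
        expect = ndi.binary_dilation(s.object_mask(0), structure=STRUCTURE)
        np.testing.assert_array_equal(out.object_mask(0), expect)

    def test_prob_zero_erodes(self):
        s = InstanceSet(30, 30, [rect(10, 10, 6, 6)])
        out = unet_correct(s, ProbabilityMap(np.zeros((30, 30))), 0.5, 1, 1)
        expect = ndi.binary_erosion(s.object_mask(0), structure=STRUCTURE, border_value=0)
        np.testing.assert_array_equal(out.object_mask(0), expect)

    def test_contested_band_pixels_go_to_nearest_object(self):
        # two rectangles one blank column apart; prob 1 makes both claim it
        s = InstanceSet(20, 21, [rect(5, 2, 6, 8), rect(5, 11, 6, 8)])
        out = unet_correct(s, ProbabilityMap(np.ones((20, 21))), 0.5, 0, 1)
        flat_counts = sum(o.shape[0] for o in out.objects)
        assert (out.to_label_image() > 0).sum() == flat_counts  # no double claim
        assert len(out) == 2

    def test_emptied_object_dropped(self):
        s = InstanceSet(20, 20, [rect(5, 5, 2, 2)])
        out = unet_correct(s, ProbabilityMap(np.zeros((20, 20))), 0.5, 2, 0)
        assert len(out) == 0


class TestRemoveLowConfidence:
    def test_zero_floor_identity(self):
        s = InstanceSet(20, 20, [rect(0, 0, 4, 4)])
        assert len(remove_low_confidence(s, ProbabilityMap(np.zeros((20, 20))), 0.0)) == 1

    def test_low_mean_removed(self):
        s = InstanceSet(20, 20, [rect(0, 0, 4, 4)])
        assert len(remove_low_confidence(s, ProbabilityMap(np.full((20, 20), 0.5)), 0.8)) == 0

    def test_mean_rule_strict(self):
        s = InstanceSet(20, 20, [rect(0, 0, 1, 4)])
        vals = np.zeros((20, 20))
        vals[0, :4] = [1.0, 1.0, 0.6, 0.6]  # mean exactly 0.8 -> kept (strict '<')
        assert len(remove_low_confidence(s, ProbabilityMap(vals), 0.8)) == 1


class TestChain:
    def test_perfect_prediction_stable_up_to_boundary(self, toy_data):
        _, gt = toy_data[0]
        out = postprocess_chain(gt, raster_prob(gt), PostprocessParams(p2=10))
        assert len(out) == len(gt)
        assert dsb_score(out, gt) >= 0.99

    def test_debris_removed_by_defaults(self, toy_data):
        _, gt = toy_data[1]
        debris = [rect(1, 1, 3, 3), rect(1, 120, 3, 3)]  # 9 px < 44
        pred = InstanceSet(gt.height, gt.width, [o.copy() for o in gt.objects] + debris)
        prob = raster_prob(pred)
        out = postprocess_chain(pred, prob)
        assert len(out) == len(gt)

    def test_background_probability_with_high_floor_empties(self, toy_data):
        _, gt = toy_data[2]
        out = postprocess_chain(gt, ProbabilityMap(np.zeros(gt.shape)), PostprocessParams(p6=0.8))
        assert len(out) == 0

    def test_stage_switches(self, toy_data):
        _, gt = toy_data[3]
        debris = [rect(0, 0, 2, 2)]
        pred = InstanceSet(gt.height, gt.width, [o.copy() for o in gt.objects] + debris)
        out = postprocess_chain(pred, raster_prob(pred), stages=(False, False, False, False, False))
        assert len(out) == len(pred)

    def test_object_count_never_increases(self, toy_data):
        for _, gt in toy_data[:4]:
            out = postprocess_chain(gt, raster_prob(gt))
            assert len(out) <= len(gt)


class TestOptimizeParams:
    def test_smoke_population_one(self, toy_data):
        _, gt = toy_data[0]
        train = [(gt, raster_prob(gt), gt)]
        a = optimize_params(train, population=1, generations=0, seed=3)
        b = optimize_params(train, population=1, generations=0, seed=3)
        assert a == b  # deterministic best-of-init

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            optimize_params([])

    def test_improves_over_default(self, toy_data):
        _, gt = toy_data[4]
        debris = [rect(2, 2, 7, 7)]  # 49 px: survives the default p2=44
        pred = InstanceSet(gt.height, gt.width, [o.copy() for o in gt.objects] + debris)
        prob = raster_prob(pred)
        train = [(pred, prob, gt)]
        best = optimize_params(train, population=16, generations=8, seed=0)
        tuned = np.mean([dsb_score(postprocess_chain(p, pr, best), g) for p, pr, g in train])
        default = np.mean([dsb_score(postprocess_chain(p, pr, PostprocessParams()), g) for p, pr, g in train])
        assert tuned >= default
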