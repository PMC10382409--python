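"""Evaluation framework: components vs flood fill, SAD conventions,
matching semantics, metric closed forms, and report accounting."""

import numpy as np
import pytest

from foveal3d.core import NodeLabelMap, ValidationError
from foveal3d.evaluate import (EvalConfig, build_report,
                               connected_components, evaluate_volume,
                               false_positive_review,
                               filter_small_components, global_dice_tp,
                               localization_rate, match_nodes, measure_sad,
                               node_sensitivity)
from foveal3d.infer import threshold_probability
from tests.conftest import make_ellipsoid_mask


def flood_fill_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Brute-force BFS flood fill oracle, independent of scipy labeling."""
    from collections import deque
    if connectivity == 6:
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
                (0, 0, -1)]
    else:
        offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    out = np.zeros(mask.shape, dtype=np.int32)
    nxt = 0
    for start in map(tuple, np.argwhere(mask)):
        if out[start]:
            continue
        nxt += 1
        q = deque([start])
        out[start] = nxt
        while q:
            p = q.popleft()
            for o in offs:
                nb = tuple(np.add(p, o))
                if all(0 <= nb[a] < mask.shape[a] for a in range(3)) \
                        and mask[nb] and not out[nb]:
                    out[nb] = nxt
                    q.append(nb)
    return out


class TestConnectedComponents:
    def test_separated_cubes_are_two_components(self):
        m = np.zeros((15, 15, 15), dtype=bool)
        m[1:6, 1:6, 1:6] = True
        m[8:13, 1:6, 1:6] = True  # 2-voxel gap along x
        assert len(connected_components(m).components) == 2

    def test_face_sharing_cubes_merge(self):
        m = np.zeros((15, 15, 15), dtype=bool)
        m[1:6, 1:6, 1:6] = True
        m[6:11, 1:6, 1:6] = True
        assert len(connected_components(m).components) == 1

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle_on_random_masks(self, connectivity):
        rng = np.random.default_rng(99)
        for _ in range(5):
            m = rng.uniform(size=(20, 20, 20)) < 0.25
            cs = connected_components(m, connectivity)
            oracle = flood_fill_components(m, connectivity)
            assert len(cs.components) == oracle.max()
            # identical partition: component of every voxel pair agrees
            a = cs.labels[m]
            b = oracle[m]
            pairing = {}
            for x, y in zip(a, b):
                assert pairing.setdefault(x, y) == y


class TestFilter:
    @pytest.mark.parametrize("n_voxels,kept", [(26, False), (27, True),
                                               (8, False), (1000, True)])
    def test_less_than_27_voxels_excluded(self, n_voxels, kept):
        m = np.zeros((30, 30, 30), dtype=bool)
        flat = np.argwhere(np.ones((10, 10, 10), dtype=bool))[:n_voxels]
        for p in flat:  # a compact connected blob of exactly n voxels
            m[tuple(p + 1)] = True
        cs = connected_components(m)
        assert len(cs.components) == 1
        filter_small_components(cs, 27)
        assert (cs.components[0].status != "filtered") == kept

    def test_mixed_sizes_enumerated(self):
        m = np.zeros((40, 40, 40), dtype=bool)
        m[1:3, 1:2, 1:4] = True          # 8 voxels -> filtered
        m[10:13, 10:13, 10:13] = True    # 27 voxels -> kept
        m[20:30, 20:30, 20:30] = True    # 1000 voxels -> kept
        cs = filter_small_components(connected_components(m), 27)
        assert sorted(c.voxel_count for c in cs.retained()) == [27, 1000]


class TestMeasureSAD:
    def test_sphere_diameter(self):
        m = make_ellipsoid_mask((32, 32, 32), (16, 16, 16), (7, 7, 7))
        assert measure_sad(m) == pytest.approx(14.0, abs=1.0)

    def test_axis_aligned_ellipsoid_short_axis(self):
        # semi-axes (10, 6, 4) mm: largest axial ellipse is 20 x 12 mm
        m = make_ellipsoid_mask((48, 48, 48), (24, 24, 24), (10, 6, 4))
        assert measure_sad(m) == pytest.approx(12.0, abs=1.0)

    def test_rotated_ellipsoid_invariant_in_plane(self):
        from foveal3d.phantom import _node_mask
        for deg in (0.0, 30.0, 75.0):
            m = _node_mask((48, 48, 48), (1, 1, 1), (24, 24, 24),
                           (10, 6, 4), deg)
            assert measure_sad(m) == pytest.approx(12.0, abs=1.0), deg

    def test_single_voxel_is_one_voxel_extent(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        assert measure_sad(m, (1.0, 1.0, 1.0)) == pytest.approx(1.0)

    def test_anisotropic_spacing_respected(self):
        m = np.zeros((5, 9, 3), dtype=bool)
        m[2, 2:7, 1] = True  # 5 voxels along y at 2 mm spacing: 10 x 0.5 mm
        sad = measure_sad(m, (0.5, 2.0, 1.0))
        assert sad == pytest.approx(0.5, abs=1e-6)  # short axis is x extent

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            measure_sad(np.zeros((3, 3, 3), dtype=bool))


def _two_node_truth():
    labels = np.zeros((40, 40, 40), dtype=np.int32)
    labels[make_ellipsoid_mask((40, 40, 40), (12, 12, 12), (5, 4, 4))] = 1
    labels[make_ellipsoid_mask((40, 40, 40), (28, 28, 28), (6, 5, 4))] = 2
    return NodeLabelMap(labels=labels)


class TestMatching:
    def test_perfect_prediction_all_localized_no_fp(self):
        gt = _two_node_truth()
        cs = filter_small_components(
            connected_components(gt.foreground()), 27)
        cs, localized = match_nodes(cs, gt)
        assert all(localized.values())
        assert all(c.status == "TP" for c in cs.retained())

    def test_empty_prediction(self):
        gt = _two_node_truth()
        cs = filter_small_components(
            connected_components(np.zeros(gt.shape, dtype=bool)), 27)
        cs, localized = match_nodes(cs, gt)
        assert not any(localized.values())
        assert sum(c.status == "FP" for c in cs.retained()) == 0

    def test_single_component_credits_touching_nodes(self):
        # two touching nodes covered by one predicted blob: both localized,
        # one TP component, zero FPs
        labels = np.zeros((40, 40, 40), dtype=np.int32)
        labels[10:20, 10:20, 10:20] = 1
        labels[20:30, 10:20, 10:20] = 2
        gt = NodeLabelMap(labels=labels)
        pred = np.zeros((40, 40, 40), dtype=bool)
        pred[8:32, 8:22, 8:22] = True
        cs = filter_small_components(connected_components(pred), 27)
        cs, localized = match_nodes(cs, gt)
        assert localized == {1: True, 2: True}
        assert [c.status for c in cs.retained()] == ["TP"]

    def test_brute_force_set_algebra_on_random_fixture(self):
        """LR / Dice / sensitivity / FP counts against direct numpy set
        algebra on a small random scene."""
        rng = np.random.default_rng(5)
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        labels[2:7, 2:7, 2:7] = 1
        labels[12:18, 12:18, 12:18] = 2
        pred = np.zeros((20, 20, 20), dtype=bool)
        pred[4:9, 2:7, 2:7] = True       # overlaps node 1
        pred[1:5, 12:17, 12:17] = True   # pure FP blob
        gt = NodeLabelMap(labels=labels)
        cs = filter_small_components(connected_components(pred), 27)
        cs, localized = match_nodes(cs, gt)
        # oracle
        gt_fg = labels > 0
        tp_vox = pred & gt_fg
        assert localized[1] is True and localized[2] is False
        assert sum(c.status == "FP" for c in cs.retained()) == 1
        tp_mask = cs.tp_mask()
        dice = global_dice_tp(cs, gt_fg)
        expected_dice = 2 * (tp_mask & gt_fg).sum() / \
            (tp_mask.sum() + gt_fg.sum())
        assert dice == pytest.approx(expected_dice)
        s1 = node_sensitivity(labels == 1, pred)
        assert s1 == pytest.approx((pred & (labels == 1)).sum()
                                   / (labels == 1).sum())


class TestMetricClosedForms:
    def test_pooled_lr_printed_counts(self):
        assert localization_rate([True] * 793 + [False] * 132) == \
            pytest.approx(85.7, abs=0.05)
        assert localization_rate([True] * 102 + [False] * 4) == \
            pytest.approx(96.2, abs=0.05)
        assert localization_rate([True] * 10) == 100.0

    def test_dice_half_coverage_closed_form(self):
        # prediction covering exactly half of the node, no extra voxels:
        # Dice = 2 (G/2) / (G/2 + G) = 2/3
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        labels[4:12, 4:12, 4:12] = 1  # 512 voxels
        gt = NodeLabelMap(labels=labels)
        pred = np.zeros((20, 20, 20), dtype=bool)
        pred[4:8, 4:12, 4:12] = True  # exactly half
        cs = filter_small_components(connected_components(pred), 27)
        cs, _ = match_nodes(cs, gt)
        assert global_dice_tp(cs, gt.foreground()) == pytest.approx(2 / 3)

    def test_fp_component_does_not_change_dice_or_sensitivity(self):
        labels = np.zeros((30, 30, 30), dtype=np.int32)
        labels[4:12, 4:12, 4:12] = 1
        gt = NodeLabelMap(labels=labels)
        base = np.zeros((30, 30, 30), dtype=bool)
        base[4:10, 4:12, 4:12] = True
        with_fp = base.copy()
        with_fp[20:26, 20:26, 20:26] = True  # far-away FP blob
        def run(pred):
            cs = filter_small_components(connected_components(pred), 27)
            cs, _ = match_nodes(cs, gt)
            return global_dice_tp(cs, gt.foreground())
        assert run(base) == pytest.approx(run(with_fp))
        assert node_sensitivity(labels == 1, base) == \
            node_sensitivity(labels == 1, with_fp)

    def test_sensitivity_direct_ratio(self):
        node = np.zeros((10, 10, 10), dtype=bool)
        node[0:4, 0:4, 0:5] = True  # 80 voxels
        pred = np.zeros((10, 10, 10), dtype=bool)
        pred[0:2, 0:4, 0:5] = True  # 40 of them
        assert node_sensitivity(node, pred) == 0.5

    def test_fp_review_accounting(self):
        assert false_positive_review(459, 268, 36, 13) == 142
        with pytest.raises(ValidationError):
            false_positive_review(10, 8, 2, 1)


class TestInvariants:
    def test_statuses_partition_and_counts_add_up(self):
        rng = np.random.default_rng(11)
        labels = np.zeros((24, 24, 24), dtype=np.int32)
        labels[3:9, 3:9, 3:9] = 1
        labels[14:21, 14:21, 14:21] = 2
        gt = NodeLabelMap(labels=labels)
        pred = rng.uniform(size=(24, 24, 24)) < 0.2
        pred[3:9, 3:9, 3:9] = True
        cs = filter_small_components(connected_components(pred), 27)
        cs, localized = match_nodes(cs, gt)
        retained = cs.retained()
        assert all(c.status in ("TP", "FP") for c in retained)
        n_tp = sum(c.status == "TP" for c in retained)
        n_fp = sum(c.status == "FP" for c in retained)
        assert n_tp + n_fp == len(retained)
        assert sum(localized.values()) <= len(gt.node_ids)

    def test_metrics_invariant_to_relabeling_and_translation(self):
        labels = np.zeros((30, 30, 30), dtype=np.int32)
        labels[5:12, 5:12, 5:12] = 1
        labels[18:26, 18:26, 18:26] = 2
        pred = np.zeros((30, 30, 30), dtype=bool)
        pred[5:10, 5:12, 5:12] = True
        def metrics(lbl, prd):
            gt = NodeLabelMap(labels=lbl)
            cs = filter_small_components(connected_components(prd), 27)
            cs, localized = match_nodes(cs, gt)
            return (sorted(localized.values()),
                    global_dice_tp(cs, lbl > 0))
        base = metrics(labels, pred)
        relabeled = np.where(labels == 1, 7, np.where(labels == 2, 3, 0))
        assert metrics(relabeled.astype(np.int32), pred) == base
        shifted_l = np.roll(labels, (2, 1, 3), axis=(0, 1, 2))
        shifted_p = np.roll(pred, (2, 1, 3), axis=(0, 1, 2))
        assert metrics(shifted_l, shifted_p) == base

    def test_random_deletion_gives_expected_sensitivity(self):
        """Prediction = truth with voxels deleted at rate q: mean node
        sensitivity ~= 1 - q."""
        rng = np.random.default_rng(3)
        labels = np.zeros((40, 40, 40), dtype=np.int32)
        nid = 0
        for cx in (8, 20, 32):
            for cy in (8, 20, 32):
                nid += 1
                labels[make_ellipsoid_mask((40, 40, 40), (cx, cy, 20),
                                           (4, 4, 4))] = nid
        q = 0.3
        pred = (labels > 0) & (rng.uniform(size=labels.shape) >= q)
        sens = [node_sensitivity(labels == i, pred)
                for i in range(1, nid + 1)]
        assert np.mean(sens) == pytest.approx(1 - q, abs=0.02)

    def test_pooled_equals_mean_lr_for_equal_node_counts(self):
        # two volumes with the same node count: mean of per-volume LRs
        # coincides with the pooled per-node LR
        def vol(detected):
            labels = np.zeros((30, 30, 30), dtype=np.int32)
            labels[2:8, 2:8, 2:8] = 1
            labels[12:18, 12:18, 12:18] = 2
            pred = np.zeros((30, 30, 30), dtype=bool)
            if detected >= 1:
                pred[2:8, 2:8, 2:8] = True
            if detected >= 2:
                pred[12:18, 12:18, 12:18] = True
            return pred, NodeLabelMap(labels=labels)
        p1, g1 = vol(1)
        p2, g2 = vol(2)
        rep = build_report([(p1, g1, "a"), (p2, g2, "b")])
        pooled = rep.summary["groups"]["overall"]["pooled_lr_percent"]
        assert rep.summary["mean_lr_percent"] == pytest.approx(pooled)


class TestThresholdOracle:
    def test_threshold_matches_exhaustive_comparison(self, rng):
        p = rng.uniform(size=(10, 10, 10)).astype(np.float32)
        mask = threshold_probability(p, 0.5)
        brute = np.zeros_like(mask)
        for idx in np.ndindex(p.shape):
            brute[idx] = p[idx] > 0.5
        np.testing.assert_array_equal(mask, brute)

    def test_monotone_in_threshold(self, rng):
        p = rng.uniform(size=(12, 12, 12)).astype(np.float32)
        prev = threshold_probability(p, 0.1)
        for t in (0.3, 0.5, 0.7, 0.9):
            cur = threshold_probability(p, t)
            assert not np.any(cur & ~prev)  # raising t never adds voxels
            prev = cur

    def test_degenerate_maps_and_bad_threshold(self):
        assert not threshold_probability(np.zeros((3, 3, 3)), 0.5).any()
        assert threshold_probability(np.ones((3, 3, 3)), 0.5).all()
        with pytest.raises(ValidationError):
            threshold_probability(np.zeros((3, 3, 3)), 1.5)


class TestReport:
    def test_perfect_single_volume_rows(self):
        gt = _two_node_truth()
        rep = build_report([(gt.foreground(), gt, "v0")])
        row = rep.per_volume.iloc[0]
        assert row.lr_percent == 100.0
        assert row.fp_count == 0
        assert row.dice_tp == pytest.approx(1.0)

    def test_totals_equal_sum_of_per_volume_counts(self):
        gt = _two_node_truth()
        vols = [(gt.foreground(), gt, "a"),
                (np.zeros(gt.shape, dtype=bool), gt, "b")]
        rep = build_report(vols)
        g = rep.summary["groups"]["overall"]
        assert g["total"] == int(rep.per_volume.n_eligible.sum())
        assert g["detected"] == int(
            rep.per_node[rep.per_node.eligible].localized.sum())

    def test_files_written(self, tmp_path):
        gt = _two_node_truth()
        rep = build_report([(gt.foreground(), gt, "v0")])
        rep.to_files(str(tmp_path))
        assert (tmp_path / "per_volume.csv").exists()
        assert (tmp_path / "per_node.csv").exists()
        assert (tmp_path / "summary.json").exists()


class TestSubFloorNodes:
    def test_small_node_predictions_count_as_fp_by_default(self):
        # a 3 mm node (below the 5 mm annotation floor) correctly excluded
        # from LR; a component hitting only it is an FP unless review mode
        labels = np.zeros((30, 30, 30), dtype=np.int32)
        labels[make_ellipsoid_mask((30, 30, 30), (8, 8, 8), (6, 5, 5))] = 1
        labels[make_ellipsoid_mask((30, 30, 30), (22, 22, 22),
                                   (1.6, 1.4, 1.4))] = 2
        gt = NodeLabelMap(labels=labels)
        pred = labels > 0
        pred[20:25, 20:25, 20:25] = True  # fatten the small hit >= 27 vox
        ev_default = evaluate_volume(pred, gt, EvalConfig())
        assert ev_default.fp_count == 1
        assert [r["eligible"] for r in ev_default.node_rows] == [True, False]
        ev_review = evaluate_volume(pred, gt,
                                    EvalConfig(review_small_nodes=True))
        assert ev_review.fp_count == 0
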