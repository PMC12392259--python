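import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import luxpaper as lp
from luxpaper.detect import Detection, circle_bbox_iou


# ---------------------------------------------------------------------------
# independent NMS oracle: shapely boxes for IoU, exhaustive subset search
# ---------------------------------------------------------------------------

def shapely_bbox_iou(a: Detection, b: Detection) -> float:
    from shapely.geometry import box

    ba = box(a.x - a.radius, a.y - a.radius, a.x + a.radius, a.y + a.radius)
    bb = box(b.x - b.radius, b.y - b.radius, b.x + b.radius, b.y + b.radius)
    union = ba.union(bb).area
    return ba.intersection(bb).area / union if union > 0 else 0.0


def exhaustive_nms(dets, thr):
    """Unique subset admissible under greedy-by-confidence suppression,
    found by checking every subset against the pairwise IoU matrix."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence,
                                                    dets[i].y, dets[i].x))
    rank = {i: k for k, i in enumerate(order)}
    iou = [[shapely_bbox_iou(a, b) for b in dets] for a in dets]
    admissible = []
    for subset in itertools.chain.from_iterable(
        itertools.combinations(range(len(dets)), k) for k in range(len(dets) + 1)
    ):
        s = set(subset)
        ok = all(iou[i][j] <= thr for i in s for j in s if i < j)
        if ok:
            for i in range(len(dets)):
                if i in s:
                    continue
                if not any(iou[i][j] > thr and rank[j] < rank[i] for j in s):
                    ok = False
                    break
        if ok:
            admissible.append(s)
    assert len(admissible) == 1, "greedy-admissible subset must be unique"
    return sorted(admissible[0], key=lambda i: rank[i])


def random_detections(rng, n):
    return [
        Detection(
            x=float(rng.uniform(0, 60)),
            y=float(rng.uniform(0, 60)),
            radius=float(rng.uniform(3, 15)),
            confidence=float(rng.uniform(0.01, 1.0)),
        )
        for _ in range(n)
    ]


class TestNMS:
    def test_single_detection_unchanged(self):
        d = [Detection(10, 10, 5, 0.9)]
        assert lp.non_maximum_suppression(d, 0.01) == d

    def test_coincident_circles_keep_highest_confidence(self):
        a = Detection(10, 10, 5, 0.9)
        b = Detection(10, 10, 5, 0.8)
        assert lp.non_maximum_suppression([b, a], 0.01) == [a]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dets = random_detections(rng, int(rng.integers(2, 9)))
        thr = float(rng.choice([0.01, 0.1, 0.3, 0.5]))
        got = lp.non_maximum_suppression(dets, thr)
        expected = [dets[i] for i in exhaustive_nms(dets, thr)]
        assert got == expected

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(7)
        dets = random_detections(rng, 8)
        out = lp.non_maximum_suppression(dets, 0.01)
        assert lp.non_maximum_suppression(out, 0.01) == out
        shuffled = [dets[i] for i in rng.permutation(len(dets))]
        assert lp.non_maximum_suppression(shuffled, 0.01) == out

    def test_output_pairwise_overlap_bounded(self):
        rng = np.random.default_rng(3)
        dets = random_detections(rng, 8)
        out = lp.non_maximum_suppression(dets, 0.05)
        for a, b in itertools.combinations(out, 2):
            assert circle_bbox_iou(a, b) <= 0.05

    def test_bbox_iou_agrees_with_shapely(self):
        rng = np.random.default_rng(1)
        dets = random_detections(rng, 6)
        for a, b in itertools.combinations(dets, 2):
            assert circle_bbox_iou(a, b) == pytest.approx(shapely_bbox_iou(a, b), abs=1e-12)


class TestConfidenceFilter:
    def test_empty_input(self):
        assert lp.filter_by_confidence([], 0.67) == []

    def test_published_threshold_separates(self):
        hi = Detection(5, 5, 3, 0.9)
        lo = Detection(20, 20, 3, 0.5)
        assert lp.filter_by_confidence([hi, lo], 0.67) == [hi]

    def test_zero_threshold_is_vacuous(self):
        dets = [Detection(5, 5, 3, 0.4), Detection(20, 20, 3, 0.1)]
        assert lp.filter_by_confidence(dets, 0.0) == dets


class TestDetectCandidates:
    def test_uniform_dark_frame_yields_nothing(self):
        img = np.full((64, 64), 400, dtype=np.uint16)
        assert lp.detect_candidates(img) == []

    def test_tiny_image_rejected(self):
        with pytest.raises(ValueError):
            lp.detect_candidates(np.zeros((16, 16)))

    def test_noiseless_flower_gives_7_wells_within_1px(self, noiseless_flower):
        img, layout, _ = noiseless_flower
        dets = lp.detect_candidates(img)
        dets = lp.filter_by_confidence(dets, 0.67)
        dets = lp.non_maximum_suppression(dets, 0.01)
        assert len(dets) == 7
        truth = layout.well_centers_px(img.shape)
        for tx, ty in truth:
            nearest = min(math.hypot(d.x - tx, d.y - ty) for d in dets)
            assert nearest <= 1.0

    def test_noiseless_grid_gives_18_wells(self, quiet_camera):
        layout = lp.grid3x6_layout([0, 0.1, 0.5, 1, 2, 4])
        m = lp.InhibitionModel(ec50=1.0, hill=1.5)
        acts = [m.activity(c) for c in layout.concentrations]
        truth = lp.SceneTruth(well_flux=tuple(40.0 * a / 100 for a in acts), seed=0)
        img, _ = lp.render_sensor_image(layout, truth, quiet_camera, seed=0)
        dets = lp.non_maximum_suppression(
            lp.filter_by_confidence(lp.detect_candidates(img), 0.67), 0.01
        )
        assert len(dets) == 18
        centers = layout.well_centers_px(img.shape)
        for tx, ty in centers:
            assert min(math.hypot(d.x - tx, d.y - ty) for d in dets) <= 1.5

    def test_confidence_invariant_under_affine_intensity(self, noiseless_flower):
        img, _, _ = noiseless_flower
        base = lp.detect_candidates(img.astype(float))
        scaled = lp.detect_candidates(2.5 * img.astype(float) + 137.0)
        assert len(base) == len(scaled)
        for a, b in zip(base, scaled):
            assert (a.x, a.y) == (b.x, b.y)
            assert a.confidence == pytest.approx(b.confidence, abs=1e-9)


class TestRoleAssignment:
    def _perfect_detections(self, layout, shape):
        return [
            Detection(x=float(x), y=float(y), radius=layout.well_radius_px, confidence=0.99)
            for x, y in layout.well_centers_px(shape)
        ]

    def test_perfect_flower_assignment_residual_zero(self):
        layout = lp.flower7_layout([0, 0.1, 0.5, 1, 2, 4])
        dets = self._perfect_detections(layout, layout.image_shape())
        ra = lp.assign_roles(dets, layout, orientation_deg=0.0)
        assert set(ra.mapping) == {"S0", "S1", "S2", "S3", "S4", "S5", "sample"}
        assert ra.residual_px == pytest.approx(0.0, abs=1e-9)
        for k, lbl in enumerate(layout.labels[:6]):
            x, y = layout.well_centers_px(layout.image_shape())[k]
            d = ra.mapping[lbl]
            assert (d.x, d.y) == pytest.approx((x, y))

    def test_rotated_pattern_with_matching_cue_gives_same_mapping(self):
        plain = lp.flower7_layout([0, 0.1, 0.5, 1, 2, 4], orientation_deg=0.0)
        rotated = lp.flower7_layout([0, 0.1, 0.5, 1, 2, 4], orientation_deg=30.0)
        shape = plain.image_shape()
        ra0 = lp.assign_roles(self._perfect_detections(plain, shape), plain,
                              orientation_deg=0.0)
        ra30 = lp.assign_roles(self._perfect_detections(rotated, shape), rotated,
                               orientation_deg=30.0)
        # role k sits at angle 60k (+cue) in both cases
        for lbl in ("S0", "S3", "S5"):
            d0, d30 = ra0.mapping[lbl], ra30.mapping[lbl]
            a0 = math.degrees(math.atan2(d0.y - ra0.mapping["sample"].y,
                                         d0.x - ra0.mapping["sample"].x))
            a30 = math.degrees(math.atan2(d30.y - ra30.mapping["sample"].y,
                                          d30.x - ra30.mapping["sample"].x))
            assert (a30 - a0) % 360 == pytest.approx(30.0, abs=1e-6)

    def test_missing_well_fails_naming_role(self):
        layout = lp.flower7_layout([0, 0.1, 0.5, 1, 2, 4])
        dets = self._perfect_detections(layout, layout.image_shape())
        with pytest.raises(lp.RoleAssignmentError):
            lp.assign_roles(dets[:6], layout, orientation_deg=0.0)

    def test_brightest_well_fallback_identifies_s0(self, noiseless_flower):
        img, layout, _ = noiseless_flower
        dets = lp.non_maximum_suppression(
            lp.filter_by_confidence(lp.detect_candidates(img), 0.67), 0.01
        )
        ra = lp.assign_roles(dets, layout, orientation_deg=None, image=img)
        expected = layout.well_centers_px(img.shape)
        d = ra.mapping["S0"]
        assert math.hypot(d.x - expected[0][0], d.y - expected[0][1]) <= 1.5

    def test_grid_assignment_row_major(self, quiet_camera):
        layout = lp.grid3x6_layout([0, 0.1, 0.5, 1, 2, 4])
        shape = layout.image_shape()
        dets = self._perfect_detections(layout, shape)
        rng = np.random.default_rng(0)
        dets = [dets[i] for i in rng.permutation(len(dets))]
        ra = lp.assign_roles(dets, layout)
        assert ra.residual_px == pytest.approx(0.0, abs=1e-6)
        centers = layout.well_centers_px(shape)
        for i, lbl in enumerate(layout.labels):
            d = ra.mapping[lbl]
            assert (d.x, d.y) == pytest.approx(tuple(centers[i]))
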