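"""Visit registration, deposit detection, change classification, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from octfuse import fuse, motion, simkit, track
from octfuse.enface import EnFaceSlab, SlabSpec, make_slab
from octfuse.motion import DisplacementModel
from octfuse.track import (CATEGORIES, ChangeRecord, QUADRANTS,
                           RegistrationError, SDDetection, VisitTransform,
                           assign_quadrant, classify_changes, detect_sdd,
                           percent, register_visits, summarize)

from conftest import small_protocol, textured_config

PITCH = 12.0


def slab_of(img):
    return EnFaceSlab(np.asarray(img, np.float32),
                      np.ones(np.shape(img), bool), SlabSpec(), PITCH)


@pytest.fixture(scope="module")
def smooth_image():
    rng = np.random.default_rng(0)
    return ndimage.gaussian_filter(rng.random((100, 100)), 2).astype(np.float32)


# --------------------------------------------------------------------------
# registration
# --------------------------------------------------------------------------

class TestRegisterVisits:
    def test_identical_slabs_identity_transform(self, smooth_image):
        tf = register_visits(slab_of(smooth_image), slab_of(smooth_image))
        assert tf.score > 0.99
        assert abs(tf.rotation_rad) < 1e-3
        assert abs(tf.tx_um) < PITCH / 2 and abs(tf.ty_um) < PITCH / 2

    def test_known_shift_recovered_within_half_pixel(self, smooth_image):
        moved = ndimage.shift(smooth_image, (-2.0, 3.0), order=1,
                              mode="nearest")
        tf = register_visits(slab_of(smooth_image), slab_of(moved))
        p = np.array([[600.0, 600.0]])
        want = p + np.array([3.0 * PITCH, -2.0 * PITCH])
        assert np.abs(tf.apply(p) - want).max() <= PITCH / 2

    def test_small_rotation_recovered(self, smooth_image):
        from skimage.transform import rotate
        rot = rotate(smooth_image, 3.0, preserve_range=True,
                     mode="edge").astype(np.float32)
        tf = register_visits(slab_of(smooth_image), slab_of(rot))
        assert np.rad2deg(abs(tf.rotation_rad)) == pytest.approx(3.0,
                                                                 abs=0.5)

    def test_pure_noise_unregistrable(self):
        rng = np.random.default_rng(1)
        with pytest.raises(RegistrationError, match="unregistrable"):
            register_visits(slab_of(rng.random((100, 100))),
                            slab_of(rng.random((100, 100))))

    def test_pitch_mismatch_rejected(self, smooth_image):
        b = slab_of(smooth_image)
        f = EnFaceSlab(smooth_image, np.ones_like(smooth_image, bool),
                       SlabSpec(), PITCH * 2)
        with pytest.raises(ValueError, match="pitch"):
            register_visits(b, f)


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

class TestDetectSDD:
    def test_uniform_slab_no_detections(self):
        assert detect_sdd(slab_of(np.full((80, 80), 0.5))) == []

    def test_seeded_deposits_all_found_no_false_positives(self):
        """20 well-separated simulated deposits: every one detected within
        a pixel of its ground-truth centroid, nothing else detected."""
        n = 128
        rng = np.random.default_rng(11)
        centres = []
        grid = np.linspace(150, n * 12.0 - 150, 5)
        for gy in grid[:4]:
            for gx in grid:
                centres.append((gx + rng.uniform(-30, 30),
                                gy + rng.uniform(-30, 30)))
        sdds = [simkit.SDD(x, y, float(rng.uniform(35, 55)),
                           int(rng.integers(1, 4))) for x, y in centres]
        cfg = textured_config(n, 220, 0, seed=4)
        cfg = simkit.PhantomConfig(
            nx=n, ny=n, nz=220, sdds=tuple(sdds), seed=4,
            undulation_amp_um=20.0)
        ph = simkit.make_phantom(cfg)
        proto = small_protocol(n, 2, duration=0.8)
        vols = simkit.acquire(ph, proto, None, speckle_contrast=0.25,
                              detector_noise_sd=0.005, seed=3)
        zero = DisplacementModel.zero(vols)
        samples = [motion.correct(v, zero) for v in vols]
        brm = fuse.mean_surface(
            [fuse.segment_surface(v, "BrM") for v in vols], zero, (n, n))
        fused = fuse.flatten_and_merge(samples, brm, 165)
        slab = make_slab(fused)
        dets = detect_sdd(slab)
        assert len(dets) == 20
        txy = np.array(centres)
        dxy = np.array([[d.x_um, d.y_um] for d in dets])
        dist = np.sqrt(((dxy[:, None] - txy[None]) ** 2).sum(-1))
        assert dist.min(axis=1).max() <= PITCH          # within one pixel
        assert (dist.min(axis=0) <= PITCH).all()        # none missed

    def test_rotation_symmetry(self):
        rng = np.random.default_rng(2)
        img = np.full((90, 90), 0.1, np.float32)
        for _ in range(6):
            cy, cx = rng.integers(15, 75, 2)
            yy, xx = np.mgrid[:90, :90]
            img += 0.8 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / 18.0)
        d0 = detect_sdd(slab_of(img))
        d180 = detect_sdd(slab_of(img[::-1, ::-1]))
        assert len(d0) == len(d180) == 6
        ext = 89 * PITCH
        got = sorted((round(ext - d.x_um), round(ext - d.y_um))
                     for d in d180)
        want = sorted((round(d.x_um), round(d.y_um)) for d in d0)
        for (gx, gy), (wx, wy) in zip(got, want):
            assert abs(gx - wx) <= PITCH and abs(gy - wy) <= PITCH


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def oracle_classify(base, follow, radius):
    """Independent pure-python re-derivation of the four-category rule from
    the longitudinal definitions: nearest-within-radius claiming, shared
    target = fused, unmatched baseline = regressed, unclaimed = new."""
    recs = []
    claims = {}
    for b in base:
        best, best_d = None, None
        for f in follow:
            d = ((b.x_um - f.x_um) ** 2 + (b.y_um - f.y_um) ** 2) ** 0.5
            if best is None or d < best_d:
                best, best_d = f, d
        if best is not None and best_d <= radius:
            claims.setdefault(best.id, []).append(b)
        else:
            recs.append(("regressed", (b.id,), None))
    for fid, members in claims.items():
        cat = "fused" if len(members) > 1 else "stable"
        for b in members:
            recs.append((cat, (b.id,), fid))
    claimed = set(claims)
    for f in follow:
        if f.id not in claimed:
            recs.append(("new", (), f.id))
    return sorted(recs)


def as_tuples(records):
    return sorted((r.category, r.baseline_ids, r.followup_id)
                  for r in records)


def random_instance(rng, n_base, n_follow, extent=500.0):
    mk = lambda i, visit: SDDetection(
        i, float(rng.uniform(0, extent)), float(rng.uniform(0, extent)),
        40.0, 1.0, visit)
    return ([mk(i, "b") for i in range(n_base)],
            [mk(i, "f") for i in range(n_follow)])


class TestClassifyChanges:
    def test_empty_inputs_empty_output(self):
        assert classify_changes([], [], None, 60.0) == []

    def test_same_positions_all_stable(self):
        base, _ = random_instance(np.random.default_rng(0), 3, 0)
        follow = [SDDetection(10 + i, d.x_um, d.y_um, 40.0, 1.0, "f")
                  for i, d in enumerate(base)]
        recs = classify_changes(base, follow, None, 60.0)
        assert [r.category for r in recs] == ["stable"] * 3

    def test_two_baseline_sharing_target_fused(self):
        base = [SDDetection(0, 0.0, 0.0, 40, 1), SDDetection(1, 80.0, 0.0, 40, 1)]
        follow = [SDDetection(5, 40.0, 0.0, 60, 1)]
        recs = classify_changes(base, follow, None, 60.0)
        assert [r.category for r in recs] == ["fused", "fused"]
        assert all(r.followup_id == 5 for r in recs)

    def test_agreement_with_exhaustive_oracle(self):
        """1000 random instances with up to 6 detections per visit."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            nb, nf = rng.integers(0, 7), rng.integers(0, 7)
            base, follow = random_instance(rng, nb, nf)
            radius = float(rng.uniform(30, 150))
            got = as_tuples(classify_changes(base, follow, None, radius))
            assert got == oracle_classify(base, follow, radius)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        base, follow = random_instance(rng, 5, 5)
        ref = as_tuples(classify_changes(base, follow, None, 80.0))
        for _ in range(5):
            bp = [base[i] for i in rng.permutation(5)]
            fp = [follow[i] for i in rng.permutation(5)]
            assert as_tuples(classify_changes(bp, fp, None, 80.0)) == ref

    def test_transform_applied_to_baseline(self):
        base = [SDDetection(0, 100.0, 100.0, 40, 1)]
        follow = [SDDetection(1, 136.0, 76.0, 40, 1)]
        tf = VisitTransform(0.0, 36.0, -24.0, 1.0)
        recs = classify_changes(base, follow, tf, 30.0)
        assert recs[0].category == "stable"

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            classify_changes([], [], None, 0.0)


class TestChangeRecordInvariants:
    @pytest.mark.parametrize("cat,bids,fid", [
        ("new", (1,), 2), ("new", (), None),
        ("regressed", (), None), ("regressed", (1,), 2),
        ("stable", (1, 2), 3), ("stable", (1,), None),
        ("fused", (), 3)])
    def test_inconsistent_records_rejected(self, cat, bids, fid):
        with pytest.raises(ValueError):
            ChangeRecord(cat, bids, fid)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            ChangeRecord("merged", (1,), 2)


# --------------------------------------------------------------------------
# quadrants
# --------------------------------------------------------------------------

def sign_based_quadrant(dx, dy, laterality):
    """Independent re-derivation by coordinate signs."""
    vert = "supero" if dy <= 0 else "infero"
    left = dx <= 0
    nasal = left if laterality == "OD" else (dx >= 0)
    return vert + ("nasal" if nasal else "temporal")


class TestAssignQuadrant:
    def test_od_fundus_left_is_nasal(self):
        det = SDDetection(0, 100.0, 100.0, 40, 1)       # above-left of fovea
        assert assign_quadrant(det, (200.0, 200.0), "OD") == "superonasal"
        assert assign_quadrant(det, (200.0, 200.0), "OS") == "superotemporal"

    def test_mirror_swaps_nasal_temporal_only(self):
        rng = np.random.default_rng(3)
        fovea = (300.0, 300.0)
        for _ in range(50):
            x, y = rng.uniform(0, 600, 2)
            q = assign_quadrant(SDDetection(0, x, y, 40, 1), fovea, "OD")
            qm = assign_quadrant(
                SDDetection(0, 2 * fovea[0] - x, y, 40, 1), fovea, "OD")
            assert q[:6] == qm[:6]
            if x != fovea[0]:
                assert q[6:] != qm[6:]

    def test_matches_independent_sign_logic(self):
        rng = np.random.default_rng(9)
        fovea = (250.0, 250.0)
        for _ in range(200):
            x, y = rng.uniform(0, 500, 2)
            lat = "OD" if rng.random() < 0.5 else "OS"
            det = SDDetection(0, x, y, 40, 1)
            assert assign_quadrant(det, fovea, lat) == \
                sign_based_quadrant(x - fovea[0], y - fovea[1], lat)

    def test_bad_laterality_rejected(self):
        with pytest.raises(ValueError):
            assign_quadrant(SDDetection(0, 0, 0, 40, 1), (0, 0), "LEFT")


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def make_records(stable=0, regressed=0, fused=0, new=0, quadrants=None):
    recs = []
    i = 0
    for cat, n in (("stable", stable), ("regressed", regressed),
                   ("fused", fused), ("new", new)):
        for _ in range(n):
            q = quadrants[i % len(quadrants)] if quadrants else None
            if cat == "stable":
                recs.append(ChangeRecord("stable", (i,), i, q))
            elif cat == "regressed":
                recs.append(ChangeRecord("regressed", (i,), None, q))
            elif cat == "fused":
                recs.append(ChangeRecord("fused", (i,), 9000, q))
            else:
                recs.append(ChangeRecord("new", (), i, q))
            i += 1
    return recs


class TestSummarize:
    def test_reported_category_percentages(self):
        """The four-category split of 326 tracked deposits (278 stable,
        32 regressed, 11 fused, 5 new) in percent."""
        t = summarize(make_records(278, 32, 11, 5))
        assert t.total == 326
        assert t.category_counts == {"stable": 278, "regressed": 32,
                                     "fused": 11, "new": 5}
        assert t.category_pct == {"stable": 85.3, "regressed": 9.8,
                                  "fused": 3.4, "new": 1.5}

    def test_reported_quadrant_percentages(self):
        counts = dict(zip(QUADRANTS, (86, 83, 79, 78)))
        want = dict(zip(QUADRANTS, (26.4, 25.5, 24.2, 23.9)))
        assert {q: percent(c, 326) for q, c in counts.items()} == want

    def test_single_stable_record(self):
        t = summarize(make_records(stable=1))
        assert t.category_pct["stable"] == 100.0
        assert t.total == 1

    def test_empty_input_masked_percentages(self):
        t = summarize([])
        assert t.total == 0
        assert all(v == 0 for v in t.category_counts.values())
        assert all(v is None for v in t.category_pct.values())

    def test_quadrant_counts_from_records(self):
        recs = make_records(4, 0, 0, 0, quadrants=list(QUADRANTS))
        t = summarize(recs)
        assert all(t.quadrant_counts[q] == 1 for q in QUADRANTS)
        assert all(t.quadrant_pct[q] == 25.0 for q in QUADRANTS)

    @given(st.lists(st.sampled_from(CATEGORIES), max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_percentages_sum_to_hundred(self, cats):
        recs = make_records(cats.count("stable"), cats.count("regressed"),
                            cats.count("fused"), cats.count("new"))
        t = summarize(recs)
        assert t.total == len(cats)
        assert sum(t.category_counts.values()) == t.total
        if t.total:
            assert sum(t.category_pct.values()) == pytest.approx(100.0,
                                                                 abs=0.2)

    @given(st.integers(0, 10_000), st.integers(1, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_percent_is_round_half_up(self, count, total):
        import decimal
        got = percent(count, total)
        q = decimal.Decimal(100 * count) / decimal.Decimal(total)
        want = q.quantize(decimal.Decimal("0.1"),
                          rounding=decimal.ROUND_HALF_UP)
        assert got == float(want)

    def test_to_frame_and_str(self):
        t = summarize(make_records(2, 1, 0, 0, quadrants=["superonasal"]))
        df = t.to_frame()
        assert set(df["group"]) == {"category", "quadrant"}
        assert "stable" in str(t)
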