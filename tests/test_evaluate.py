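"""Metric suite: hand-arithmetic cases, brute-force oracles, summaries."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from bonesct.evaluate import (EvalConfig, MetricReport, cohort_summary, dice,
                              dilate_mask, evaluate_case, extract_bone, mad,
                              md, surface_rmsd)
from bonesct.phantom import (LesionSpec, PhantomSpec, Tissue,
                             bone_mask_from_labels, build_label_map,
                             lesion_mask_from_labels, render_ct)


# --- independent brute-force oracles ---------------------------------------

def brute_surface_points(mask):
    """Boundary voxels by explicit 6-neighbour enumeration."""
    pts = []
    nx, ny, nz = mask.shape
    for i, j, k in np.argwhere(mask):
        boundary = False
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            ii, jj, kk = i + di, j + dj, k + dk
            if not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz) \
                    or not mask[ii, jj, kk]:
                boundary = True
                break
        if boundary:
            pts.append((i, j, k))
    return np.array(pts, dtype=float)


def brute_surface_rmsd(a, b, spacing):
    sp = np.asarray(spacing, dtype=float)
    pa = brute_surface_points(a) * sp
    pb = brute_surface_points(b) * sp
    d = cdist(pa, pb).min(axis=1)
    return float(np.sqrt(np.mean(d**2)))


def brute_dilate(mask, margin, spacing):
    sp = np.asarray(spacing, dtype=float)
    src = np.argwhere(mask) * sp
    out = np.zeros_like(mask)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * sp
        if np.sqrt(((src - p) ** 2).sum(axis=1)).min() <= margin:
            out[idx] = True
    return out


def _random_mask(rng, shape=(8, 8, 8), p=0.2):
    m = rng.random(shape) < p
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m


# --- intensity differences --------------------------------------------------

class TestMadMd:
    def test_identical_images(self):
        v = np.full((4, 4, 4), 100.0)
        m = np.ones_like(v, dtype=bool)
        assert mad(v, v, m) == 0.0
        assert md(v, v, m) == 0.0

    def test_uniform_offset(self):
        v = np.zeros((4, 4, 4))
        m = np.ones_like(v, dtype=bool)
        assert mad(v + 50, v, m) == 50.0
        assert md(v + 50, v, m) == 50.0

    def test_two_voxel_hand_case(self):
        ct = np.zeros((2, 1, 1))
        sct = np.array([30.0, -10.0]).reshape(2, 1, 1)
        m = np.ones_like(ct, dtype=bool)
        assert mad(sct, ct, m) == pytest.approx(20.0)
        assert md(sct, ct, m) == pytest.approx(10.0)

    def test_md_never_exceeds_mad(self, rng):
        for _ in range(20):
            sct = rng.normal(0, 100, (5, 5, 5))
            ct = rng.normal(0, 100, (5, 5, 5))
            m = _random_mask(rng, (5, 5, 5), 0.5)
            assert abs(md(sct, ct, m)) <= mad(sct, ct, m) + 1e-12

    def test_empty_mask_rejected(self):
        v = np.zeros((3, 3, 3))
        with pytest.raises(ValueError, match="empty"):
            mad(v, v, np.zeros_like(v, dtype=bool))


class TestExtractBone:
    def test_air_yields_empty(self):
        vol = np.full((4, 4, 4), -1000.0)
        assert not extract_bone(vol, np.ones_like(vol, dtype=bool)).any()

    def test_infinite_threshold_empty(self):
        vol = np.full((4, 4, 4), 2000.0)
        assert not extract_bone(vol, np.ones_like(vol, dtype=bool),
                                np.inf).any()

    def test_threshold_inclusive(self):
        vol = np.array([[[149.9, 150.0, 150.1]]])
        out = extract_bone(vol, np.ones_like(vol, dtype=bool))
        np.testing.assert_array_equal(out, [[[False, True, True]]])

    def test_noiseless_phantom_cortical_recovered(self):
        spec = PhantomSpec(shape=(48, 48, 32), seed=1, ct_blur_sigma=0.0)
        labels = build_label_map(spec)
        ct = render_ct(labels, spec, noise=False)
        ext = extract_bone(ct, bone_mask_from_labels(labels))
        cortical = labels == int(Tissue.CORTICAL)
        assert (ext & cortical).sum() == cortical.sum()


class TestDice:
    def test_self_dice_is_one(self, rng):
        m = _random_mask(rng)
        assert dice(m, m) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dice(a, b) == 0.0

    def test_half_overlap_hand_case(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, :4] = a[1, 0, :4] = True   # |a| = 8
        b[1, 0, :4] = b[2, 0, :4] = True   # |b| = 8, overlap 4
        assert dice(a, b) == pytest.approx(0.5)

    def test_symmetry(self, rng):
        a, b = _random_mask(rng), _random_mask(rng)
        assert dice(a, b) == dice(b, a)

    def test_both_empty_returns_one_with_warning(self):
        e = np.zeros((3, 3, 3), dtype=bool)
        with pytest.warns(UserWarning, match="empty"):
            assert dice(e, e) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice(np.ones((2, 2, 2), dtype=bool), np.ones((3, 3, 3), dtype=bool))


class TestSurfaceRMSD:
    def test_identical_masks_zero(self, rng):
        m = _random_mask(rng)
        assert surface_rmsd(m, m, (1, 1, 1)) == 0.0

    def test_parallel_plates_closed_form(self):
        a = np.zeros((10, 6, 6), dtype=bool)
        b = np.zeros((10, 6, 6), dtype=bool)
        a[2] = True   # 1-voxel-thick plate, normal along axis 0
        b[5] = True   # 3 mm away at 1 mm spacing
        assert surface_rmsd(a, b, (1, 1, 1)) == pytest.approx(3.0)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            a, b = _random_mask(rng), _random_mask(rng)
            spacing = rng.choice([1.0, 1.5, 2.0], size=3)
            got = surface_rmsd(a, b, spacing)
            want = brute_surface_rmsd(a, b, spacing)
            assert got == pytest.approx(want, abs=1e-9)

    def test_directed_vs_symmetric(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[3:5, 3:5, 3:5] = True
        b[2:6, 2:6, 2:6] = True
        d_ab = surface_rmsd(a, b, (1, 1, 1))
        sym = surface_rmsd(a, b, (1, 1, 1), symmetric=True)
        assert sym >= min(d_ab, surface_rmsd(b, a, (1, 1, 1))) - 1e-12

    def test_empty_side_rejected(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        f = m.copy()
        f[1, 1, 1] = True
        with pytest.raises(ValueError, match="empty"):
            surface_rmsd(f, m, (1, 1, 1))


class TestDilateMask:
    def test_zero_margin_identity(self, rng):
        m = _random_mask(rng)
        np.testing.assert_array_equal(dilate_mask(m, 0.0, (1, 1, 1)), m)

    def test_single_voxel_ball_count(self):
        m = np.zeros((13, 13, 13), dtype=bool)
        m[6, 6, 6] = True
        out = dilate_mask(m, 5.0, (1, 1, 1))
        want = brute_dilate(m, 5.0, (1, 1, 1))
        np.testing.assert_array_equal(out, want)

    def test_anisotropic_extent(self):
        m = np.zeros((11, 11, 11), dtype=bool)
        m[5, 5, 5] = True
        out = dilate_mask(m, 4.0, (1, 1, 2))
        xs = np.argwhere(out)
        assert xs[:, 0].max() - xs[:, 0].min() == 8   # 4 mm on 1 mm axis
        assert xs[:, 2].max() - xs[:, 2].min() == 4   # 4 mm on 2 mm axis

    def test_monotone_in_margin(self, rng):
        m = _random_mask(rng)
        small = dilate_mask(m, 2.0, (1, 1, 1))
        large = dilate_mask(m, 4.0, (1, 1, 1))
        assert not (small & ~large).any()

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            m = _random_mask(rng, (7, 7, 7), 0.1)
            spacing = rng.choice([1.0, 2.0], size=3)
            margin = float(rng.uniform(1.0, 4.0))
            np.testing.assert_array_equal(dilate_mask(m, margin, spacing),
                                          brute_dilate(m, margin, spacing))


class TestEvaluateCase:
    @pytest.fixture(scope="class")
    def phantom(self):
        spec = PhantomSpec(
            shape=(48, 48, 32), seed=2, ct_blur_sigma=0.0,
            lesions=(LesionSpec("osteoblastic", center=(24, 24, 16),
                                radius=5.0),))
        labels = build_label_map(spec)
        ct = render_ct(labels, spec, noise=False)
        return (ct, bone_mask_from_labels(labels),
                lesion_mask_from_labels(labels), spec.spacing)

    def test_perfect_sct(self, phantom):
        ct, bone, lesion, spacing = phantom
        rb, rl = evaluate_case(ct, ct, bone, lesion, spacing)
        assert (rb.mad, rb.md, rb.dsc, rb.rmsd) == (0.0, 0.0, 1.0, 0.0)
        assert (rl.mad, rl.md, rl.dsc, rl.rmsd) == (0.0, 0.0, 1.0, 0.0)

    def test_uniform_200_offset(self, phantom):
        ct, bone, lesion, spacing = phantom
        rb, _ = evaluate_case(ct + 200.0, ct, bone, lesion, spacing)
        assert rb.mad == pytest.approx(200.0)
        assert rb.md == pytest.approx(200.0)
        # marrow at -50 HU crosses the 150-HU threshold after +200
        assert rb.dsc < 1.0

    def test_lesion_rmsd_uses_dilated_region(self, phantom):
        ct, bone, lesion, spacing = phantom
        cfg_wide = EvalConfig(lesion_margin=30.0)
        cfg_tight = EvalConfig(lesion_margin=0.0)
        _, wide = evaluate_case(ct + 200.0, ct, bone, lesion, spacing, cfg_wide)
        _, tight = evaluate_case(ct + 200.0, ct, bone, lesion, spacing, cfg_tight)
        # MAD/MD/DSC identical (undilated mask); RMSD may differ
        assert wide.mad == tight.mad and wide.dsc == tight.dsc

    def test_all_soft_sct_flags_lesion(self, phantom):
        ct, bone, lesion, spacing = phantom
        soft = np.zeros_like(ct)  # nothing above 150 anywhere
        with pytest.warns(UserWarning):
            rb, rl = evaluate_case(soft, ct, bone, lesion, spacing)
        assert rl.flagged and np.isnan(rl.rmsd)


class TestCohortSummary:
    def test_sample_sd_convention(self):
        reports = [MetricReport(f"c{i}", "bone", m, 0.0, 0.9, 1.0)
                   for i, m in enumerate([100.0, 120.0, 140.0])]
        s = cohort_summary(reports)
        assert s.mean[("bone", "mad")] == pytest.approx(120.0)
        assert s.sd[("bone", "mad")] == pytest.approx(20.0)  # n-1 divisor

    def test_identical_reports_zero_sd(self):
        reports = [MetricReport(f"c{i}", "lesion", 50.0, -10.0, 0.8, 2.0)
                   for i in range(4)]
        s = cohort_summary(reports)
        assert s.sd[("lesion", "mad")] == 0.0

    def test_single_report_sd_undefined(self):
        s = cohort_summary([MetricReport("c0", "bone", 1.0, 0.5, 0.9, 1.0)])
        assert np.isnan(s.sd[("bone", "mad")])
        assert s.mean[("bone", "mad")] == 1.0

    def test_invalid_report_rejected(self):
        with pytest.raises(ValueError, match="MAD"):
            MetricReport("c", "bone", mad=5.0, md=10.0, dsc=0.5, rmsd=1.0)
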