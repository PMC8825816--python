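"""Seed detection, diagonal sets and rectangular patch voting."""

import numpy as np
import pytest

from octcyst import (
    DetectionParams,
    compute_diff_maps,
    detect_candidates,
    find_diagonal_sets,
    find_vertical_seeds,
)

from conftest import random_images
from oracles import naive_candidates, naive_sets


def antialiased_step(m=24, n=20, edge=10, top=200.0, bottom=50.0):
    """Bright band over dark band with a one-row intermediate value, so
    the vertical transition has a unique strict difference maximum."""
    px = np.full((m, n), bottom)
    px[:edge] = top
    px[edge] = 0.5 * (top + bottom)
    return px


def dark_disk(m=40, n=40, center=(20, 20), radius=9, inside=40.0, outside=200.0):
    rr, cc = np.ogrid[:m, :n]
    px = np.full((m, n), outside)
    px[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 < radius**2] = inside
    return px


class TestVerticalSeeds:
    def test_constant_image_has_no_seeds(self):
        d = compute_diff_maps(np.full((15, 15), 90.0))
        assert not find_vertical_seeds(d, thv=20.0).any()

    def test_light_over_dark_step_seeds_every_interior_column(self):
        px = antialiased_step()
        d = compute_diff_maps(px)
        V = find_vertical_seeds(d, thv=20.0)
        rows, cols = np.nonzero(V)
        assert set(cols) == set(range(1, px.shape[1] - 1))
        assert len(set(rows)) == 1  # same peak row in every column

    def test_dark_over_light_step_gives_no_seeds(self):
        px = antialiased_step(top=50.0, bottom=200.0)  # dark above, light below
        d = compute_diff_maps(px)
        assert not find_vertical_seeds(d, thv=20.0).any()

    def test_thv_monotonicity_shrinks_all_sets(self):
        px = next(random_images(1, (30, 30), seed=3))
        d = compute_diff_maps(px)
        for lo, hi in [(5.0, 15.0), (15.0, 40.0)]:
            V1, V2 = find_vertical_seeds(d, lo), find_vertical_seeds(d, hi)
            assert np.all(V2 <= V1)
            (L1, R1), (L2, R2) = find_diagonal_sets(d, lo), find_diagonal_sets(d, hi)
            assert np.all(L2 <= L1) and np.all(R2 <= R1)


class TestDiagonalSets:
    def test_constant_image_empty(self):
        d = compute_diff_maps(np.full((15, 15), 90.0))
        L, R = find_diagonal_sets(d, thv=10.0)
        assert not L.any() and not R.any()

    def test_disk_boundary_arcs_split_left_right(self):
        px = dark_disk()
        d = compute_diff_maps(px)
        L, R = find_diagonal_sets(d, thv=20.0)
        cr, cc = 20, 20
        lr, lc = np.nonzero(L)
        rr_, rc = np.nonzero(R)
        # left-diagonal transitions concentrate on the upper-left arc
        upper_left = (lr < cr) & (lc < cc)
        assert upper_left.sum() >= 0.5 * len(lr) and len(lr) > 0
        upper_right = (rr_ < cr) & (rc > cc)
        assert upper_right.sum() >= 0.5 * len(rr_) and len(rr_) > 0

    def test_membership_matches_bruteforce_conditions(self):
        px = dark_disk()
        d = compute_diff_maps(px)
        L, R = find_diagonal_sets(d, thv=20.0)
        _, Lo, Ro = naive_sets(px, 1, 1, 20.0)
        assert np.array_equal(L, Lo) and np.array_equal(R, Ro)

    def test_mirrored_image_swaps_L_and_R(self):
        px = dark_disk(center=(18, 14))
        d = compute_diff_maps(px)
        L, R = find_diagonal_sets(d, thv=20.0)
        dm = compute_diff_maps(px[:, ::-1])
        Lm, Rm = find_diagonal_sets(dm, thv=20.0)
        assert np.array_equal(Lm, R[:, ::-1])
        assert np.array_equal(Rm, L[:, ::-1])


class TestDetectCandidates:
    def test_constant_image_yields_nothing(self):
        assert detect_candidates(np.full((30, 30), 90.0), DetectionParams(thv=10.0)) == []

    def test_cystic_phantom_candidate_near_top_boundary(self, cystic_scan):
        from octcyst import denoise

        clean = denoise(cystic_scan.image, 3)
        cands = detect_candidates(clean, DetectionParams())
        assert cands, "expected at least one accepted patch on the cyst"
        spec_cyst = cystic_scan.spec.cysts[0]
        best = 1e9
        for c in cands:
            i, j = c.seed
            dx = (j - spec_cyst.center_col) / spec_cyst.semi_cols
            if abs(dx) < 1:
                top = spec_cyst.center_row - spec_cyst.semi_rows * np.sqrt(1 - dx**2)
                best = min(best, abs(i - top))
        assert best <= 3.0

    def test_clean_phantom_same_noise_yields_nothing(self, clean_scan):
        from octcyst import denoise

        clean = denoise(clean_scan.image, 3)
        assert detect_candidates(clean, DetectionParams()) == []

    def test_every_candidate_certifies_more_than_num_pixels(self, cystic_scan):
        params = DetectionParams()
        cands = detect_candidates(cystic_scan.image, params)
        assert cands
        assert min(c.member_count for c in cands) >= params.num + 1

    def test_candidate_invariants_audited(self, cystic_scan):
        params = DetectionParams()
        diff = compute_diff_maps(cystic_scan.image.pixels, params.a, params.b)
        thv = params.resolve_thv(cystic_scan.image.pixels)
        V = find_vertical_seeds(diff, thv)
        L, R = find_diagonal_sets(diff, thv)
        for c in detect_candidates(cystic_scan.image, params, diff=diff):
            assert V[c.seed]
            assert c.member_count == len(c.members) > params.num
            mask = L if c.side == "left" else R
            (r1, r2), (c1, c2) = c.row_range, c.col_range
            for i, j in c.members:
                assert r1 <= i <= r2 and c1 <= j <= c2
                assert mask[i, j]

    def test_num_monotonicity_candidate_subset(self, cystic_scan):
        def keyset(num):
            cands = detect_candidates(cystic_scan.image, DetectionParams(num=num))
            return {(c.seed, c.side) for c in cands}

        assert keyset(14) <= keyset(12) <= keyset(10)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_straightline_bruteforce(self, seed):
        params = DetectionParams(s=5, t=4, num=2, thv=25.0)
        for px in random_images(5, (30, 30), seed=seed):
            got = [
                (c.seed, c.side, c.row_range, c.col_range, c.member_count)
                for c in detect_candidates(px, params)
            ]
            want = naive_candidates(px, 1, 1, 5, 4, 2, 25.0)
            assert got == want

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="num"):
            DetectionParams(num=-1)
        with pytest.raises(ValueError, match="patch area"):
            DetectionParams(s=3, t=3, num=9)
        with pytest.raises(ValueError, match="thv"):
            DetectionParams(thv=-5.0)
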