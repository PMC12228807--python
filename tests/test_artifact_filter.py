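"""Speck and concentration artifact filters: detectors, boundaries, replacement."""

import numpy as np
import pytest

from redetect.artifact_filter import (FilterConfig, apply_artifact_filters,
                                      detect_specks,
                                      flag_concentrated_subdomains,
                                      flag_speck_subdomains)
from redetect.rarity import CohortSpec, RarityRanking, select_cohort
from redetect.slide_io import SlideTiling, tile_slide

from conftest import make_slide


def _slide_with_ck(ck_plane, w=64, h=64, n_frames=1):
    px = np.zeros((4, ck_plane.shape[0], ck_plane.shape[1]), dtype=np.float32)
    px[1] = ck_plane
    return make_slide(px, w, h, n_frames)


class TestDetectSpecks:
    def test_blank_frame_zero(self):
        slide = _slide_with_ck(np.zeros((64, 64), dtype=np.float32))
        assert detect_specks(slide, 0) == 0

    def test_three_isolated_bright_pixels(self):
        ck = np.zeros((64, 64), dtype=np.float32)
        ck[3, 3] = ck[10, 40] = ck[50, 20] = 0.9
        assert detect_specks(_slide_with_ck(ck), 0) == 3

    def test_large_blob_excluded_by_area(self):
        ck = np.zeros((64, 64), dtype=np.float32)
        ck[10:30, 10:20] = 0.9  # area 200 > speck_max_area
        assert detect_specks(_slide_with_ck(ck), 0) == 0

    def test_area_boundary_inclusive(self):
        ck = np.zeros((64, 64), dtype=np.float32)
        ck[5, 10:20] = 0.9  # area exactly 10
        assert detect_specks(_slide_with_ck(ck), 0) == 1
        ck[5, 10:21] = 0.9  # area 11
        assert detect_specks(_slide_with_ck(ck), 0) == 0

    def test_dim_pixels_not_specks(self):
        ck = np.full((64, 64), 0.4, dtype=np.float32)  # below cutoff 0.5
        assert detect_specks(_slide_with_ck(ck), 0) == 0

    def test_unknown_frame_fatal(self):
        slide = _slide_with_ck(np.zeros((64, 64), dtype=np.float32))
        with pytest.raises(KeyError):
            detect_specks(slide, 3)


class TestSpeckFlagBoundary:
    def test_strict_exceedance_at_500(self):
        counts = np.array([0, 500, 501, 9999])
        assert flag_speck_subdomains(counts) == {2, 3}

    def test_clean_slide_no_flags(self):
        assert flag_speck_subdomains(np.zeros(10, dtype=int)) == set()


def _uniform_tiling(n_frames, per_frame):
    n = n_frames * per_frame
    frame_ids = np.repeat(np.arange(n_frames), per_frame)
    xs = np.tile(np.arange(per_frame) * 32, n_frames)
    ys = np.zeros(n, dtype=np.int64)
    return SlideTiling(None, frame_ids, xs, ys)


def _order_with_count_in_frame(tiling, frame, count, top_k):
    """Ranking whose top-k holds `count` tiles of `frame`, rest spread
    round-robin so no other frame concentrates."""
    head = np.flatnonzero(tiling.frame_ids == frame)[:count]
    others = np.flatnonzero(tiling.frame_ids != frame)
    per_frame = np.bincount(tiling.frame_ids[others])
    filler = others.reshape(len(per_frame[per_frame > 0]), -1).T.ravel()
    filler = filler[:top_k - count]
    tail = np.setdiff1d(np.arange(len(tiling)), np.concatenate([head, filler]))
    return np.concatenate([head, filler, tail])


class TestConcentrationFlag:
    def test_26_in_one_frame_flags_it(self):
        tiling = _uniform_tiling(4, 100)
        order = _order_with_count_in_frame(tiling, 1, 26, 100)
        ranking = RarityRanking(order, np.linspace(1, 0, len(order)))
        cfg = FilterConfig(top_k=100, concentration_threshold=25)
        assert flag_concentrated_subdomains(ranking, tiling, cfg) == {1}

    def test_25_in_one_frame_not_flagged(self):
        tiling = _uniform_tiling(4, 100)
        order = _order_with_count_in_frame(tiling, 1, 25, 100)
        ranking = RarityRanking(order, np.linspace(1, 0, len(order)))
        cfg = FilterConfig(top_k=100, concentration_threshold=25)
        assert flag_concentrated_subdomains(ranking, tiling, cfg) == set()

    def test_uniform_spread_no_flags(self):
        tiling = _uniform_tiling(8, 50)
        order = np.arange(len(tiling))  # 50 per frame but top_k covers few
        ranking = RarityRanking(order, np.linspace(1, 0, len(order)))
        cfg = FilterConfig(top_k=80, concentration_threshold=25)
        # top 80 in frame order: frames 0,1 get 50/30 -> both exceed 25
        assert flag_concentrated_subdomains(ranking, tiling, cfg) == {0, 1}
        # interleave frames evenly: 10 per frame, below threshold
        order = np.argsort(np.tile(np.arange(50), 8), kind="stable")
        ranking = RarityRanking(order, np.linspace(1, 0, len(order)))
        assert flag_concentrated_subdomains(ranking, tiling, cfg) == set()

    def test_top_k_clamped_with_warning(self):
        tiling = _uniform_tiling(2, 10)
        ranking = RarityRanking(np.arange(20), np.linspace(1, 0, 20))
        cfg = FilterConfig(top_k=10_000, concentration_threshold=25)
        with pytest.warns(UserWarning, match="top_k"):
            flag_concentrated_subdomains(ranking, tiling, cfg)


class TestApplyFilters:
    def _ranking_and_tiling(self):
        # 10 tiles over 5 frames (2 per frame); ranking by descending id
        tiling = _uniform_tiling(5, 2)
        order = np.arange(10)
        return RarityRanking(order, np.linspace(1, 0.1, 10)), tiling

    def test_no_flags_equals_select_cohort(self):
        ranking, tiling = self._ranking_and_tiling()
        spec = CohortSpec(4)
        out = apply_artifact_filters(ranking, set(), spec, tiling)
        assert np.array_equal(out, select_cohort(ranking, spec))

    def test_flagged_top_tile_replaced_by_next(self):
        ranking, tiling = self._ranking_and_tiling()
        # rank-0 tile is tile 0 in frame 0; flag frame 0
        out = apply_artifact_filters(ranking, {0}, CohortSpec(1), tiling)
        assert list(out) == [2]  # former rank-2 tile (tile 1 also frame 0)

    def test_hand_walked_deletion(self):
        # ranks 1-3 (tiles 0,1,2) live in flagged frames {0, 1}; cohort of 5
        ranking, tiling = self._ranking_and_tiling()
        out = apply_artifact_filters(ranking, {0, 1}, CohortSpec(5), tiling)
        assert list(out) == [4, 5, 6, 7, 8]

    def test_cohort_never_contains_flagged_frames(self, rng):
        tiling = _uniform_tiling(6, 20)
        order = rng.permutation(len(tiling))
        ranking = RarityRanking(order, np.sort(rng.random(len(order)))[::-1])
        flags = {1, 4}
        out = apply_artifact_filters(ranking, flags, CohortSpec(30), tiling)
        assert not set(tiling.frame_ids[out]) & flags
        assert len(out) == 30

    def test_order_preserving_deletion(self, rng):
        tiling = _uniform_tiling(6, 20)
        order = rng.permutation(len(tiling))
        ranking = RarityRanking(order, np.sort(rng.random(len(order)))[::-1])
        out = apply_artifact_filters(ranking, {2}, CohortSpec(50), tiling)
        pos = {int(t): i for i, t in enumerate(ranking.tile_ids)}
        ranks = [pos[int(t)] for t in out]
        assert ranks == sorted(ranks)

    def test_all_frames_flagged_empty_cohort_with_warning(self):
        ranking, tiling = self._ranking_and_tiling()
        with pytest.warns(UserWarning, match="empty"):
            out = apply_artifact_filters(ranking, set(range(5)),
                                         CohortSpec(3), tiling)
        assert len(out) == 0

    def test_unknown_flagged_frame_fatal(self):
        ranking, tiling = self._ranking_and_tiling()
        with pytest.raises(ValueError):
            apply_artifact_filters(ranking, {99}, CohortSpec(2), tiling)


def test_exact_bookkeeping_on_artifact_slide(rng):
    """Artifacts in 2 of 12 frames: filtering removes exactly those frames'
    tiles and replaces them with the next-ranked clean tiles."""
    from redetect.artifact_filter import count_specks
    from redetect.synth import SyntheticSlideSpec, make_synthetic_slide
    from redetect.slide_io import FrameGrid

    spec = SyntheticSlideSpec(
        grid=FrameGrid(96, 96, 12), rare_templates=(),
        artifact_frames=(2, 7), common_density=0.5,
        n_specks_per_frame=120, seed=5)
    slide, _ = make_synthetic_slide(spec)
    tiling = tile_slide(slide)
    # speck threshold scaled to the small test frames; concentration rule off
    cfg = FilterConfig(speck_threshold=80, top_k=len(tiling),
                       concentration_threshold=10 ** 9)
    speck_flags = flag_speck_subdomains(count_specks(slide, cfg), cfg)
    assert speck_flags == {2, 7}
    # proxy ranking by total tile intensity (bright artifacts rank high)
    mags = tiling.get_pixels(tiling.tile_ids).sum(axis=(1, 2, 3))
    order = np.argsort(-mags, kind="stable")
    ranking = RarityRanking(tiling.tile_ids[order], mags[order])
    nbar = 20
    out = apply_artifact_filters(ranking, speck_flags, CohortSpec(nbar), tiling)
    survivors = [t for t in ranking.tile_ids
                 if tiling.frame_ids[t] not in speck_flags]
    assert list(out) == survivors[:nbar]
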