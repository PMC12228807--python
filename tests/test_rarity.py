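"""Rarity metric, normalization, ranking, and cohort selection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from redetect.denoiser import DenoiserConfig, NoiseSpec, build_denoiser, train
from redetect.rarity import (CohortSpec, RarityConfig, RarityRanking,
                             TileScores, channel_error, normalize_scores,
                             rank_tiles, rarity_metric, score_slide,
                             select_cohort)
from redetect.slide_io import tile_slide

from conftest import make_slide


class TestChannelError:
    def test_identical_reconstruction_zero(self, rng):
        t = rng.random((4, 32, 32))
        assert np.array_equal(channel_error(t, t.copy()), np.zeros(4))

    def test_single_offset_pixel_in_ck(self):
        clean = np.zeros((4, 32, 32))
        recon = clean.copy()
        recon[1, 5, 7] = 0.3
        e = channel_error(clean, recon)
        assert e == pytest.approx([0, 0.3, 0, 0])

    def test_uniform_offset_in_d_is_32d(self):
        d = 0.01
        clean = np.zeros((4, 32, 32))
        recon = clean.copy()
        recon[0] += d
        e = channel_error(clean, recon)
        assert e[0] == pytest.approx(32 * d)  # sqrt(1024) * d
        assert e[1:] == pytest.approx([0, 0, 0])

    def test_shape_mismatch_fatal(self):
        with pytest.raises(ValueError):
            channel_error(np.zeros((4, 32, 32)), np.zeros((4, 16, 16)))


class TestRarityMetric:
    def test_cd_weight_annihilates_cd_error(self):
        assert rarity_metric(np.array([3.0, 3, 3, 99])) == pytest.approx(3.0)

    def test_zero_errors_zero_rarity(self):
        assert rarity_metric(np.zeros(4)) == 0.0

    def test_negative_error_fatal(self):
        with pytest.raises(ValueError):
            rarity_metric(np.array([1.0, -0.1, 0, 0]))

    def test_default_weights_are_thirds_and_zero(self):
        cfg = RarityConfig()
        assert cfg.channel_weights == pytest.approx((1 / 3, 1 / 3, 1 / 3, 0))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            RarityConfig(channel_weights=(0, 0, 0, 0))

    @given(lam=st.floats(0.1, 50), seed=st.integers(0, 100))
    def test_scaling_errors_scales_rarity_and_preserves_order(self, lam, seed):
        r = np.random.default_rng(seed)
        errors = r.random((10, 4))
        base = rarity_metric(errors)
        scaled = rarity_metric(lam * errors)
        assert scaled == pytest.approx(lam * base)
        assert np.array_equal(np.argsort(-base, kind="stable"),
                              np.argsort(-scaled, kind="stable"))

    def test_cd_blindness(self, rng):
        errors = rng.random((20, 4))
        perturbed = errors.copy()
        perturbed[:, 3] += rng.random(20) * 10
        assert rarity_metric(errors) == pytest.approx(rarity_metric(perturbed))


@pytest.fixture(scope="module")
def trained_setup():
    """Background-dominated slide with one bright unseen object tile.

    Trained long enough (40 steps, path-matched rate) that the model
    reconstructs the dim background instead of its initial gray guess.
    """
    from redetect.denoiser import path_matched_lr

    rng = np.random.default_rng(0)
    grid_px = rng.uniform(0, 0.05, size=(4, 64, 2048)).astype(np.float32)
    # bright CK blob in the 3rd tile of frame 0
    grid_px[1, 8:24, 72:88] = 0.9
    slide = make_slide(grid_px, 2048, 64, 1)
    tiling = tile_slide(slide)  # 128 tiles
    cfg = DenoiserConfig(latent_dim=32, width_scale=1 / 16, batch_size=128,
                         learning_rate=path_matched_lr(len(tiling) * 40, 128),
                         epochs=40, seed=0)
    model = build_denoiser(cfg)
    train(model, tiling, cfg, NoiseSpec(seed=1))
    return model, tiling


class TestScoreSlide:

    def test_repeat_scoring_identical(self, trained_setup):
        model, tiling = trained_setup
        a = score_slide(model, tiling)
        b = score_slide(model, tiling)
        assert np.array_equal(a.rarity, b.rarity)

    def test_unseen_bright_object_scores_highest(self, trained_setup):
        model, tiling = trained_setup
        scores = score_slide(model, tiling)
        assert int(np.argmax(scores.rarity)) == 2

    def test_more_noise_draws_reduce_score_variance(self, trained_setup):
        model, tiling = trained_setup
        spread = {}
        for k in (1, 8):
            reruns = np.stack([
                score_slide(model, tiling, NoiseSpec(seed=s),
                            RarityConfig(noise_draws=k)).rarity
                for s in range(4)])
            spread[k] = reruns.std(axis=0).mean()
        assert spread[8] < spread[1]


class TestNormalize:
    def test_two_tile_fixture(self):
        # tiles with magnitudes 3 and 5 -> M = 4; rarity 4 -> normalized 1
        t = np.zeros((2, 4, 32, 32), dtype=np.float32)
        t[0, 0, 0, 0] = 3.0  # magnitude 3 (single value)
        t[1, 0, 0, 0] = 5.0

        class _T:
            tile_ids = np.arange(2)

            def __len__(self):
                return 2

            def get_pixels(self, ids):
                return t[ids]

        scores = TileScores(np.arange(2), np.full((2, 4), 1.0),
                            np.array([4.0, 4.0]))
        out = normalize_scores(scores, _T())
        assert out.normalized_rarity == pytest.approx([1.0, 1.0])

    def test_linearity(self, small_tiling):
        s1 = TileScores(small_tiling.tile_ids,
                        np.ones((len(small_tiling), 4)),
                        np.full(len(small_tiling), 2.0))
        s2 = TileScores(small_tiling.tile_ids,
                        np.ones((len(small_tiling), 4)),
                        np.full(len(small_tiling), 4.0))
        a = normalize_scores(s1, small_tiling).normalized_rarity
        b = normalize_scores(s2, small_tiling).normalized_rarity
        assert b == pytest.approx(2 * a)

    def test_all_black_slide_fatal(self):
        t = np.zeros((2, 4, 32, 32), dtype=np.float32)

        class _T:
            tile_ids = np.arange(2)

            def __len__(self):
                return 2

            def get_pixels(self, ids):
                return t[ids]

        scores = TileScores(np.arange(2), np.zeros((2, 4)), np.zeros(2))
        with pytest.raises(ValueError, match="all-black"):
            normalize_scores(scores, _T())


class TestRanking:
    def test_descending_order(self):
        scores = TileScores(np.arange(3), np.zeros((3, 4)),
                            np.array([0.2, 0.9, 0.5]))
        r = rank_tiles(scores)
        assert list(r.tile_ids) == [1, 2, 0]

    def test_ties_broken_by_ascending_id(self):
        scores = TileScores(np.arange(5), np.zeros((5, 4)), np.ones(5))
        r = rank_tiles(scores)
        assert list(r.tile_ids) == [0, 1, 2, 3, 4]

    def test_duplicate_ids_fatal(self):
        scores = TileScores(np.array([0, 0, 1]), np.zeros((3, 4)),
                            np.ones(3))
        with pytest.raises(ValueError):
            rank_tiles(scores)

    @given(seed=st.integers(0, 1000))
    def test_ranking_is_permutation(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 50))
        scores = TileScores(np.arange(n), np.zeros((n, 4)), r.random(n))
        ranking = rank_tiles(scores)
        assert sorted(ranking.tile_ids) == list(range(n))
        assert np.all(np.diff(ranking.rarity) <= 0)

    def test_raw_and_normalized_rarity_rank_identically(self, small_tiling):
        r = np.random.default_rng(1)
        scores = TileScores(small_tiling.tile_ids,
                            r.random((len(small_tiling), 4)),
                            r.random(len(small_tiling)))
        normed = normalize_scores(scores, small_tiling)
        by_raw = rank_tiles(normed)
        by_norm = rank_tiles(TileScores(normed.tile_ids,
                                        normed.per_channel_error,
                                        normed.normalized_rarity))
        assert np.array_equal(by_raw.tile_ids, by_norm.tile_ids)


class TestCohort:
    def _ranking(self, n):
        return RarityRanking(np.arange(n)[::-1].copy(),
                             np.sort(np.linspace(0, 1, n))[::-1])

    def test_empty_cohort(self):
        assert len(select_cohort(self._ranking(5), CohortSpec(0))) == 0

    def test_full_cohort_is_whole_ranking(self):
        r = self._ranking(5)
        assert np.array_equal(select_cohort(r, CohortSpec(5)), r.tile_ids)

    def test_oversized_cohort_fatal(self):
        with pytest.raises(ValueError):
            select_cohort(self._ranking(5), CohortSpec(6))

    def test_default_cohort_size_is_2500(self):
        assert CohortSpec().cohort_size == 2500
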