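"""Channel-weighted rarity metric, normalization, ranking, cohort selection.

For each tile the reconstruction residual against the denoiser output is
reduced to one Euclidean norm per channel, e_c; the rarity metric is the
weighted sum rho = sum_c w_c e_c. The default weights are 1/3 for the DAPI,
cytokeratin and vimentin channels and 0 for the CD45/CD31 channel: CD is
highly expressed on the leukocyte supermajority, so down-weighting it keeps
ordinary white blood cells from dominating the top of the ranking while
tumor-associated phenotypes (CK/V/DAPI-defined) are emphasized.

Rarity is reported both raw and normalized by the slide's mean tile
magnitude (the average Euclidean norm of the clean 32x32x4 tile), which puts
slides of different overall brightness on a common scale; since that factor
is one positive constant per slide, ranking by raw and normalized rarity is
identical. Ties are broken by ascending tile id so cohorts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .denoiser import DenoiserModel, NoiseSpec, corrupt
from .slide_io import SlideTiling

DEFAULT_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0, 0.0)


@dataclass(frozen=True)
class RarityConfig:
    channel_weights: tuple[float, ...] = DEFAULT_WEIGHTS
    noise_draws: int = 1
    seed: int = 0
    batch_size: int = 500

    def __post_init__(self) -> None:
        w = np.asarray(self.channel_weights, dtype=float)
        if (w < 0).any():
            raise ValueError(f"channel weights must be >= 0, got {tuple(w)}")
        if not (w > 0).any():
            raise ValueError("at least one channel weight must be positive")
        if self.noise_draws < 1:
            raise ValueError("noise_draws must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Size of the retained rare-tile cohort (a ~1000-fold reduction at the
    full-slide default of 2500 out of ~2.5 million tiles)."""

    cohort_size: int = 2500

    def __post_init__(self) -> None:
        if self.cohort_size < 0:
            raise ValueError("cohort_size must be >= 0")


class TileScores:
    """Per-tile channel errors, rarity, and (optionally) normalized rarity."""

    def __init__(self, tile_ids: np.ndarray, per_channel_error: np.ndarray,
                 rarity: np.ndarray,
                 normalized_rarity: np.ndarray | None = None) -> None:
        self.tile_ids = np.asarray(tile_ids, dtype=np.int64)
        self.per_channel_error = np.asarray(per_channel_error, dtype=np.float64)
        self.rarity = np.asarray(rarity, dtype=np.float64)
        self.normalized_rarity = (None if normalized_rarity is None
                                  else np.asarray(normalized_rarity, dtype=np.float64))
        n = len(self.tile_ids)
        if self.per_channel_error.shape[0] != n or self.rarity.shape[0] != n:
            raise ValueError("score arrays must share one length")
        if (self.per_channel_error < 0).any() or (self.rarity < 0).any():
            raise ValueError("errors and rarity must be non-negative")

    def __len__(self) -> int:
        return len(self.tile_ids)


@dataclass(frozen=True)
class RarityRanking:
    """All tile ids ordered by descending rarity (ties: ascending tile id)."""

    tile_ids: np.ndarray
    rarity: np.ndarray

    def __len__(self) -> int:
        return len(self.tile_ids)


def channel_error(clean: np.ndarray, reconstruction: np.ndarray) -> np.ndarray:
    """Per-channel Euclidean norm of the reconstruction residual.

    Accepts one tile (C, t, t) or a batch (B, C, t, t); returns (C,) or
    (B, C) non-negative magnitudes.
    """
    clean = np.asarray(clean, dtype=np.float64)
    reconstruction = np.asarray(reconstruction, dtype=np.float64)
    if clean.shape != reconstruction.shape:
        raise ValueError(
            f"shape mismatch: clean {clean.shape} vs reconstruction "
            f"{reconstruction.shape}")
    d = clean - reconstruction
    if d.ndim == 3:
        return np.sqrt((d * d).sum(axis=(1, 2)))
    return np.sqrt((d * d).sum(axis=(2, 3)))


def rarity_metric(errors: np.ndarray, config: RarityConfig | None = None) -> np.ndarray:
    """Weighted sum of per-channel error magnitudes: rho = sum_c w_c e_c."""
    config = config or RarityConfig()
    errors = np.asarray(errors, dtype=np.float64)
    if (errors < 0).any():
        raise ValueError("channel errors must be non-negative")
    w = np.asarray(config.channel_weights, dtype=np.float64)
    if errors.ndim == 1:
        return float(errors @ w)
    return errors @ w


def score_slide(model: DenoiserModel, tiling: SlideTiling,
                noise: NoiseSpec | None = None,
                config: RarityConfig | None = None) -> TileScores:
    """Score every tile of a slide with the trained denoiser.

    Each tile is corrupted with K seeded noise draws, reconstructed in
    inference mode, per-channel errors are averaged over draws, and the
    weighted rarity is attached. Fully deterministic for fixed seeds.
    """
    noise = noise or NoiseSpec()
    config = config or RarityConfig()
    n = len(tiling)
    n_ch = len(config.channel_weights)
    errors = np.zeros((n, n_ch), dtype=np.float64)
    ids = tiling.tile_ids
    for b0 in range(0, n, config.batch_size):
        idx = ids[b0:b0 + config.batch_size]
        clean = tiling.get_pixels(idx)
        acc = np.zeros((len(idx), n_ch), dtype=np.float64)
        for k in range(config.noise_draws):
            noisy = np.stack([
                corrupt(px, noise, draw_index=k, tile_id=int(tid))
                for tid, px in zip(idx, clean)
            ])
            recon = model.reconstruct(noisy)
            acc += channel_error(clean, recon)
        errors[b0:b0 + len(idx)] = acc / config.noise_draws
    return TileScores(ids, errors, rarity_metric(errors, config))


def normalize_scores(scores: TileScores, tiling: SlideTiling,
                     batch_size: int = 2048) -> TileScores:
    """Attach normalized rarity: rarity / mean clean-tile magnitude.

    The normalizer M is the average over all tiles of the Euclidean norm of
    the tile's full 4096-value intensity vector. An all-black slide (M = 0)
    has no meaningful rarity scale and is rejected.
    """
    n = len(tiling)
    total = 0.0
    for b0 in range(0, n, batch_size):
        px = tiling.get_pixels(tiling.tile_ids[b0:b0 + batch_size])
        total += np.sqrt(
            (px.astype(np.float64) ** 2).sum(axis=(1, 2, 3))).sum()
    m = total / n
    if m == 0:
        raise ValueError("mean tile magnitude is zero (all-black slide); "
                         "normalized rarity is undefined")
    return TileScores(scores.tile_ids, scores.per_channel_error, scores.rarity,
                      scores.rarity / m)


def rank_tiles(scores: TileScores) -> RarityRanking:
    """Order all tiles by descending rarity, ties broken by ascending id."""
    ids = scores.tile_ids
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate tile_id in scores")
    # lexsort on (tile_id asc, -rarity) -> stable descending-rarity order
    order = np.lexsort((ids, -scores.rarity))
    return RarityRanking(ids[order], scores.rarity[order])


def select_cohort(ranking: RarityRanking, spec: CohortSpec) -> np.ndarray:
    """The first cohort_size entries of the ranking, order preserved."""
    if spec.cohort_size > len(ranking):
        raise ValueError(
            f"cohort_size {spec.cohort_size} exceeds tile count {len(ranking)}")
    return ranking.tile_ids[:spec.cohort_size].copy()
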