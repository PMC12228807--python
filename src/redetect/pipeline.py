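"""End-to-end orchestration: tile -> train -> score -> filter (-> evaluate).

One seeded run takes a normalized slide to a rare-tile cohort and a
machine-readable report. Per-stage seeds are derived from the global seed by
hashing the stage name, so a single integer reproduces the whole run. All
tabular outputs are TSV; floats are written with 6 significant digits and
the ranking as integers so round trips cannot drift.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .artifact_filter import (FilterConfig, count_specks,
                              flag_concentrated_subdomains,
                              flag_speck_subdomains, apply_artifact_filters,
                              subdomain_reports, reports_to_frame)
from .denoiser import (DenoiserConfig, NoiseSpec, build_denoiser, train)
from .evaluation import EventLabel, evaluate_ranking, label_tiles
from .rarity import (CohortSpec, RarityConfig, normalize_scores, rank_tiles,
                     score_slide)
from .slide_io import ChannelSpec, FrameGrid, SlideImage, SlideTiling, tile_slide

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived by stage-name hashing."""
    return int(np.random.SeedSequence(
        [int(global_seed), zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2 ** 31))


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration covering every pipeline stage."""

    channels: tuple[str, ...] = ("D", "CK", "V", "CD")
    frame_width: int = 1362
    frame_height: int = 1004
    n_frames: int = 2304
    tile_size: int = 32
    bit_depth: int = 16
    sigma: float = 0.05
    latent_dim: int = 512
    epochs: int = 1
    learning_rate: float = 1e-5
    batch_size: int = 500
    width_scale: float = 1.0
    channel_weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3, 0.0)
    noise_draws: int = 1
    speck_threshold: int = 500
    speck_intensity_cutoff: float = 0.5
    speck_max_area: int = 10
    top_k: int = 10_000
    concentration_threshold: int = 25
    cohort_size: int = 2500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a flat key/value YAML document; unknown keys are errors."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("channels", "channel_weights"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def grid(self) -> FrameGrid:
        return FrameGrid(self.frame_width, self.frame_height, self.n_frames)

    def channel_spec(self) -> ChannelSpec:
        return ChannelSpec(tuple(self.channels))

    def denoiser_config(self) -> DenoiserConfig:
        return DenoiserConfig(self.latent_dim, self.epochs, self.learning_rate,
                              self.batch_size, self.width_scale,
                              stage_seed(self.seed, "train"))

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(self.sigma, stage_seed(self.seed, "noise"))

    def rarity_config(self) -> RarityConfig:
        return RarityConfig(tuple(self.channel_weights), self.noise_draws,
                            stage_seed(self.seed, "score"), self.batch_size)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(self.speck_threshold, self.speck_intensity_cutoff,
                            self.speck_max_area, self.top_k,
                            self.concentration_threshold)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(self.cohort_size)


@dataclass
class RunReport:
    n_tiles: int = 0
    n_steps: int = 0
    initial_loss: float | None = None
    final_loss: float | None = None
    flagged_frames: list[int] = field(default_factory=list)
    cohort_size: int = 0
    metrics: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _write_scores(path: Path, tiling: SlideTiling, scores, ranking) -> None:
    rank_of = np.empty(len(ranking), dtype=np.int64)
    rank_of[ranking.tile_ids] = np.arange(len(ranking))
    df = pd.DataFrame({
        "tile_id": scores.tile_ids,
        "frame_id": tiling.frame_ids,
        "x": tiling.xs,
        "y": tiling.ys,
        "e_D": scores.per_channel_error[:, 0],
        "e_CK": scores.per_channel_error[:, 1],
        "e_V": scores.per_channel_error[:, 2],
        "e_CD": scores.per_channel_error[:, 3],
        "rarity": scores.rarity,
        "normalized_rarity": scores.normalized_rarity,
        "rank": rank_of,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_cohort(path: Path, cohort: np.ndarray, tiling: SlideTiling,
                  scores) -> None:
    rarity = {int(t): r for t, r in zip(scores.tile_ids, scores.rarity)}
    norm = {int(t): r for t, r in zip(scores.tile_ids, scores.normalized_rarity)}
    df = pd.DataFrame({
        "rank": np.arange(len(cohort)),
        "tile_id": cohort,
        "frame_id": tiling.frame_ids[cohort],
        "x": tiling.xs[cohort],
        "y": tiling.ys[cohort],
        "rarity": [rarity[int(t)] for t in cohort],
        "normalized_rarity": [norm[int(t)] for t in cohort],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_red(slide: SlideImage, config: RunConfig,
            events: list[EventLabel] | None = None,
            out_dir: str | Path | None = None):
    """Execute the four-step pipeline on a normalized slide.

    Returns ``(cohort, report)`` where ``cohort`` is the ordered array of
    rare tile ids surviving artifact filtering, truncated to the configured
    cohort size. When ``events`` are provided, TPR/FPR at the cohort size,
    AUROC, and per-category metrics are added to the report. When
    ``out_dir`` is given, scores.tsv, cohort.tsv, filter_report.tsv and
    run_report.json are written there.
    """
    report = RunReport(config=asdict(config))
    stage = "tile"
    try:
        logger.info("[tile] partitioning slide into %dpx tiles", config.tile_size)
        tiling = tile_slide(slide, config.tile_size)
        report.n_tiles = len(tiling)
        logger.info("[tile] %d tiles", len(tiling))

        stage = "train"
        logger.info("[train] building and training the denoiser")
        model = build_denoiser(config.denoiser_config())
        noise = config.noise_spec()
        train(model, tiling, config.denoiser_config(), noise)
        report.n_steps = len(model.loss_history)
        report.initial_loss = model.loss_history[0]
        report.final_loss = model.loss_history[-1]
        logger.info("[train] %d steps, loss %.4g -> %.4g", report.n_steps,
                    report.initial_loss, report.final_loss)

        stage = "score"
        logger.info("[score] scoring %d tiles", len(tiling))
        scores = score_slide(model, tiling, noise, config.rarity_config())
        scores = normalize_scores(scores, tiling)
        ranking = rank_tiles(scores)

        stage = "filter"
        fcfg = config.filter_config()
        speck_counts = count_specks(slide, fcfg)
        flags = (flag_speck_subdomains(speck_counts, fcfg)
                 | flag_concentrated_subdomains(ranking, tiling, fcfg))
        report.flagged_frames = sorted(flags)
        cohort = apply_artifact_filters(ranking, flags, config.cohort_spec(),
                                        tiling)
        report.cohort_size = len(cohort)
        logger.info("[filter] %d frames flagged; cohort of %d tiles",
                    len(flags), len(cohort))

        if events is not None:
            stage = "evaluate"
            labels = label_tiles(events, tiling)
            report.metrics = evaluate_ranking(ranking, labels, cohort)
            logger.info("[evaluate] TPR %.3f, AUROC %.4f",
                        report.metrics["tpr"], report.metrics["auroc"])

        if out_dir is not None:
            stage = "write"
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            _write_scores(out / "scores.tsv", tiling, scores, ranking)
            _write_cohort(out / "cohort.tsv", cohort, tiling, scores)
            reports_to_frame(
                subdomain_reports(speck_counts, ranking, tiling, fcfg)
            ).to_csv(out / "filter_report.tsv", sep="\t", index=False)
            (out / "run_report.json").write_text(report.to_json())
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return cohort, report
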