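"""Regional artifact removal from the top of the rarity ranking.

Imaging artifacts — bright cytokeratin-channel specks, multi-channel blurs
and streaks — are rare in pixel terms and therefore compete with genuine
rare events for cohort slots, but unlike biology they cluster at specific
locations of the slide. Both filters exploit that: the predefined,
non-overlapping subdomain for counting is the scanner frame.

Rule 1 (specks): count small bright connected components in a frame's CK
channel; a frame whose count strictly exceeds the threshold (500 at full
scale) is flagged. Rule 2 (concentration): count how many of the top-k
(10,000 at full scale) ranked tiles fall in each frame; strictly more than
the concentration threshold (25) flags the frame. Flags from both rules are
unioned, every tile of a flagged frame is deleted from the ranking, and the
cohort is re-drawn from the survivors — so each removed slot is filled by
the next-ranked clean tile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage import measure

from .rarity import CohortSpec, RarityRanking
from .slide_io import SlideImage, SlideTiling

logger = logging.getLogger(__name__)

# Full-scale reference proportions used by for_slide(): the top-10,000 of
# ~2.5M tiles (1/250), and a per-frame concentration threshold of 25 against
# a uniform share of 10,000/2304 frames (~5.76x uniform).
_FULL_SCALE_TILES = 2_500_000
_FULL_SCALE_TOP_K = 10_000
_FULL_SCALE_FRAMES = 2304
_FULL_SCALE_CONC = 25


@dataclass(frozen=True)
class FilterConfig:
    speck_threshold: int = 500
    speck_intensity_cutoff: float = 0.5
    speck_max_area: int = 10
    top_k: int = 10_000
    concentration_threshold: int = 25

    def __post_init__(self) -> None:
        if min(self.speck_threshold, self.speck_max_area, self.top_k,
               self.concentration_threshold) <= 0:
            raise ValueError("all filter thresholds must be positive")
        if not 0 < self.speck_intensity_cutoff < 1:
            raise ValueError("speck_intensity_cutoff must be in (0, 1)")

    @classmethod
    def for_slide(cls, n_tiles: int, n_frames: int, **overrides) -> "FilterConfig":
        """Scale the concentration rule to a slide smaller than full scale,
        preserving the full-scale proportions (top_k fraction and the ratio
        of the concentration threshold to the uniform per-frame share)."""
        top_k = max(1, round(n_tiles * _FULL_SCALE_TOP_K / _FULL_SCALE_TILES))
        uniform_ref = _FULL_SCALE_TOP_K / _FULL_SCALE_FRAMES
        ratio = _FULL_SCALE_CONC / uniform_ref
        conc = max(1, round(top_k / n_frames * ratio))
        cfg = cls(top_k=top_k, concentration_threshold=conc)
        return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class SubdomainReport:
    frame_id: int
    speck_count: int
    top_k_tile_count: int
    flagged_by: frozenset[str]


def detect_specks(slide: SlideImage, frame_id: int,
                  config: FilterConfig | None = None,
                  ck_channel: str = "CK") -> int:
    """Count speck artifacts in one frame's cytokeratin channel.

    A speck is a connected component (8-connectivity) of pixels all above
    ``speck_intensity_cutoff`` with area at most ``speck_max_area`` pixels.
    """
    config = config or FilterConfig()
    if not slide.normalized:
        raise ValueError("slide must be normalized")
    frame = slide.frame_pixels(frame_id)  # raises on unknown frame_id
    ck = frame[slide.channels.index(ck_channel)]
    mask = ck > config.speck_intensity_cutoff
    if not mask.any():
        return 0
    labels = measure.label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())[1:]  # skip background label 0
    return int((areas[areas > 0] <= config.speck_max_area).sum())


def count_specks(slide: SlideImage,
                 config: FilterConfig | None = None) -> np.ndarray:
    """Speck counts for every frame of the slide."""
    config = config or FilterConfig()
    return np.array([detect_specks(slide, f, config)
                     for f in range(slide.grid.n_frames)], dtype=np.int64)


def flag_speck_subdomains(counts: np.ndarray,
                          config: FilterConfig | None = None) -> set[int]:
    """Frames whose speck count strictly exceeds the threshold."""
    config = config or FilterConfig()
    counts = np.asarray(counts)
    return set(np.flatnonzero(counts > config.speck_threshold).tolist())


def flag_concentrated_subdomains(ranking: RarityRanking, tiling: SlideTiling,
                                 config: FilterConfig | None = None) -> set[int]:
    """Frames holding strictly more than the threshold of the top-k tiles."""
    config = config or FilterConfig()
    top_k = config.top_k
    if top_k > len(ranking):
        warnings.warn(
            f"top_k {top_k} exceeds tile count {len(ranking)}; using all "
            f"{len(ranking)} tiles", stacklevel=2)
        logger.warning("top_k %d exceeds tile count %d; using all tiles",
                       top_k, len(ranking))
        top_k = len(ranking)
    top = ranking.tile_ids[:top_k]
    frames = tiling.frame_ids[top]
    counts = np.bincount(frames, minlength=int(tiling.frame_ids.max()) + 1)
    return set(np.flatnonzero(counts > config.concentration_threshold).tolist())


def subdomain_reports(speck_counts: np.ndarray, ranking: RarityRanking,
                      tiling: SlideTiling,
                      config: FilterConfig | None = None) -> list[SubdomainReport]:
    """Per-frame bookkeeping of both rules (for the filter report TSV)."""
    config = config or FilterConfig()
    speck_flags = flag_speck_subdomains(speck_counts, config)
    conc_flags = flag_concentrated_subdomains(ranking, tiling, config)
    top_k = min(config.top_k, len(ranking))
    top_frames = tiling.frame_ids[ranking.tile_ids[:top_k]]
    n_frames = len(speck_counts)
    top_counts = np.bincount(top_frames, minlength=n_frames)
    reports = []
    for f in range(n_frames):
        by = set()
        if f in speck_flags:
            by.add("speck")
        if f in conc_flags:
            by.add("concentration")
        reports.append(SubdomainReport(f, int(speck_counts[f]),
                                       int(top_counts[f]), frozenset(by)))
    return reports


def reports_to_frame(reports: list[SubdomainReport]) -> pd.DataFrame:
    return pd.DataFrame({
        "frame_id": [r.frame_id for r in reports],
        "speck_count": [r.speck_count for r in reports],
        "top_k_tile_count": [r.top_k_tile_count for r in reports],
        "flagged_by": ["+".join(sorted(r.flagged_by)) for r in reports],
    })


def apply_artifact_filters(ranking: RarityRanking, flags: set[int],
                           spec: CohortSpec, tiling: SlideTiling) -> np.ndarray:
    """Delete all tiles of flagged frames, then take the top cohort.

    Deletion is order-preserving, so surviving tiles keep their relative
    ranks and every removed cohort slot is filled by the next-ranked clean
    tile. Returns the ordered cohort tile ids (possibly shorter than
    requested when too few tiles survive).
    """
    known = set(np.unique(tiling.frame_ids).tolist())
    unknown = set(flags) - known
    if unknown:
        raise ValueError(f"flagged frame ids not in tiling: {sorted(unknown)}")
    if flags:
        flag_arr = np.zeros(int(tiling.frame_ids.max()) + 1, dtype=bool)
        flag_arr[list(flags)] = True
        keep = ~flag_arr[tiling.frame_ids[ranking.tile_ids]]
        survivors = ranking.tile_ids[keep]
    else:
        survivors = ranking.tile_ids
    if len(survivors) == 0:
        warnings.warn("all frames flagged; cohort is empty", stacklevel=2)
        logger.warning("all frames flagged; cohort is empty")
    n = min(spec.cohort_size, len(survivors))
    return survivors[:n].copy()
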