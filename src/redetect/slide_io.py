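"""Reading, normalizing, and tiling multichannel immunofluorescence slides.

A slide is a four-channel fluorescence image (DAPI, cytokeratin, vimentin,
CD45/CD31 — "D", "CK", "V", "CD") acquired as a grid of scanner frames
(1362x1004 px each on the instrument this models, 2304 frames per slide).
Frames are stored side by side in a single per-channel mosaic. The unit of
analysis is the tile: a 32x32x4 crop, anchored on a frame origin, with
intensities normalized to [0, 1].

Tiling is per frame: ``floor(w/32) x floor(h/32)`` tiles anchored at the
frame origin, residual right/bottom strips discarded, tile ids assigned
row-major within a frame and frames in ascending id — a deterministic
partition that downstream manifests and tie-breaking rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

DEFAULT_CHANNELS = ("D", "CK", "V", "CD")
DEFAULT_TILE_SIZE = 32


@dataclass(frozen=True)
class ChannelSpec:
    """Ordered fluorescence channel identifiers."""

    names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"channel names must be unique, got {self.names}")

    @property
    def count(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class FrameGrid:
    """Layout of scanner frames inside the slide mosaic.

    ``layout`` maps frame_id -> (x, y) pixel offset of the frame origin in
    the mosaic; frames are non-overlapping. The default constructor packs
    frames row-major into a near-square grid (48x48 for the 2304-frame
    instrument default).
    """

    frame_width: int = 1362
    frame_height: int = 1004
    n_frames: int = 2304
    n_cols: int | None = None

    def __post_init__(self) -> None:
        if self.frame_width <= 0 or self.frame_height <= 0 or self.n_frames <= 0:
            raise ValueError("frame dimensions and count must be positive")
        if self.n_cols is None:
            object.__setattr__(self, "n_cols", int(math.ceil(math.sqrt(self.n_frames))))

    @property
    def n_rows(self) -> int:
        return (self.n_frames + self.n_cols - 1) // self.n_cols

    @property
    def mosaic_shape(self) -> tuple[int, int]:
        """(height, width) of the full per-channel mosaic."""
        return self.n_rows * self.frame_height, self.n_cols * self.frame_width

    def frame_origin(self, frame_id: int) -> tuple[int, int]:
        """Pixel offset (x, y) of the frame origin in the mosaic."""
        if not 0 <= frame_id < self.n_frames:
            raise KeyError(f"frame_id {frame_id} outside [0, {self.n_frames})")
        r, c = divmod(frame_id, self.n_cols)
        return c * self.frame_width, r * self.frame_height

    def frame_of_point(self, x: float, y: float) -> int | None:
        """Frame containing mosaic point (x, y), or None if outside."""
        c = int(x) // self.frame_width
        r = int(y) // self.frame_height
        if c < 0 or c >= self.n_cols or r < 0:
            return None
        fid = r * self.n_cols + c
        return fid if fid < self.n_frames else None


@dataclass
class SlideImage:
    """Per-channel intensity mosaics with their frame layout."""

    channels: ChannelSpec
    grid: FrameGrid
    pixels: np.ndarray  # (n_channels, H, W)
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[0] != self.channels.count:
            raise ValueError(
                f"pixels must be (n_channels, H, W) with n_channels="
                f"{self.channels.count}, got {self.pixels.shape}")
        if self.pixels.shape[1:] != self.grid.mosaic_shape:
            raise ValueError(
                f"pixel mosaic {self.pixels.shape[1:]} does not match the "
                f"frame grid mosaic {self.grid.mosaic_shape}")

    def frame_pixels(self, frame_id: int) -> np.ndarray:
        """(n_channels, frame_height, frame_width) view of one frame."""
        x0, y0 = self.grid.frame_origin(frame_id)
        g = self.grid
        return self.pixels[:, y0:y0 + g.frame_height, x0:x0 + g.frame_width]


@dataclass(frozen=True)
class Tile:
    """One 32x32x4 sub-region; ``pixels`` has shape (n_channels, t, t)."""

    tile_id: int
    frame_id: int
    x: int
    y: int
    pixels: np.ndarray


class SlideTiling:
    """The deterministic non-overlapping tile partition of a slide.

    Stores the coordinate table and a reference to the slide; tile pixel
    blocks are extracted on demand so that multi-million-tile slides never
    need a second full copy in memory.
    """

    def __init__(self, slide: SlideImage | None, frame_ids: np.ndarray,
                 xs: np.ndarray, ys: np.ndarray,
                 tile_size: int = DEFAULT_TILE_SIZE) -> None:
        self.slide = slide
        self.frame_ids = np.asarray(frame_ids, dtype=np.int64)
        self.xs = np.asarray(xs, dtype=np.int64)
        self.ys = np.asarray(ys, dtype=np.int64)
        self.tile_size = int(tile_size)
        if not (len(self.frame_ids) == len(self.xs) == len(self.ys)):
            raise ValueError("coordinate arrays must have equal length")

    def __len__(self) -> int:
        return len(self.frame_ids)

    @property
    def count(self) -> int:
        return len(self)

    @property
    def tile_ids(self) -> np.ndarray:
        return np.arange(len(self), dtype=np.int64)

    def get_pixels(self, tile_ids: np.ndarray) -> np.ndarray:
        """(len(tile_ids), n_channels, t, t) float32 pixel blocks."""
        if self.slide is None:
            raise ValueError("tiling holds no slide pixels (manifest-only)")
        t = self.tile_size
        px = self.slide.pixels
        out = np.empty((len(tile_ids), px.shape[0], t, t), dtype=np.float32)
        for k, tid in enumerate(np.asarray(tile_ids)):
            x, y = self.xs[tid], self.ys[tid]
            out[k] = px[:, y:y + t, x:x + t]
        return out

    def tile(self, tile_id: int) -> Tile:
        t = self.tile_size
        px = None
        if self.slide is not None:
            x, y = self.xs[tile_id], self.ys[tile_id]
            px = np.asarray(self.slide.pixels[:, y:y + t, x:x + t], dtype=np.float32)
        return Tile(int(tile_id), int(self.frame_ids[tile_id]),
                    int(self.xs[tile_id]), int(self.ys[tile_id]), px)

    def tile_of_point(self, x: float, y: float) -> int | None:
        """Tile whose half-open footprint [x0,x0+t) x [y0,y0+t) contains (x, y)."""
        if self.slide is None:
            raise ValueError("requires the slide's frame grid")
        grid = self.slide.grid
        fid = grid.frame_of_point(x, y)
        if fid is None:
            return None
        fx, fy = grid.frame_origin(fid)
        t = self.tile_size
        ci = (int(x) - fx) // t
        cj = (int(y) - fy) // t
        nx = grid.frame_width // t
        ny = grid.frame_height // t
        if ci >= nx or cj >= ny:
            return None  # discarded right/bottom margin
        first = np.searchsorted(self.frame_ids, fid)
        if first >= len(self) or self.frame_ids[first] != fid:
            return None
        return int(first + cj * nx + ci)


def load_slide(paths: dict[str, str | Path] | list[str | Path],
               spec: ChannelSpec | None = None,
               grid: FrameGrid | None = None) -> SlideImage:
    """Read one mosaic TIFF per channel into an un-normalized SlideImage.

    ``paths`` is either an ordered list (one file per channel, in channel
    order) or a mapping from channel name to file.
    """
    spec = spec or ChannelSpec()
    grid = grid or FrameGrid()
    if isinstance(paths, dict):
        missing = [n for n in spec.names if n not in paths]
        if missing:
            raise FileNotFoundError(f"missing channel file(s) for: {', '.join(missing)}")
        ordered = [Path(paths[n]) for n in spec.names]
    else:
        if len(paths) != spec.count:
            raise FileNotFoundError(
                f"expected {spec.count} channel files "
                f"({', '.join(spec.names)}), got {len(paths)}")
        ordered = [Path(p) for p in paths]
    planes = []
    for name, p in zip(spec.names, ordered):
        if not p.exists():
            raise FileNotFoundError(f"channel {name}: file not found: {p}")
        planes.append(tifffile.imread(p))
    shape = planes[0].shape
    for name, pl in zip(spec.names, planes):
        if pl.shape != shape:
            raise ValueError(
                f"channel {name} has dimensions {pl.shape}, "
                f"expected {shape} as in channel {spec.names[0]}")
    if shape != grid.mosaic_shape:
        raise ValueError(
            f"channel mosaics {shape} do not match the frame grid "
            f"mosaic {grid.mosaic_shape}")
    return SlideImage(spec, grid, np.stack(planes), normalized=False)


def normalize_intensities(slide: SlideImage, bit_depth: int = 16) -> SlideImage:
    """Scale raw integer intensities onto [0, 1] by the fixed bit-depth maximum.

    Dividing by ``2**bit_depth - 1`` (rather than a per-slide min-max)
    preserves cross-slide comparability: scanner exposure and gain are set
    for consistent background intensity, so a fixed scale is the meaningful
    one. Idempotent on already-normalized slides.
    """
    if slide.normalized:
        return slide
    full_scale = float(2 ** bit_depth - 1)
    peak = float(slide.pixels.max(initial=0.0))
    if peak > full_scale:
        raise ValueError(
            f"pixel value {peak:g} exceeds the declared {bit_depth}-bit "
            f"full scale {full_scale:g}")
    pixels = np.asarray(slide.pixels, dtype=np.float32) / np.float32(full_scale)
    return SlideImage(slide.channels, slide.grid, pixels, normalized=True)


def tile_slide(slide: SlideImage, tile_size: int = DEFAULT_TILE_SIZE) -> SlideTiling:
    """Partition a normalized slide into non-overlapping tiles."""
    if not slide.normalized:
        raise ValueError("slide must be normalized before tiling")
    g = slide.grid
    if tile_size > g.frame_width or tile_size > g.frame_height:
        raise ValueError(
            f"tile_size {tile_size} exceeds frame dimensions "
            f"{g.frame_width}x{g.frame_height}")
    nx = g.frame_width // tile_size
    ny = g.frame_height // tile_size
    per_frame = nx * ny
    n = per_frame * g.n_frames
    frame_ids = np.repeat(np.arange(g.n_frames, dtype=np.int64), per_frame)
    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    local_x = (ii.ravel() * tile_size)
    local_y = (jj.ravel() * tile_size)
    xs = np.empty(n, dtype=np.int64)
    ys = np.empty(n, dtype=np.int64)
    for fid in range(g.n_frames):
        fx, fy = g.frame_origin(fid)
        xs[fid * per_frame:(fid + 1) * per_frame] = fx + local_x
        ys[fid * per_frame:(fid + 1) * per_frame] = fy + local_y
    return SlideTiling(slide, frame_ids, xs, ys, tile_size)


_MANIFEST_COLUMNS = ["tile_id", "frame_id", "x", "y"]


def write_tile_manifest(tiling: SlideTiling, path: str | Path) -> None:
    """Write the tile coordinate table as TSV (tile_id, frame_id, x, y)."""
    df = pd.DataFrame({
        "tile_id": tiling.tile_ids,
        "frame_id": tiling.frame_ids,
        "x": tiling.xs,
        "y": tiling.ys,
    })
    df.to_csv(path, sep="\t", index=False)


def read_tile_manifest(path: str | Path, slide: SlideImage | None = None,
                       tile_size: int = DEFAULT_TILE_SIZE) -> SlideTiling:
    """Read a tile manifest back into a SlideTiling.

    If ``slide`` is given, coordinates are validated against its frame grid
    and the tiling can serve pixels; otherwise it is coordinate-only.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _MANIFEST_COLUMNS:
        raise ValueError(
            f"malformed manifest {path}: expected columns {_MANIFEST_COLUMNS}, "
            f"got {list(df.columns)}")
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(f"malformed manifest row at line {line}: "
                         f"{df.loc[bad.idxmax()].tolist()}")
    df = coerced.astype(np.int64)
    if len(df) and not np.array_equal(df["tile_id"].to_numpy(),
                                      np.arange(len(df))):
        raise ValueError("manifest tile_ids must be 0..N-1 in order")
    if slide is not None and len(df):
        if df["frame_id"].max() >= slide.grid.n_frames:
            bad = int(df["frame_id"].max())
            raise ValueError(
                f"manifest frame_id {bad} >= n_frames {slide.grid.n_frames}")
    return SlideTiling(slide, df["frame_id"].to_numpy(), df["x"].to_numpy(),
                       df["y"].to_numpy(), tile_size)
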