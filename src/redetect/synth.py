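"""Synthetic slides with known rare events, and a Gaussian-mixture fixture.

The simulator emulates the statistical structure of a liquid-biopsy
immunofluorescence slide that matters to rarity detection, not its optics:

* a supermajority of common leukocyte-like cells with DAPI and CD45/CD31
  signal (about 1.2 cells per tile, matching a few million nucleated cells
  plated across a few million tiles);
* a handful of rare events drawn from the seven phenotype categories, with
  high-contrast cytokeratin or vimentin signal against a CK/V-dark common
  population — the regime of cultured epithelial/endothelial cells spiked
  into normal-donor blood;
* clustered artifacts confined to designated frames: hundreds of bright
  cytokeratin specks plus one multi-channel streak per artifact frame.

Cells are isotropic Gaussian intensity blobs with jittered peak intensity;
the background is a low, noisy baseline. Everything is seeded and
reproducible bit for bit.

The Gaussian-mixture reference provides closed-form score magnitudes
|grad log p(x)| and ancestral sampling, used to validate the theoretical
basis of the rarity metric (reconstruction error ~ sigma^2 |score|) on data
where the score is known exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .evaluation import EVENT_CATEGORIES, EventLabel
from .slide_io import ChannelSpec, FrameGrid, SlideImage

# -- cell templates -----------------------------------------------------------


@dataclass(frozen=True)
class CellTemplate:
    """Peak channel intensities and size of one rendered cell population."""

    name: str
    peaks: tuple[float, float, float, float]  # (D, CK, V, CD) in [0, 1]
    radius: float = 3.0        # Gaussian sigma of the blob, pixels
    radius_spread: float = 0.5
    count: int = 0

    def __post_init__(self) -> None:
        if not all(0 <= p <= 1 for p in self.peaks):
            raise ValueError(f"peak intensities must lie in [0,1]: {self.peaks}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


#: The common population: leukocyte-like, DAPI+CD45/CD31 signal only.
LEUKOCYTE = CellTemplate("leukocyte", (0.55, 0.0, 0.0, 0.6), radius=2.5,
                         radius_spread=0.4)

#: High-contrast rare phenotypes (CK or V peak >= 0.7 against a CK/V-dark
#: common population), emulating bright spiked cells. Epithelial (SK-BR-3
#: model) is D|CK; endothelial (HPAEC model) is D|V|CD.
RARE_TEMPLATES: dict[str, CellTemplate] = {
    "D-|CK": CellTemplate("D-|CK", (0.0, 0.8, 0.0, 0.0), radius=2.5),
    "D|CK": CellTemplate("D|CK", (0.7, 0.85, 0.0, 0.0), radius=3.5),
    "D|CK|V": CellTemplate("D|CK|V", (0.7, 0.8, 0.75, 0.0), radius=3.5),
    "D|CK|V|CD": CellTemplate("D|CK|V|CD", (0.7, 0.8, 0.75, 0.6), radius=3.5),
    "D|V": CellTemplate("D|V", (0.7, 0.0, 0.8, 0.0), radius=3.0),
    "D|V|CD": CellTemplate("D|V|CD", (0.7, 0.0, 0.8, 0.6), radius=3.5),
    "D|CK|CD": CellTemplate("D|CK|CD", (0.7, 0.8, 0.0, 0.6), radius=3.0),
}

EPITHELIAL_CATEGORY = "D|CK"
ENDOTHELIAL_CATEGORY = "D|V|CD"


def default_rare_mix(n_rare: int) -> list[CellTemplate]:
    """``n_rare`` rare cells distributed round-robin over the 7 categories."""
    cats = list(EVENT_CATEGORIES)
    out = []
    for i in range(n_rare):
        out.append(RARE_TEMPLATES[cats[i % len(cats)]])
    return out


def spiked_mix(n_epithelial: int, n_endothelial: int) -> list[CellTemplate]:
    """Spiked-cell study mix: epithelial (D|CK) plus endothelial (D|V|CD)."""
    return ([RARE_TEMPLATES[EPITHELIAL_CATEGORY]] * n_epithelial
            + [RARE_TEMPLATES[ENDOTHELIAL_CATEGORY]] * n_endothelial)


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Study conditions for one synthetic slide.

    The default grid (100 frames of 736x672 px, dimensions multiples of the
    tile size so no margin is discarded) yields 48,300 tiles — a slide-scale
    model about fifty-fold smaller than a real 2.5M-tile slide — with 20
    rare cells and 2 artifact frames.
    """

    grid: FrameGrid = field(default_factory=lambda: FrameGrid(736, 672, 100))
    common_template: CellTemplate = LEUKOCYTE
    common_density: float = 1.2          # common cells per tile
    rare_templates: tuple[CellTemplate, ...] = tuple(default_rare_mix(20))
    artifact_frames: tuple[int, ...] = (3, 47)
    n_specks_per_frame: int = 600
    background_level: float = 0.02
    background_noise: float = 0.01
    intensity_jitter: float = 0.1
    tile_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        bad = [f for f in self.artifact_frames if not 0 <= f < self.grid.n_frames]
        if bad:
            raise ValueError(f"artifact frames outside the grid: {bad}")

    @property
    def n_tiles(self) -> int:
        t = self.tile_size
        per = (self.grid.frame_width // t) * (self.grid.frame_height // t)
        return per * self.grid.n_frames


def render_cell(pixels: np.ndarray, template: CellTemplate,
                position: tuple[float, float], rng: np.random.Generator) -> None:
    """Add one cell (isotropic Gaussian blob per channel) in place.

    Peak intensity is the template peak times (1 + uniform jitter of
    +-10%); the blob sigma is the template radius with its spread. Values
    are clipped to [0, 1] after addition.
    """
    _, h, w = pixels.shape
    cx, cy = position
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"cell position ({cx}, {cy}) outside the slide")
    sigma = max(0.5, rng.normal(template.radius, template.radius_spread))
    jitter = 1.0 + rng.uniform(-0.1, 0.1)
    half = int(math.ceil(3.5 * sigma))
    x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    blob = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2)))
    blob = blob.astype(np.float32)
    for c, peak in enumerate(template.peaks):
        if peak == 0:
            continue
        region = pixels[c, y0:y1, x0:x1]
        np.clip(region + np.float32(peak * jitter) * blob, 0.0, 1.0, out=region)


def _tiled_extent(spec: SyntheticSlideSpec) -> tuple[int, int]:
    t = spec.tile_size
    return ((spec.grid.frame_width // t) * t, (spec.grid.frame_height // t) * t)


def _random_position(spec: SyntheticSlideSpec, rng: np.random.Generator,
                     margin: float = 4.0) -> tuple[float, float]:
    """Uniform position within the tiled region of a random frame."""
    fid = int(rng.integers(spec.grid.n_frames))
    fx, fy = spec.grid.frame_origin(fid)
    tw, th = _tiled_extent(spec)
    return (fx + rng.uniform(margin, tw - margin),
            fy + rng.uniform(margin, th - margin))


def make_synthetic_slide(spec: SyntheticSlideSpec | None = None,
                         ) -> tuple[SlideImage, list[EventLabel]]:
    """Render a synthetic slide; returns it with labels for the rare cells.

    Rare cells are re-drawn (up to 100 attempts each) until pairwise
    separated by at least one tile so each ground-truth event occupies its
    own tile. Labels carry the template's phenotype category; common cells
    and artifacts are unlabeled.
    """
    spec = spec or SyntheticSlideSpec()
    rng = np.random.default_rng(spec.seed)
    channels = ChannelSpec()
    h, w = spec.grid.mosaic_shape
    pixels = np.full((channels.count, h, w), spec.background_level,
                     dtype=np.float32)
    pixels += rng.normal(0.0, spec.background_noise,
                         size=pixels.shape).astype(np.float32)
    np.clip(pixels, 0.0, 1.0, out=pixels)

    n_common = int(round(spec.common_density * spec.n_tiles))
    for _ in range(n_common):
        render_cell(pixels, spec.common_template, _random_position(spec, rng), rng)

    labels: list[EventLabel] = []
    placed: list[tuple[float, float]] = []
    min_sep = float(spec.tile_size)
    for ev_id, template in enumerate(spec.rare_templates):
        for attempt in range(100):
            pos = _random_position(spec, rng, margin=6.0)
            if all((pos[0] - p[0]) ** 2 + (pos[1] - p[1]) ** 2 >= min_sep ** 2
                   for p in placed):
                break
        else:
            raise RuntimeError(
                f"could not place rare cell {ev_id} with {min_sep}px "
                f"separation after 100 attempts")
        render_cell(pixels, template, pos, rng)
        placed.append(pos)
        labels.append(EventLabel(ev_id, pos[0], pos[1], template.name))

    slide = SlideImage(channels, spec.grid, pixels, normalized=True)
    inject_artifacts(slide, spec, rng)
    return slide, labels


def inject_artifacts(slide: SlideImage, spec: SyntheticSlideSpec,
                     rng: np.random.Generator) -> None:
    """Add clustered artifacts to the designated frames, in place.

    Each artifact frame receives ``n_specks_per_frame`` bright cytokeratin
    specks of 1-4 pixels (enough to exceed the full-scale speck threshold
    of 500 per frame) and one bright multi-channel streak across the frame.
    """
    ck = slide.channels.index("CK")
    fw, fh = slide.grid.frame_width, slide.grid.frame_height
    for fid in spec.artifact_frames:
        frame = slide.frame_pixels(fid)
        for _ in range(spec.n_specks_per_frame):
            x = int(rng.integers(1, fw - 2))
            y = int(rng.integers(1, fh - 2))
            n_px = int(rng.integers(1, 5))
            frame[ck, y, x] = rng.uniform(0.85, 0.98)
            offsets = [(0, 1), (1, 0), (1, 1)]
            for dy, dx in offsets[:n_px - 1]:
                frame[ck, y + dy, x + dx] = rng.uniform(0.85, 0.98)
        # one multi-channel streak: a blurred horizontal band
        y0 = int(rng.integers(fh // 4, 3 * fh // 4))
        band = np.zeros((fh, fw), dtype=np.float32)
        band[y0:y0 + 3, :] = rng.uniform(0.5, 0.7)
        band = ndimage.gaussian_filter(band, sigma=1.0)
        for c in range(frame.shape[0]):
            np.clip(frame[c] + band, 0.0, 1.0, out=frame[c])


# -- Gaussian-mixture score reference ----------------------------------------


@dataclass(frozen=True)
class GaussianMixtureRef:
    """A d-dimensional Gaussian mixture with closed-form score function."""

    weights: np.ndarray
    means: np.ndarray        # (k, d)
    covariances: np.ndarray  # (k, d, d)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w <= 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be positive and sum to 1")
        for c in np.asarray(self.covariances, dtype=float):
            if not np.allclose(c, c.T) or np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError("covariances must be symmetric positive-definite")

    @property
    def dim(self) -> int:
        return np.asarray(self.means).shape[1]


def two_component_reference(separation: float = 3.0,
                            var: float = 0.35) -> GaussianMixtureRef:
    """The canonical 2-D two-component mixture used as a validation fixture."""
    return GaussianMixtureRef(
        weights=np.array([0.5, 0.5]),
        means=np.array([[-separation / 2, 0.0], [separation / 2, 0.0]]),
        covariances=np.array([np.eye(2) * var, np.eye(2) * var]),
    )


def gmm_logpdf(gmm: GaussianMixtureRef, x: np.ndarray) -> np.ndarray:
    """log p(x) for points x of shape (n, d)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    comps = []
    for w, mu, cov in zip(gmm.weights, gmm.means, gmm.covariances):
        d = gmm.dim
        diff = x - mu
        prec = np.linalg.inv(cov)
        maha = np.einsum("ni,ij,nj->n", diff, prec, diff)
        logdet = np.linalg.slogdet(cov)[1]
        comps.append(np.log(w) - 0.5 * (maha + logdet + d * np.log(2 * np.pi)))
    stack = np.vstack(comps)
    mx = stack.max(axis=0)
    return mx + np.log(np.exp(stack - mx).sum(axis=0))


def gmm_score(gmm: GaussianMixtureRef, x: np.ndarray) -> np.ndarray:
    """Closed-form score grad log p(x), shape (n, d).

    grad log p = sum_k r_k(x) * Sigma_k^{-1} (mu_k - x) with responsibilities
    r_k proportional to w_k N(x; mu_k, Sigma_k).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, d = x.shape
    log_terms = []
    grads = []
    for w, mu, cov in zip(gmm.weights, gmm.means, gmm.covariances):
        diff = x - mu
        prec = np.linalg.inv(cov)
        maha = np.einsum("ni,ij,nj->n", diff, prec, diff)
        logdet = np.linalg.slogdet(cov)[1]
        log_terms.append(np.log(w) - 0.5 * (maha + logdet + d * np.log(2 * np.pi)))
        grads.append(-diff @ prec.T)
    stack = np.vstack(log_terms)          # (k, n)
    resp = np.exp(stack - stack.max(axis=0))
    resp /= resp.sum(axis=0)
    out = np.zeros_like(x)
    for r, g in zip(resp, grads):
        out += r[:, None] * g
    return out


def gmm_score_magnitude(gmm: GaussianMixtureRef, x: np.ndarray) -> np.ndarray:
    """|grad log p(x)| — small in high-density regions, large in the tails."""
    s = gmm_score(gmm, x)
    mag = np.sqrt((s * s).sum(axis=1))
    return mag if np.atleast_2d(np.asarray(x)).shape[0] > 1 else float(mag[0])


def sample_gmm(gmm: GaussianMixtureRef, n: int, seed: int = 0) -> np.ndarray:
    """Seeded ancestral sampling: component by weight, then a Gaussian draw."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    comps = rng.choice(len(gmm.weights), size=n, p=np.asarray(gmm.weights))
    out = np.empty((n, gmm.dim))
    for k, (mu, cov) in enumerate(zip(gmm.means, gmm.covariances)):
        mask = comps == k
        if mask.any():
            out[mask] = rng.multivariate_normal(mu, cov, size=int(mask.sum()))
    return out


def hdr_mask(gmm: GaussianMixtureRef, points: np.ndarray,
             mass: float = 0.5, n_mc: int = 200_000, seed: int = 0) -> np.ndarray:
    """Boolean mask of points inside the highest-density region of given mass.

    The density threshold is the (1-mass) quantile of p(X) under X ~ p,
    estimated by Monte Carlo; points with density above it lie inside the
    HDR.
    """
    samples = sample_gmm(gmm, n_mc, seed=seed)
    log_thresh = np.quantile(gmm_logpdf(gmm, samples), 1 - mass)
    return gmm_logpdf(gmm, points) >= log_thresh
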