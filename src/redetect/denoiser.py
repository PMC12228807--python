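"""Denoising autoencoder trained per slide on its own tiles.

The model is trained to reconstruct a clean tile x from a corrupted version
x + eps, where eps is uncorrelated homoscedastic Gaussian pixel noise with
standard deviation sigma (0.05 in normalized intensity units). The loss is

    L(r) = (1/N) sum_i || x_i - r(x_i + eps) ||_2^2,

the squared Euclidean norm summed over all 32*32*4 values of a tile,
averaged over the batch. For such a model the reconstruction residual
approximates sigma^2 times the score grad log p(x) of the tile distribution,
which is what makes its magnitude a principled rarity measure: common tiles
(the leukocyte supermajority) sit where the density is high and the score is
small; rare tiles sit in the tails where the score is large.

Architecture: a symmetric convolutional encoder/decoder. The encoder
interleaves 3x3 convolutions and densely connected blocks while halving the
spatial grid with 2x2 average pooling (32 -> 2 over four poolings, widths
32-64-128-256-512), flattens to 2048 and maps through fully connected layers
(with one batch-norm) to a 512-dimensional latent code; the decoder mirrors
this with nearest-neighbour upsampling and ends in a 4-channel sigmoid so
every reconstructed intensity lies in (0, 1). ``width_scale`` multiplies all
internal widths (rounded up, minimum one filter) so the identical layer
sequence can run at desk scale; 1.0 reproduces the reference widths exactly.

Training follows the per-slide protocol: a single epoch over all tiles,
Adam, learning rate 1e-5, batch size 500, fresh noise per tile per step,
fully seeded. ``path_matched_lr`` rescales the learning rate for corpora
much smaller than a whole slide so the optimizer traverses the same total
path length (steps x lr) as the full-scale protocol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .slide_io import SlideTiling, Tile

TILE_SIZE = 32
N_CHANNELS = 4
TILE_VALUES = TILE_SIZE * TILE_SIZE * N_CHANNELS

# Reference full-scale training protocol: ~2.5M tiles / batch 500 -> 5000
# Adam steps at lr 1e-5.
REFERENCE_STEPS = 5000
REFERENCE_LR = 1e-5


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian corruption in normalized-intensity units."""

    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class DenoiserConfig:
    latent_dim: int = 512
    epochs: int = 1
    learning_rate: float = REFERENCE_LR
    batch_size: int = 500
    width_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.width_scale <= 1:
            raise ValueError("width_scale must be in (0, 1]")


def path_matched_lr(n_tiles: int, batch_size: int = 500, epochs: int = 1) -> float:
    """Learning rate preserving the full-scale optimizer path length.

    Adam's per-step parameter displacement is ~lr, so a corpus yielding S
    optimizer steps matches the reference protocol's total displacement
    (REFERENCE_STEPS * REFERENCE_LR) when lr = that product / S.
    """
    steps = max(1, math.ceil(n_tiles / batch_size) * epochs)
    return REFERENCE_LR * REFERENCE_STEPS / steps


class DenoiserModel:
    """Encoder/decoder pair realizing the reconstruction map r(.)."""

    def __init__(self, encoder: nn.Sequential, decoder: nn.Sequential,
                 config: DenoiserConfig, input_shape: tuple[int, ...],
                 kind: str = "conv") -> None:
        self.encoder = encoder
        self.decoder = decoder
        self.config = config
        self.input_shape = tuple(input_shape)
        self.kind = kind
        self.loss_history: list[float] = []

    def params(self) -> list[nn.Param]:
        return self.encoder.params() + self.decoder.params()

    def _to_internal(self, x: np.ndarray) -> np.ndarray:
        # convolutional layers run channels-last internally
        if self.kind == "conv":
            return np.ascontiguousarray(np.moveaxis(x, 1, -1))
        return x

    def _from_internal(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "conv":
            return np.ascontiguousarray(np.moveaxis(x, -1, 1))
        return x

    def encode(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.encoder.forward(self._to_internal(x), train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = self.encoder.forward(self._to_internal(x), train)
        return self._from_internal(self.decoder.forward(z, train))

    def backward(self, g: np.ndarray) -> np.ndarray:
        gz = self.decoder.backward(self._to_internal(g))
        return self._from_internal(self.encoder.backward(gz))

    def reconstruct(self, noisy: np.ndarray) -> np.ndarray:
        """Inference-mode reconstruction of one input or a batch."""
        single = noisy.ndim == len(self.input_shape)
        x = noisy[None] if single else noisy
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model input "
                f"{self.input_shape}")
        out = self.forward(np.ascontiguousarray(x, dtype=np.float32), train=False)
        return out[0] if single else out


def _scaled(width: int, scale: float) -> int:
    return max(1, math.ceil(width * scale))


def build_denoiser(config: DenoiserConfig | None = None) -> DenoiserModel:
    """Build the convolutional denoising autoencoder.

    Raises if ``latent_dim`` exceeds the flattened encoder dimension (the
    latent code would no longer be a bottleneck of the printed layout).
    """
    config = config or DenoiserConfig()
    rng = np.random.default_rng(config.seed)
    w = config.width_scale
    c1, c2, c3, c4, c5 = (_scaled(c, w) for c in (32, 64, 128, 256, 512))
    wide = _scaled(1536, w)
    flat = 2 * 2 * c5
    z = config.latent_dim
    if z > flat:
        raise ValueError(
            f"latent_dim {z} is inconsistent with the flattened encoder "
            f"dimension {flat} (no bottleneck); reduce latent_dim or raise "
            f"width_scale")
    encoder = nn.Sequential([
        nn.Conv3x3(N_CHANNELS, c1, rng), nn.ReLU(),
        nn.DenseBlock(c1, 3, rng),
        nn.Conv3x3(c1, c2, rng), nn.AvgPool2(), nn.ReLU(),
        nn.DenseBlock(c2, 3, rng),
        nn.Conv3x3(c2, c3, rng), nn.AvgPool2(), nn.ReLU(),
        nn.DenseBlock(c3, 3, rng),
        nn.Conv3x3(c3, c4, rng), nn.AvgPool2(), nn.ReLU(),
        nn.DenseBlock(c4, 3, rng),
        nn.Conv3x3(c4, c5, rng), nn.AvgPool2(), nn.ReLU(),
        nn.Flatten(),
        nn.Linear(flat, wide, rng), nn.ReLU(), nn.BatchNorm1d(wide),
        nn.Linear(wide, z, rng), nn.ReLU(),
        nn.Linear(z, z, rng, init="linear"),
    ])
    decoder = nn.Sequential([
        nn.Linear(z, z, rng), nn.ReLU(),
        nn.Linear(z, wide, rng), nn.ReLU(), nn.BatchNorm1d(wide),
        nn.Linear(wide, flat, rng), nn.ReLU(),
        nn.Reshape((2, 2, c5)),
        nn.Conv3x3(c5, c4, rng), nn.ReLU(), nn.Upsample2(),
        nn.DenseBlock(c4, 3, rng),
        nn.Conv3x3(c4, c3, rng), nn.ReLU(), nn.Upsample2(),
        nn.DenseBlock(c3, 3, rng),
        nn.Conv3x3(c3, c2, rng), nn.ReLU(), nn.Upsample2(),
        nn.DenseBlock(c2, 3, rng),
        nn.Conv3x3(c2, c1, rng), nn.ReLU(), nn.Upsample2(),
        nn.DenseBlock(c1, 3, rng),
        nn.Conv3x3(c1, N_CHANNELS, rng, init="linear"), nn.Sigmoid(),
    ])
    return DenoiserModel(encoder, decoder, config,
                         (N_CHANNELS, TILE_SIZE, TILE_SIZE), kind="conv")


def build_dense_denoiser(input_dim: int, latent_dim: int = 16,
                         hidden: tuple[int, ...] = (128, 64),
                         seed: int = 0) -> DenoiserModel:
    """Fully connected denoiser for low-dimensional (non-image) data.

    Same latent contract and loss as the convolutional model, but the layers
    are plain fully connected stacks and the output is linear (the data are
    not intensities in [0, 1]). Used for validating the score-function
    property on analytically tractable distributions.
    """
    rng = np.random.default_rng(seed)
    dims = (input_dim,) + tuple(hidden)
    enc: list[nn.Layer] = []
    for a, b in zip(dims[:-1], dims[1:]):
        enc += [nn.Linear(a, b, rng), nn.ReLU()]
    enc.append(nn.Linear(dims[-1], latent_dim, rng, init="linear"))
    dec: list[nn.Layer] = []
    rdims = (latent_dim,) + tuple(reversed(hidden))
    for a, b in zip(rdims[:-1], rdims[1:]):
        dec += [nn.Linear(a, b, rng), nn.ReLU()]
    dec.append(nn.Linear(rdims[-1], input_dim, rng, init="linear"))
    config = DenoiserConfig(latent_dim=latent_dim)
    return DenoiserModel(nn.Sequential(enc), nn.Sequential(dec), config,
                         (input_dim,), kind="dense")


def _philox_rng(seed: int, tile_id: int, draw_index: int) -> np.random.Generator:
    # Counter-based stream: one independent substream per (tile, draw).
    key = ((int(seed) & 0xFFFFFFFFFFFFFFFF) << 64) \
        | ((int(tile_id) & 0xFFFFFFFF) << 32) \
        | (int(draw_index) & 0xFFFFFFFF)
    return np.random.Generator(np.random.Philox(key=key))


def corrupt(tile: Tile | np.ndarray, noise: NoiseSpec, draw_index: int = 0,
            tile_id: int | None = None) -> np.ndarray:
    """Add seeded Gaussian noise to a clean tile.

    Deterministic given (noise.seed, tile_id, draw_index); the output is
    intentionally not clipped to [0, 1] — the clean tile remains the
    regression target.
    """
    if isinstance(tile, Tile):
        pixels, tid = tile.pixels, tile.tile_id
    else:
        pixels, tid = tile, (0 if tile_id is None else tile_id)
    pixels = np.asarray(pixels, dtype=np.float32)
    if noise.sigma == 0:
        return pixels.copy()
    rng = _philox_rng(noise.seed, tid, draw_index)
    eps = rng.normal(0.0, noise.sigma, size=pixels.shape).astype(np.float32)
    return pixels + eps


def reconstruction_loss(clean: np.ndarray, recon: np.ndarray) -> float:
    """Mean over the batch of the summed squared reconstruction residual."""
    if clean.shape != recon.shape:
        raise ValueError(f"shape mismatch: {clean.shape} vs {recon.shape}")
    d = (np.asarray(clean, dtype=np.float64)
         - np.asarray(recon, dtype=np.float64))
    return float((d * d).sum() / d.shape[0])


def training_loss(model: DenoiserModel, tiles: np.ndarray,
                  noise: NoiseSpec, draw_index: int = 0) -> float:
    """Evaluate the denoising loss on a batch of clean tiles.

    Each tile is corrupted with its seeded noise draw, reconstructed in
    inference mode, and the per-tile summed squared error is averaged.
    """
    tiles = np.asarray(tiles, dtype=np.float32)
    if tiles.ndim == len(model.input_shape):
        tiles = tiles[None]
    if tiles.shape[0] == 0:
        raise ValueError("empty batch")
    noisy = np.stack([
        corrupt(t, noise, draw_index=draw_index, tile_id=i)
        for i, t in enumerate(tiles)
    ])
    recon = model.reconstruct(noisy)
    return reconstruction_loss(tiles, recon)


def train(model: DenoiserModel, tiling: SlideTiling | np.ndarray,
          config: DenoiserConfig | None = None,
          noise: NoiseSpec | None = None) -> DenoiserModel:
    """Train the denoiser on a slide's tiles (or a raw sample array).

    ``config.epochs`` passes over a seeded random permutation of the corpus
    in batches of ``config.batch_size`` (last batch kept); fresh noise is
    drawn for every tile at every step; updates use Adam at the configured
    learning rate. The per-step loss trajectory is stored on
    ``model.loss_history``.
    """
    config = config or model.config
    noise = noise or NoiseSpec()
    n = len(tiling) if isinstance(tiling, SlideTiling) else tiling.shape[0]
    if n < 1:
        raise ValueError("training corpus must contain at least one tile")
    perm_rng = np.random.default_rng(config.seed + 1)
    noise_rng = np.random.default_rng(noise.seed + 1)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    for _ in range(config.epochs):
        order = perm_rng.permutation(n)
        for b0 in range(0, n, config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            if isinstance(tiling, SlideTiling):
                clean = tiling.get_pixels(idx)
            else:
                clean = np.asarray(tiling[idx], dtype=np.float32)
            if noise.sigma > 0:
                noisy = clean + noise_rng.normal(
                    0.0, noise.sigma, size=clean.shape).astype(np.float32)
            else:
                noisy = clean
            out = model.forward(noisy, train=True)
            d = out - clean
            loss = float((d.astype(np.float64) ** 2).sum() / d.shape[0])
            model.loss_history.append(loss)
            opt.zero_grad()
            model.backward(d * np.float32(2.0 / d.shape[0]))
            opt.step()
    return model


def denoise(model: DenoiserModel, noisy: np.ndarray) -> np.ndarray:
    """Reconstruct a (possibly corrupted) tile; values in (0, 1) for the
    convolutional model by the final sigmoid."""
    return model.reconstruct(noisy)


def save_checkpoint(model: DenoiserModel, path: str | Path) -> None:
    """Write model parameters (npz) plus a JSON sidecar with the config."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for i, p in enumerate(model.params()):
        arrays[f"p{i:04d}"] = p.value
    for j, layer in enumerate(model.encoder.layers + model.decoder.layers):
        if isinstance(layer, nn.BatchNorm1d):
            arrays[f"bn{j:04d}_mean"] = layer.running_mean
            arrays[f"bn{j:04d}_var"] = layer.running_var
    np.savez(path, **arrays)
    sidecar = {
        "kind": model.kind,
        "config": asdict(model.config),
        "input_shape": list(model.input_shape),
        "final_loss": model.loss_history[-1] if model.loss_history else None,
        "n_steps": len(model.loss_history),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> DenoiserModel:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    if sidecar["kind"] != "conv":
        raise ValueError("only convolutional checkpoints are rebuildable")
    config = DenoiserConfig(**sidecar["config"])
    model = build_denoiser(config)
    npz = str(path)
    if not npz.endswith(".npz"):
        npz += ".npz"  # np.savez appends the suffix when absent
    with np.load(npz) as data:
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i:04d}"]
        for j, layer in enumerate(model.encoder.layers + model.decoder.layers):
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean = data[f"bn{j:04d}_mean"]
                layer.running_var = data[f"bn{j:04d}_var"]
    return model
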