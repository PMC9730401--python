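"""Attention-gated 2D U-Net for multi-sequence parotid/tumor segmentation.

The network is an encoder-decoder with skip connections. Each resolution
level is a run of (3x3 conv -> batch norm -> ReLU) blocks; 2x2 max pooling
halves resolution between encoder levels and bilinear upsampling restores it
in the decoder. Every skip connection passes through an additive attention
gate whose gating signal is, by default, the bottleneck feature map (the
deepest features), resampled to the skip resolution — a per-level multiplying
mask in [0, 1] that suppresses responses outside the attended region. The
four output channels (left/right parotid, left/right tumor) get independent
per-pixel sigmoids, so nested structures (a tumor inside its parotid) can
both be foreground at one pixel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, no_grad
from .data import ROI_NAMES, RoiLabelVolume, SEQUENCES
from .errors import ConfigError
from .layers import AttentionGate, ConvBlock, Module


def _default_allocation(depth: int) -> list[int]:
    # Default depth 4 -> [2, 2, 2, 3, 3]: 12 encoder conv blocks over five
    # resolution levels, bottleneck last.
    if depth == 4:
        return [2, 2, 2, 3, 3]
    return [2] * (depth + 1)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``encoder_block_allocation`` lists the number of conv blocks per encoder
    resolution level (bottleneck included, last entry); the default for depth
    4 sums to 12. ``gate_source`` selects where the attention gating signal
    comes from: the network bottleneck (default) or the adjacent coarser
    decoder feature (the standard attention U-Net wiring).
    """

    in_channels: int = 3
    out_channels: int = 4
    input_size: int = 512
    depth: int = 4
    base_filters: int = 64
    encoder_block_allocation: list[int] | None = None
    decoder_blocks_per_level: int = 2
    gate_source: str = "bottleneck"
    inter_channel_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.encoder_block_allocation is None:
            self.encoder_block_allocation = _default_allocation(self.depth)
        self.validate()

    def validate(self):
        if not 1 <= self.in_channels <= len(SEQUENCES):
            raise ConfigError(f"in_channels must be 1..3, got {self.in_channels}")
        if self.input_size % (2**self.depth) != 0:
            raise ConfigError(
                f"input_size {self.input_size} not divisible by 2^depth={2**self.depth}"
            )
        alloc = self.encoder_block_allocation
        if len(alloc) != self.depth + 1 or any(a < 1 for a in alloc):
            raise ConfigError(
                f"encoder_block_allocation needs {self.depth + 1} entries >= 1, got {alloc}"
            )
        if self.gate_source not in ("bottleneck", "adjacent_decoder"):
            raise ConfigError(f"unknown gate_source {self.gate_source!r}")

    def filters_at(self, level: int) -> int:
        return self.base_filters * (2**level)


class AttentionUNet(Module):
    """The segmentation network. Arrays are channel-last at the interface
    ((batch, H, W, C)); internal layout is channel-first."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        alloc = config.encoder_block_allocation
        d = config.depth

        self.encoder_levels: list[list[ConvBlock]] = []
        ch = config.in_channels
        for level in range(d + 1):
            f = config.filters_at(level)
            blocks = []
            for _ in range(alloc[level]):
                blocks.append(ConvBlock(ch, f, rng))
                ch = f
            self.encoder_levels.append(blocks)

        self.up_blocks: list[ConvBlock] = []
        self.gates: list[AttentionGate] = []
        self.decoder_levels: list[list[ConvBlock]] = []
        gate_ch = (
            config.filters_at(d)
            if config.gate_source == "bottleneck"
            else None
        )
        for level in range(d - 1, -1, -1):
            f = config.filters_at(level)
            self.up_blocks.append(ConvBlock(config.filters_at(level + 1), f, rng))
            g_ch = gate_ch if gate_ch is not None else config.filters_at(level + 1)
            inter = max(1, int(f * config.inter_channel_ratio))
            self.gates.append(AttentionGate(f, g_ch, inter, rng))
            blocks = [ConvBlock(2 * f, f, rng)]
            for _ in range(config.decoder_blocks_per_level - 1):
                blocks.append(ConvBlock(f, f, rng))
            self.decoder_levels.append(blocks)

        from .layers import Conv2d

        self.head = Conv2d(config.filters_at(0), config.out_channels, 1, rng)
        self.training = True

    # -- introspection ------------------------------------------------------

    @property
    def encoder_conv_block_count(self) -> int:
        return sum(len(b) for b in self.encoder_levels)

    @property
    def pool_stage_count(self) -> int:
        return self.config.depth

    @property
    def attention_masks(self) -> dict[int, np.ndarray]:
        """Per-skip-level attention masks of the most recent forward pass,
        keyed by encoder level (0 = finest)."""
        d = self.config.depth
        return {
            d - 1 - i: g.last_mask
            for i, g in enumerate(self.gates)
            if g.last_mask is not None
        }

    # -- forward ------------------------------------------------------------

    def __call__(self, x) -> Tensor:
        """Map (batch, H, W, in_channels) to (batch, H, W, out_channels)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4 or x.shape[3] != self.config.in_channels:
            raise ConfigError(
                f"expected (N, H, W, {self.config.in_channels}) input, got {x.shape}"
            )
        if x.shape[1] % (2**self.config.depth) or x.shape[2] % (2**self.config.depth):
            raise ConfigError(
                f"spatial size {x.shape[1:3]} not divisible by 2^depth"
            )
        h = ad.transpose(x, (0, 3, 1, 2))
        skips: list[Tensor] = []
        for level, blocks in enumerate(self.encoder_levels):
            for block in blocks:
                h = block(h)
            if level < self.config.depth:
                skips.append(h)
                h = ad.max_pool2x2(h)
        bottleneck = h
        self.last_bottleneck_shape = tuple(bottleneck.shape[2:])
        for i, level in enumerate(range(self.config.depth - 1, -1, -1)):
            skip = skips[level]
            target = skip.shape[2:]
            coarse = h
            h = self.up_blocks[i](ad.resize_bilinear(h, *target))
            gate_src = bottleneck if self.config.gate_source == "bottleneck" else coarse
            gated = self.gates[i](skip, gate_src)
            h = ad.concat([gated, h], axis=1)
            for block in self.decoder_levels[i]:
                h = block(h)
        out = ad.sigmoid(self.head(h))
        return ad.transpose(out, (0, 2, 3, 1))


def build_model(config: ModelConfig) -> AttentionUNet:
    """Construct a seeded network from its configuration."""
    return AttentionUNet(config)


# -- case-level inference ---------------------------------------------------


def predict_case(model: AttentionUNet, volume, threshold: float = 0.5,
                 sequences=None, batch_size: int = 4) -> RoiLabelVolume:
    """Segment one case volume slice by slice.

    The volume is normalized and grid-fitted exactly as in training, each
    axial slice is passed through the network in eval mode, sigmoid outputs
    are thresholded (default 0.5) and the binary masks are mapped back onto
    the native grid through the recorded grid transform.
    """
    from .io_preprocess import make_slice_dataset  # imported here to stay cycle-free

    if hasattr(volume, "volume"):  # PhantomCase-like container
        volume = volume.volume
    elif isinstance(volume, tuple):  # (volume, labels) pair
        volume = volume[0]
    samples = make_slice_dataset(
        [(volume, None)], sequences, target_size=model.config.input_size
    )
    model.eval()
    native = volume.grid_shape
    masks = np.zeros(native + (len(ROI_NAMES),), dtype=np.uint8)
    with no_grad():
        for start in range(0, len(samples), batch_size):
            chunk = samples[start : start + batch_size]
            batch = np.stack([s.image for s in chunk]).astype(np.float32)
            pred = model(batch).data
            for s, p in zip(chunk, pred):
                binary = (p >= threshold).astype(np.uint8)
                masks[s.slice_index] = s.grid_transform.inverse(binary)
    return RoiLabelVolume(masks=masks, spacing=volume.spacing)


# -- checkpointing ----------------------------------------------------------


def save_checkpoint(model: AttentionUNet, path):
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, config=json.dumps(asdict(model.config)), **arrays)


def load_checkpoint(path) -> AttentionUNet:
    with np.load(path, allow_pickle=False) as z:
        config = ModelConfig(**json.loads(str(z["config"])))
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
    model = AttentionUNet(config)
    model.load_state_arrays(arrays)
    return model
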