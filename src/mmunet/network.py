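"""MM-UNet assembly: four encoders, one decoder, and the ablation variants.

Architecture (default widths, 160x160 input):

* Four independent encoders, one per MRI modality.  Each stage applies a
  residual double convolution (widths 32/64/128/256) and 2x2 max pooling.
  The pre-pool feature of every stage forks into the hybrid attention
  block, whose output feeds the skip connection only; pooling consumes the
  raw feature.
* The dilated convolution block sits per encoder after the second pooling
  (64 channels at 40x40) by default, or after the fourth pooling as a
  control variant.
* The four encoder bottoms (each 10x10x256) are fused by channel
  concatenation to 10x10x1024, then a double convolution expands to 2048.
* Decoder, per stage: a 2x2 stride-2 transposed convolution halves the
  channels; the result is concatenated with the four attention-refined
  skip features of the same stage (which together match its width exactly),
  a double convolution reduces back to the deconvolution width, and the
  deconvolution output is added element-wise as a parameter-free residual.
* A final 1x1 convolution maps to the four class scores; output height and
  width equal the input's.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .blocks import HAB_ORDERS, DilatedConvBlock, HybridAttention, PlainDoubleConv, ResidualConv
from .nn import DTYPE, ConvTranspose2d, Conv2d, Module, load_state_dict, state_dict

DCB_POSITIONS = ("after_stage2", "after_stage4")

VARIANTS = (
    "baseline",
    "dcb_only",
    "hab_only",
    "full",
    "spatial_first",
    "parallel_attention",
    "dcb_after_stage4",
)


@dataclass(frozen=True)
class NetworkConfig:
    """Every architecture hyperparameter of the network."""

    modalities: int = 4
    classes: int = 4
    base_channels: int = 32
    depth: int = 4
    hab_enabled: bool = True
    hab_order: str = "channel_first"
    hab_reduction: int = 1
    dcb_enabled: bool = True
    dcb_position: str = "after_stage2"
    final_kernel: int = 1
    input_size: int = 160
    seed: int = 0

    def __post_init__(self):
        if self.hab_order not in HAB_ORDERS:
            raise ValueError(f"hab_order must be one of {HAB_ORDERS}, got {self.hab_order!r}")
        if self.dcb_position not in DCB_POSITIONS:
            raise ValueError(
                f"dcb_position must be one of {DCB_POSITIONS}, got {self.dcb_position!r}"
            )
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by {2 ** self.depth}"
            )
        if self.final_kernel not in (1, 3):
            raise ValueError("final_kernel must be 1 or 3")
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be positive")

    @property
    def stage_channels(self) -> tuple[int, ...]:
        """Encoder widths; the base width doubles at every stage."""
        return tuple(self.base_channels * 2**s for s in range(self.depth))

    def to_dict(self) -> dict:
        return {
            "modalities": self.modalities,
            "classes": self.classes,
            "base_channels": self.base_channels,
            "depth": self.depth,
            "hab_enabled": self.hab_enabled,
            "hab_order": self.hab_order,
            "hab_reduction": self.hab_reduction,
            "dcb_enabled": self.dcb_enabled,
            "dcb_position": self.dcb_position,
            "final_kernel": self.final_kernel,
            "input_size": self.input_size,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


def make_variant(name: str, **overrides) -> NetworkConfig:
    """Named ablation/control configurations.

    ``baseline`` disables both blocks; ``full`` enables both with
    channel-first attention and the dilated block after the second
    downsampling.  The remaining names modify the full model one switch at
    a time.
    """
    table = {
        "baseline": dict(hab_enabled=False, dcb_enabled=False),
        "dcb_only": dict(hab_enabled=False, dcb_enabled=True),
        "hab_only": dict(hab_enabled=True, dcb_enabled=False),
        "full": dict(hab_enabled=True, dcb_enabled=True),
        "spatial_first": dict(hab_order="spatial_first"),
        "parallel_attention": dict(hab_order="parallel"),
        "dcb_after_stage4": dict(dcb_position="after_stage4"),
    }
    if name not in table:
        raise ValueError(f"unknown variant {name!r}; valid names: {', '.join(VARIANTS)}")
    return NetworkConfig(**{**table[name], **overrides})


class Encoder(Module):
    """One per-modality encoder path."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator, tag: str):
        chans = cfg.stage_channels
        self.stages = [
            ResidualConv(1 if s == 0 else chans[s - 1], chans[s], rng=rng, name=f"{tag}.rc{s+1}")
            for s in range(cfg.depth)
        ]
        self.habs = (
            [
                HybridAttention(
                    chans[s],
                    reduction=cfg.hab_reduction,
                    order=cfg.hab_order,
                    rng=rng,
                    name=f"{tag}.hab{s+1}",
                )
                for s in range(cfg.depth)
            ]
            if cfg.hab_enabled
            else []
        )
        self.dcb = None
        if cfg.dcb_enabled:
            ch = chans[1] if cfg.dcb_position == "after_stage2" else chans[-1]
            self.dcb = DilatedConvBlock(ch, rng=rng, name=f"{tag}.dcb")
        self._dcb_after = 1 if cfg.dcb_position == "after_stage2" else cfg.depth - 1

    def __call__(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        """Returns (skip features per stage, pooled bottom feature)."""
        skips: list[Tensor] = []
        h = x
        for s, stage in enumerate(self.stages):
            feat = stage(h)
            skips.append(self.habs[s](feat) if self.habs else feat)
            h = ad.max_pool2d_2x2(feat)
            if self.dcb is not None and s == self._dcb_after:
                h = self.dcb(h)
        return skips, h


class MMUNetNetwork(Module):
    """The assembled network.  Construction is deterministic from the config seed."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        chans = config.stage_channels
        top = 4 * chans[-1]  # fused width at the bottom (e.g. 1024)
        self.encoders = [
            Encoder(config, rng, tag=f"enc{m}") for m in range(config.modalities)
        ]
        self.bottleneck = PlainDoubleConv(top, 2 * top, 2 * top, rng=rng, name="bottleneck")
        self.deconvs = []
        self.dec_convs = []
        for s in reversed(range(config.depth)):
            w = 4 * chans[s]  # decoder width at stage s (equals the fused skip width)
            self.deconvs.append(ConvTranspose2d(2 * w, w, rng=rng, name=f"deconv{s+1}"))
            self.dec_convs.append(
                PlainDoubleConv(2 * w, w, w, rng=rng, name=f"dec{s+1}")
            )
        self.head = Conv2d(
            4 * chans[0],
            config.classes,
            config.final_kernel,
            pad=config.final_kernel // 2,
            rng=rng,
            name="head",
        )
        self.training = True

    # -- inference --------------------------------------------------------

    def forward(self, x, *, requires_grad: bool = False) -> Tensor:
        """Map a batch (N, 4, H, W) of modality stacks to class scores."""
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))
        if t.ndim != 4 or t.shape[1] != self.config.modalities:
            raise ValueError(
                f"expected input of shape (N, {self.config.modalities}, H, W), got {t.shape}"
            )
        if t.shape[2] % 2**self.config.depth or t.shape[3] % 2**self.config.depth:
            raise ValueError(
                f"spatial size {t.shape[2]}x{t.shape[3]} must be divisible by "
                f"{2 ** self.config.depth}"
            )
        if requires_grad:
            t.requires_grad = True

        all_skips: list[list[Tensor]] = []
        bottoms: list[Tensor] = []
        for m, enc in enumerate(self.encoders):
            skips, bottom = enc(t[:, m : m + 1])
            all_skips.append(skips)
            bottoms.append(bottom)
        h = self.bottleneck(ad.concat(bottoms, axis=1))
        for i, s in enumerate(reversed(range(self.config.depth))):
            up = self.deconvs[i](h)
            merged = ad.concat([up] + [sk[s] for sk in all_skips], axis=1)
            h = self.dec_convs[i](merged) + up
        return self.head(h)

    def predict_labels(self, x) -> np.ndarray:
        """Argmax class map (N, H, W) in evaluation mode."""
        was_training = self.training
        self.set_train(False)
        try:
            scores = self.forward(x)
        finally:
            self.set_train(was_training)
        return scores.data.argmax(axis=1).astype(np.int16)

    # -- accounting -------------------------------------------------------

    def summary(self) -> str:
        """Per-stage shape table (diffable against the published layout)."""
        cfg = self.config
        size = cfg.input_size
        chans = cfg.stage_channels
        m = cfg.modalities
        rows = [f"Input                {m}@{size}*{size}*1"]
        s_px = size
        for s, c in enumerate(chans):
            rows.append(f"Encoder stage {s+1}      {m}@{s_px}*{s_px}*{c}")
            s_px //= 2
            rows.append(f"Max pooling [2*2]    {m}@{s_px}*{s_px}*{c}")
            if cfg.dcb_enabled and (
                (cfg.dcb_position == "after_stage2" and s == 1)
                or (cfg.dcb_position == "after_stage4" and s == cfg.depth - 1)
            ):
                rows.append(f"Dilated conv block   {m}@{s_px}*{s_px}*{c}")
        top = m * chans[-1]
        rows.append(f"Multimodal fusion    {s_px}*{s_px}*{top}")
        rows.append(f"Bottleneck conv      {s_px}*{s_px}*{2 * top}")
        for s in reversed(range(cfg.depth)):
            w = 4 * chans[s]
            s_px *= 2
            rows.append(f"Upsampling + fusion  {s_px}*{s_px}*{2 * w}")
            rows.append(f"Decoder stage {s+1}      {s_px}*{s_px}*{w}")
        rows.append(f"Output conv [{cfg.final_kernel}*{cfg.final_kernel}]     {size}*{size}*{cfg.classes}")
        rows.append(f"Parameters           {self.count_parameters():,}")
        return "\n".join(rows)

    def flops_estimate(self) -> float:
        """Multiply-accumulate count for one forward pass, in units of 1e9.

        Convention: one MAC per kernel tap per output element for every
        convolution, transposed convolution (dense k^2 per output pixel)
        and linear layer; pooling, normalization, activations and additions
        are not counted.
        """
        cfg = self.config
        chans = cfg.stage_channels
        size = cfg.input_size
        total = 0.0
        # encoders
        px = size
        for s, c in enumerate(chans):
            cin = 1 if s == 0 else chans[s - 1]
            total += cfg.modalities * px * px * (9 * cin * c + 9 * c * c + cin * c)
            if cfg.hab_enabled:
                total += cfg.modalities * (
                    3 * 2 * c * (c // cfg.hab_reduction) + 49 * 3 * px * px
                )
            px //= 2
            if cfg.dcb_enabled and (
                (cfg.dcb_position == "after_stage2" and s == 1)
                or (cfg.dcb_position == "after_stage4" and s == cfg.depth - 1)
            ):
                total += cfg.modalities * px * px * (42 * c * c)
        # bottleneck
        top = cfg.modalities * chans[-1]
        total += px * px * (9 * top * 2 * top + 9 * 2 * top * 2 * top)
        # decoder
        for s in reversed(range(cfg.depth)):
            w = 4 * chans[s]
            px *= 2
            total += px * px * 4 * (2 * w) * w  # deconv, dense convention
            total += px * px * (9 * 2 * w * w + 9 * w * w)
        total += size * size * cfg.final_kernel**2 * 4 * chans[0] * cfg.classes
        return total / 1e9

    # -- persistence ------------------------------------------------------

    def save_weights(self, path) -> None:
        np.savez_compressed(path, **state_dict(self))

    def load_weights(self, path) -> None:
        with np.load(path) as archive:
            load_state_dict(self, dict(archive))


def build(config: NetworkConfig) -> MMUNetNetwork:
    """Construct the network for a validated configuration."""
    return MMUNetNetwork(config)


def variant_network(name: str, **overrides) -> MMUNetNetwork:
    return build(make_variant(name, **overrides))


def parameter_budget_m(config: NetworkConfig) -> float:
    """Total learnable parameters in millions for a configuration."""
    return build(config).count_parameters() / 1e6
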