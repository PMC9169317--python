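"""DNL-Net assembly: Conv+BN encoder, RSEP bottleneck, DNL+MFF decoder.

The network is a U shape.  Each encoder stage is two (3x3 conv -> BN ->
ReLU) layers followed by 2x2 max pooling; channel width doubles per stage.
The bottleneck applies residual SE pyramid pooling (RSEP).  Each decoder
stage runs the deformed non-local block on the deep features and fuses them
with the matching encoder skip through multi-scale feature fusion (MFF),
optionally followed by one refinement conv.  A 1x1 convolution with sigmoid
produces the per-pixel vessel probability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .attention import DNLBlock, fit_reduction
from .fusion import MFFBlock, MFFConfig, RSEPBlock, RSEPConfig
from .nn import Tensor, no_grad
from .nn import functional as F

__all__ = ["DNLNetConfig", "DNLNet", "build_model", "forward",
           "save_checkpoint", "load_checkpoint", "predict_image",
           "TEST_PRESET", "FULL_PRESET"]

_CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class DNLNetConfig:
    """Architecture hyper-parameters.

    ``base_width`` doubles at every encoder stage; input spatial dims must
    be divisible by ``2 ** n_stages``.  ``dnl_rate`` / ``se_reduction`` are
    clamped per block to the largest divisor of the local channel width.
    """
    n_stages: int = 4
    base_width: int = 64
    in_channels: int = 1
    out_classes: int = 1
    dnl_inner: int | None = None       # C̄ of the DNL blocks (default: C)
    dnl_rate: int = 4
    dnl_gate: str = "sigmoid"
    se_reduction: int = 16
    mff: MFFConfig = field(default_factory=MFFConfig)
    rsep: RSEPConfig = field(default_factory=RSEPConfig)
    decoder_refine: bool = True        # extra 3x3 conv+BN+ReLU after each MFF
    bias: bool = True

    def widths(self) -> list[int]:
        """Encoder stage widths plus the bottleneck width."""
        return [self.base_width * 2 ** i for i in range(self.n_stages + 1)]

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "DNLNetConfig":
        raw = json.loads(text)
        raw["mff"] = MFFConfig(**raw["mff"])
        rsep = dict(raw["rsep"])
        rsep["dilations"] = tuple(rsep["dilations"])
        raw["rsep"] = RSEPConfig(**rsep)
        return cls(**raw)


# Small preset used throughout the test-suite; full-scale preset for real runs.
TEST_PRESET = DNLNetConfig(n_stages=2, base_width=8,
                           rsep=RSEPConfig(dilations=(1, 2, 4, 4)))
FULL_PRESET = DNLNetConfig()


def _double_conv(cin: int, cout: int, rng: np.random.Generator,
                 bias: bool) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(cin, cout, 3, rng, padding=1, bias=bias),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
        nn.Conv2d(cout, cout, 3, rng, padding=1, bias=bias),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


class DNLNet(nn.Module):
    """The assembled network; also the serialisable model handle."""

    def __init__(self, config: DNLNetConfig | None = None, seed: int = 0):
        super().__init__()
        cfg = config if config is not None else DNLNetConfig()
        self.config = cfg
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        widths = cfg.widths()

        # encoder
        cin = cfg.in_channels
        self.enc_stages = []
        for i in range(cfg.n_stages):
            stage = _double_conv(cin, widths[i], rng, cfg.bias)
            self.enc_stages.append(stage)
            self._modules[f"enc{i}"] = stage
            cin = widths[i]

        # bottleneck
        self.bottleneck_conv = _double_conv(widths[-2] if cfg.n_stages else
                                            cfg.in_channels,
                                            widths[-1], rng, cfg.bias)
        self.rsep = RSEPBlock(widths[-1], cfg.rsep, rng=rng)

        # decoder: one MFF (with internal DNL) per stage, deepest first
        self.dec_stages = []
        self.refine_stages = []
        for i in reversed(range(cfg.n_stages)):
            deep_c, skip_c = widths[i + 1], widths[i]
            cbar = cfg.dnl_inner if cfg.dnl_inner is not None else deep_c
            dnl = DNLBlock(deep_c, inner_channels=cbar,
                           rate=fit_reduction(cbar, cfg.dnl_rate),
                           se_reduction=cfg.se_reduction, gate=cfg.dnl_gate,
                           rng=rng, bias=cfg.bias)
            mff = MFFBlock(deep_c, skip_c, cfg.mff, dnl=dnl, rng=rng)
            self.dec_stages.append(mff)
            self._modules[f"dec{i}"] = mff
            if cfg.decoder_refine:
                refine = nn.Sequential(
                    nn.Conv2d(skip_c, skip_c, 3, rng, padding=1, bias=cfg.bias),
                    nn.BatchNorm2d(skip_c),
                    nn.ReLU(),
                )
            else:
                refine = nn.Identity()
            self.refine_stages.append(refine)
            self._modules[f"refine{i}"] = refine

        self.head = nn.Conv2d(widths[0] if cfg.n_stages else widths[-1],
                              cfg.out_classes, 1, rng, bias=cfg.bias)

    # -------------------------------------------------------------- forward
    def _check_input(self, x: Tensor) -> None:
        n, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ValueError(f"model expects {self.config.in_channels} input "
                             f"channels, got {c}")
        div = 2 ** self.config.n_stages
        if h % div or w % div:
            raise ValueError(f"input spatial dims {h}x{w} must be divisible "
                             f"by {div} (2^n_stages)")

    def forward(self, x: Tensor) -> Tensor:
        self._check_input(x)
        skips = []
        for stage in self.enc_stages:
            x = stage(x)
            skips.append(x)
            x = F.max_pool2d_2x(x)
        x = self.rsep(self.bottleneck_conv(x))
        for mff, refine, skip in zip(self.dec_stages, self.refine_stages,
                                     reversed(skips)):
            x = refine(mff(x, skip))
        return self.head(x).sigmoid()


def build_model(config: DNLNetConfig | None = None, seed: int = 0) -> DNLNet:
    """Deterministically initialise a DNL-Net from a config and seed."""
    return DNLNet(config, seed)


def forward(model: DNLNet, image: np.ndarray) -> np.ndarray:
    """Run the network in eval mode on a C x H x W (or N x C x H x W) array.

    Returns per-pixel vessel probabilities in [0, 1] with the same rank as
    the input.
    """
    image = np.asarray(image, dtype=np.float64)
    squeeze = image.ndim == 3
    if squeeze:
        image = image[None]
    if image.ndim != 4:
        raise ValueError(f"expected CxHxW or NxCxHxW input, got {image.shape}")
    model.eval()
    with no_grad():
        out = model(Tensor(image)).data
    return out[0] if squeeze else out


# --------------------------------------------------------------------------
# Checkpointing
# --------------------------------------------------------------------------

def save_checkpoint(model: DNLNet, path) -> None:
    """Single-file archive: weights + config snapshot + build seed."""
    state = model.state_dict()
    np.savez(path, __config__=np.array(model.config.to_json()),
             __seed__=np.array(model.seed),
             __version__=np.array(_CHECKPOINT_VERSION), **state)


def load_checkpoint(path) -> DNLNet:
    with np.load(path, allow_pickle=False) as data:
        version = int(data["__version__"])
        if version != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {version}")
        cfg = DNLNetConfig.from_json(str(data["__config__"]))
        model = DNLNet(cfg, seed=int(data["__seed__"]))
        state = {k: data[k] for k in data.files
                 if not k.startswith("__")}
    model.load_state_dict(state)
    return model


# --------------------------------------------------------------------------
# Full-image prediction with overlapped tiling
# --------------------------------------------------------------------------

def _cosine_window(size: int) -> np.ndarray:
    w = np.hanning(size + 2)[1:-1]
    return w / w.max()


def predict_image(model: DNLNet, image: np.ndarray, tile: int | None = None,
                  overlap: float = 0.5) -> np.ndarray:
    """Predict an H x W (or C x H x W) image of arbitrary size.

    Images are reflect-padded to the divisibility constraint.  If `tile` is
    given, overlapping tiles are predicted and blended with a separable
    cosine window (patch-trained models generalise across the seam).
    Returns an H x W probability map.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[None]
    c, h, w = image.shape
    div = 2 ** model.config.n_stages

    if tile is None:
        ph = (-h) % div
        pw = (-w) % div
        padded = np.pad(image, ((0, 0), (0, ph), (0, pw)), mode="reflect")
        prob = forward(model, padded)[0]
        return prob[:h, :w]

    if tile % div:
        raise ValueError(f"tile size {tile} must be divisible by {div}")
    step = max(int(tile * (1.0 - overlap)), 1)
    win = np.outer(_cosine_window(tile), _cosine_window(tile)) + 1e-6
    acc = np.zeros((h, w))
    norm = np.zeros((h, w))
    pad_h, pad_w = max(tile - h, 0), max(tile - w, 0)
    img = np.pad(image, ((0, 0), (0, pad_h), (0, pad_w)), mode="reflect")
    hh, ww = img.shape[1], img.shape[2]
    tops = sorted({min(t, hh - tile) for t in range(0, hh, step)})
    lefts = sorted({min(l, ww - tile) for l in range(0, ww, step)})
    full = np.zeros((hh, ww))
    fnorm = np.zeros((hh, ww))
    for top in tops:
        for left in lefts:
            patch = img[:, top:top + tile, left:left + tile]
            prob = forward(model, patch)[0]
            full[top:top + tile, left:left + tile] += prob * win
            fnorm[top:top + tile, left:left + tile] += win
    acc = full[:h, :w]
    norm = fnorm[:h, :w]
    return acc / norm
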