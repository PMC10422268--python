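"""Channel/spatial attention blocks and the attention encoder-decoder
segmentation network.

The encoder is a five-stage VGG-style stack (conv counts 2,2,3,3,3; widths
64,128,256,512,512) with an attention block between the last convolution
and the 2x2 max pool of every stage.  The decoder upsamples 2x (nearest)
then convolves, and concatenates at each scale with the attention-refined
encoder feature routed through a skip connection.  For the default widths
the decoder concatenations are, for a 256x256 input:
16x16x1024, 32x32x768, 64x64x384, 128x128x192 and finally 256x256x256,
followed by two 3x3 convolutions and a per-pixel softmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

DEFAULT_ENCODER_WIDTHS = (64, 128, 256, 512, 512)
DEFAULT_ENCODER_CONVS = (2, 2, 3, 3, 3)
DEFAULT_DECODER_WIDTHS = (512, 256, 128, 64, 192)
DEFAULT_DECODER_CONVS = (3, 3, 3, 2, 2)
# concatenation channel counts implied by the default widths
PRINTED_CONCAT_CHANNELS = (1024, 768, 384, 192, 256)


@dataclass
class NetworkConfig:
    in_channels: int = 8
    num_classes: int = 3
    input_size: int = 256
    encoder_widths: tuple = DEFAULT_ENCODER_WIDTHS
    encoder_convs: tuple = DEFAULT_ENCODER_CONVS
    decoder_widths: tuple = DEFAULT_DECODER_WIDTHS
    decoder_convs: tuple = DEFAULT_DECODER_CONVS
    head_width: int = 64
    reduction: int = 8            # channel-attention compression ratio r
    attention: bool = True        # False -> no attention blocks
    skip_connections: bool = True  # False -> plain encoder-decoder baseline
    separate_skip_attention: bool = True
    batch_norm: bool = True
    seed: int = 0

    def validate(self):
        if len(self.encoder_widths) != 5 or len(self.encoder_convs) != 5:
            raise ValueError("encoder must have exactly five stages")
        if len(self.decoder_widths) != 5 or len(self.decoder_convs) != 5:
            raise ValueError("decoder must have exactly five blocks")
        if self.reduction < 1:
            raise ValueError("reduction ratio must be >= 1")
        if self.input_size % 32:
            raise ValueError("input size must be divisible by 32")

    def concat_channels(self) -> tuple:
        ew, dw = self.encoder_widths, self.decoder_widths
        return tuple(dw[i] + ew[4 - i] for i in range(5))

    @classmethod
    def scaled(cls, width_scale: float, **kwargs) -> "NetworkConfig":
        """Config with all widths multiplied by `width_scale` (>= 1 channel)."""
        def sc(ws):
            return tuple(max(1, int(round(w * width_scale))) for w in ws)
        kwargs.setdefault("reduction", max(2, int(round(8 * width_scale))))
        return cls(encoder_widths=sc(DEFAULT_ENCODER_WIDTHS),
                   decoder_widths=sc(DEFAULT_DECODER_WIDTHS),
                   head_width=max(1, int(round(64 * width_scale))),
                   **kwargs)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        d = json.loads(text)
        for k in ("encoder_widths", "encoder_convs", "decoder_widths", "decoder_convs"):
            d[k] = tuple(d[k])
        return cls(**d)


class ChannelAttention(nn.Module):
    """Per-channel sigmoid gates from global average/max pooling through a
    shared two-layer perceptron: gate = sigmoid(W1 relu(W0 a) + W1 relu(W0 m))."""

    def __init__(self, channels: int, reduction: int = 8, rng=None):
        super().__init__()
        bottleneck = max(1, channels // reduction)
        self.channels = channels
        self.fc0 = nn.Linear(channels, bottleneck, bias=False, rng=rng)
        self.fc1 = nn.Linear(bottleneck, channels, bias=False, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        if c != self.channels:
            raise ValueError(f"channel mismatch: feature {c}, attention {self.channels}")
        avg = nn.reshape(nn.mean_hw(x), (n, c))
        mx = nn.reshape(nn.max_hw(x), (n, c))
        h = nn.add(self.fc1(nn.relu(self.fc0(avg))),
                   self.fc1(nn.relu(self.fc0(mx))))
        return nn.reshape(nn.sigmoid(h), (n, c, 1, 1))

    def __call__(self, x: Tensor) -> Tensor:
        return nn.mul(x, self.gate(x))


class SpatialAttention(nn.Module):
    """Per-pixel sigmoid gates from channel-wise mean/max pooling and a
    same-padded 7x7 convolution over the 2-channel pooled map."""

    def __init__(self, kernel_size: int = 7, rng=None):
        super().__init__()
        if kernel_size != 7:
            raise ValueError("spatial attention kernel size is fixed at 7")
        self.conv = nn.Conv2d(2, 1, k=7, bias=True, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        pooled = nn.concat([nn.mean_c(x), nn.max_c(x)], axis=1)
        return nn.sigmoid(self.conv(pooled))

    def __call__(self, x: Tensor) -> Tensor:
        return nn.mul(x, self.gate(x))


class CBAM(nn.Module):
    """Channel attention followed by spatial attention, both applied
    multiplicatively; the output shape equals the input shape."""

    def __init__(self, channels: int, reduction: int = 8, rng=None):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        refined = self.channel(x)
        return self.spatial(refined)


class _EncoderStage(nn.Module):
    def __init__(self, cin, cout, n_convs, reduction, attention, batch_norm, rng):
        super().__init__()
        convs = []
        for i in range(n_convs):
            convs.append(nn.ConvBNReLU(cin if i == 0 else cout, cout,
                                       batch_norm=batch_norm, rng=rng))
        self.convs = nn.ModuleList(convs)
        self.cbam = CBAM(cout, reduction, rng=rng) if attention else None

    def __call__(self, x: Tensor):
        for conv in self.convs:
            x = conv(x)
        if self.cbam is not None:
            x = self.cbam(x)
        return nn.maxpool2x2(x), x  # (downsampled, pre-pool feature for skips)


class _DecoderBlock(nn.Module):
    def __init__(self, cin, cout, n_convs, batch_norm, rng):
        super().__init__()
        convs = []
        for i in range(n_convs):
            convs.append(nn.ConvBNReLU(cin if i == 0 else cout, cout,
                                       batch_norm=batch_norm, rng=rng))
        self.convs = nn.ModuleList(convs)

    def __call__(self, x: Tensor) -> Tensor:
        x = nn.upsample2x(x)
        for conv in self.convs:
            x = conv(x)
        return x


class AttentionSegNet(nn.Module):
    """Five-stage attention encoder-decoder segmentation network.

    `forward` returns per-pixel class logits; `last_trace` holds the named
    intermediate shapes of the most recent forward pass for auditing the
    architecture against its printed stage dimensions.
    """

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        cfg.validate()
        if cfg.encoder_widths == DEFAULT_ENCODER_WIDTHS and \
           cfg.decoder_widths == DEFAULT_DECODER_WIDTHS:
            assert cfg.concat_channels() == PRINTED_CONCAT_CHANNELS, \
                "default widths no longer reproduce the published concatenation dims"
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ew, ec = cfg.encoder_widths, cfg.encoder_convs
        dw, dc = cfg.decoder_widths, cfg.decoder_convs
        stages = []
        cin = cfg.in_channels
        for w, n in zip(ew, ec):
            stages.append(_EncoderStage(cin, w, n, cfg.reduction, cfg.attention,
                                        cfg.batch_norm, rng))
            cin = w
        self.stages = nn.ModuleList(stages)
        if cfg.attention and cfg.skip_connections and cfg.separate_skip_attention:
            self.skip_cbams = nn.ModuleList(
                [CBAM(w, cfg.reduction, rng=rng) for w in ew])
        else:
            self.skip_cbams = None
        blocks = []
        cin = ew[-1]
        for i, (w, n) in enumerate(zip(dw, dc)):
            blocks.append(_DecoderBlock(cin, w, n, cfg.batch_norm, rng))
            # the next block consumes the concatenation (or the plain output
            # when skip connections are disabled, SegNet-style)
            cin = w + ew[4 - i] if cfg.skip_connections else w
        self.decoder = nn.ModuleList(blocks)
        head_in = dw[4] + ew[0] if cfg.skip_connections else dw[4]
        self.head_conv = nn.ConvBNReLU(head_in, cfg.head_width,
                                       batch_norm=cfg.batch_norm, rng=rng)
        self.classifier = nn.Conv2d(cfg.head_width, cfg.num_classes, rng=rng)
        self.last_trace: dict[str, tuple] = {}

    def forward(self, x: Tensor, return_features: bool = False):
        if x.ndim != 4:
            raise ValueError("input must be NCHW")
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channels, "
                             f"got {x.shape[1]}")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("spatial dims must be divisible by 32")
        trace = {"input": x.shape}
        skips = []
        for i, stage in enumerate(self.stages):
            x, pre_pool = stage(x)
            trace[f"stage{i + 1}_pre_pool"] = pre_pool.shape
            trace[f"stage{i + 1}_pool"] = x.shape
            skips.append(pre_pool)
        trace["encoder_output"] = x.shape
        for i, block in enumerate(self.decoder):
            x = block(x)
            trace[f"decoder{i + 1}_conv"] = x.shape
            if self.cfg.skip_connections:
                skip = skips[4 - i]
                if self.skip_cbams is not None:
                    skip = self.skip_cbams[4 - i](skip)
                trace[f"skip{i + 1}"] = skip.shape
                x = nn.concat([skip, x], axis=1)
                trace[f"decoder{i + 1}_concat"] = x.shape
        x = self.head_conv(x)
        trace["head"] = x.shape
        logits = self.classifier(x)
        trace["logits"] = logits.shape
        self.last_trace = trace
        if return_features:
            return logits, x
        return logits

    __call__ = forward

    # -- inference helpers --------------------------------------------------
    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (N, k, H, W) in inference mode."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                logits = self.forward(Tensor(batch))
        finally:
            self.train(was_training)
        return nn.softmax(logits.data, axis=1)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Per-pixel argmax class maps (N, H, W)."""
        return self.predict_proba(batch).argmax(axis=1)

    def extract_features(self, batch: np.ndarray) -> np.ndarray:
        """Penultimate-layer feature maps (N, head_width, H, W)."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                _, feats = self.forward(Tensor(batch), return_features=True)
        finally:
            self.train(was_training)
        return feats.data

    def summary(self) -> str:
        """Per-stage shape table from a dry forward pass."""
        size = self.cfg.input_size
        dummy = np.zeros((1, self.cfg.in_channels, size, size), dtype=np.float32)
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                self.forward(Tensor(dummy))
        finally:
            self.train(was_training)
        lines = [f"{'layer':24s} shape (N, C, H, W)"]
        for name, shape in self.last_trace.items():
            lines.append(f"{name:24s} {tuple(shape)}")
        lines.append(f"parameters: {self.num_parameters()}")
        return "\n".join(lines)


def build_a2segnet(cfg: NetworkConfig | None = None) -> AttentionSegNet:
    return AttentionSegNet(cfg or NetworkConfig())


def save_checkpoint(net: AttentionSegNet, path):
    """Weights as .npz next to an architecture JSON for exact rebuild."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **net.state_dict())
    path.with_suffix(".json").write_text(net.cfg.to_json())


def load_checkpoint(path) -> AttentionSegNet:
    path = Path(path)
    cfg = NetworkConfig.from_json(path.with_suffix(".json").read_text())
    net = AttentionSegNet(cfg)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net
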