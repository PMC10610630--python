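"""Dilated 1D U-Net for three-class ECG beat segmentation.

The network maps a single-channel ECG of length L to an L x 3 logit
matrix over (background, normal beat, PVC).  Layout:

* an initial 16-filter dilated convolution (kernel 9, dilation 3);
* four encoder blocks, each a dilated convolution (kernel 9, dilation 3)
  followed by a stride-2 downsampling convolution (kernel 2) — strided
  convolutions take the place of max pooling; filter counts double per
  block (16, 32, 64, 128);
* a single 128-filter dilated bottleneck convolution;
* four decoder blocks, each: linear 2x upsampling, a pointwise (1x1)
  channel-mixing convolution, concatenation with the matching encoder
  skip, a dilated convolution (kernel 9, dilation 3) and a kernel-3
  refinement convolution;
* a 1x1 head from 16 channels to the 3 classes.

Every convolution except the head is bias-free and followed by batch
normalization and ReLU.  With the default configuration the model has
exactly 836,387 trainable parameters.  The first dilated convolution
sees a receptive field of (9 - 1) * 3 + 1 = 25 samples, about 200 ms at
125 Hz.

Inputs are right-padded with zeros to a multiple of 2**depth so that
every downsampling halves exactly; the output is cropped back, so output
length always equals input length.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm1d, Conv1d, ReLU, Upsample2


@dataclass
class UNetConfig:
    """Architecture hyperparameters.

    ``base_filters`` doubles after every encoder block (growth factor);
    ``kernel_size``/``dilation`` apply to the dilated convolutions,
    ``down_kernel`` to the stride-2 downsamplers, ``refine_kernel`` to
    the second convolution of each decoder block.
    """

    in_channels: int = 1
    n_classes: int = 3
    depth: int = 4
    base_filters: int = 16
    growth: int = 2
    kernel_size: int = 9
    dilation: int = 3
    down_stride: int = 2
    down_kernel: int = 2
    refine_kernel: int = 3
    min_input_len: int = 400
    seed: int = 0

    def validate(self):
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for symmetric padding")
        if self.dilation < 1 or self.growth < 1:
            raise ValueError("dilation and growth must be >= 1")

    @property
    def widths(self):
        return [self.base_filters * self.growth ** i for i in range(self.depth)]


def receptive_field_block(k: int, d: int) -> int:
    """Receptive field of one dilated convolution: (k - 1) * d + 1."""
    if k < 1 or d < 1:
        raise ValueError("kernel size and dilation must be >= 1")
    return (k - 1) * d + 1


class _ConvBNReLU:
    def __init__(self, cin, cout, k, stride, dilation, rng):
        self.conv = Conv1d(cin, cout, k, stride=stride, dilation=dilation,
                           bias=False, rng=rng)
        self.bn = BatchNorm1d(cout)
        self.act = ReLU()

    def forward(self, x):
        return self.act.forward(self.bn.forward(self.conv.forward(x)))

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.act.backward(dy)))

    def layers(self):
        return [self.conv, self.bn, self.act]


class UNet1d:
    """See module docstring.  Build via :func:`build_unet`."""

    def __init__(self, cfg: UNetConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.widths
        k, d = cfg.kernel_size, cfg.dilation
        self.stem = _ConvBNReLU(cfg.in_channels, w[0], k, 1, d, rng)
        self.enc = []
        prev = w[0]
        for c in w:
            block_a = _ConvBNReLU(prev, c, k, 1, d, rng)
            down = _ConvBNReLU(c, c, cfg.down_kernel, cfg.down_stride, 1, rng)
            self.enc.append((block_a, down))
            prev = c
        self.bottleneck = _ConvBNReLU(prev, prev, k, 1, d, rng)
        self.dec = []
        for c in reversed(w):
            up = Upsample2()
            proj = _ConvBNReLU(prev, prev, 1, 1, 1, rng)
            conv_a = _ConvBNReLU(prev + c, c, k, 1, d, rng)
            conv_b = _ConvBNReLU(c, c, cfg.refine_kernel, 1, 1, rng)
            self.dec.append((up, proj, conv_a, conv_b))
            prev = c
        self.head = Conv1d(prev, cfg.n_classes, 1, bias=True, rng=rng)
        self._training = True

    # -- plumbing ---------------------------------------------------------

    def _all_layers(self):
        out = list(self.stem.layers())
        for a, dn in self.enc:
            out += a.layers() + dn.layers()
        out += self.bottleneck.layers()
        for up, proj, a, b in self.dec:
            out += [up] + proj.layers() + a.layers() + b.layers()
        out.append(self.head)
        return out

    def train(self, mode: bool = True):
        self._training = mode
        for layer in self._all_layers():
            layer.train(mode)
        return self

    def parameters(self):
        ps = []
        for layer in self._all_layers():
            ps += layer.parameters()
        return ps

    def gradients(self):
        gs = []
        for layer in self._all_layers():
            gs += layer.gradients()
        return gs

    def zero_grad(self):
        for g in self.gradients():
            g[...] = 0.0

    def count_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward / backward ----------------------------------------------

    def _pad_len(self, L):
        m = 2 ** self.cfg.depth
        return (m - L % m) % m

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Batched forward: x (N, in_channels, L) -> logits (N, n_classes, L)."""
        N, C, L = x.shape
        pad = self._pad_len(L)
        if pad:
            x = np.pad(x, ((0, 0), (0, 0), (0, pad)))
        self._skips = []
        h = self.stem.forward(x.astype(np.float32))
        for a, dn in self.enc:
            h = a.forward(h)
            self._skips.append(h)
            h = dn.forward(h)
        h = self.bottleneck.forward(h)
        for i, (up, proj, a, b) in enumerate(self.dec):
            h = up.forward(h)
            h = proj.forward(h)
            skip = self._skips[-1 - i]
            h = np.concatenate([h, skip], axis=1)
            h = a.forward(h)
            h = b.forward(h)
        logits = self.head.forward(h)
        self._out_pad = pad
        if not self._training:
            self._skips = None
        return logits[:, :, :L] if pad else logits

    def backward(self, dlogits: np.ndarray):
        """Backpropagate d(loss)/d(logits); accumulates parameter grads."""
        if self._out_pad:
            dlogits = np.pad(dlogits, ((0, 0), (0, 0), (0, self._out_pad)))
        d = self.head.backward(dlogits.astype(np.float32))
        dskips = [None] * len(self.dec)
        for i in range(len(self.dec) - 1, -1, -1):
            up, proj, a, b = self.dec[i]
            d = a.backward(b.backward(d))
            c_skip = self._skips[-1 - i].shape[1]
            d, dskip = d[:, :-c_skip, :], d[:, -c_skip:, :]
            dskips[i] = dskip
            d = up.backward(proj.backward(d))
        d = self.bottleneck.backward(d)
        for i in range(len(self.enc) - 1, -1, -1):
            a, dn = self.enc[i]
            d = dn.backward(d)
            d = d + dskips[len(self.enc) - 1 - i]
            d = a.backward(d)
        d = self.stem.backward(d)
        self._skips = None
        return d

    # -- inference --------------------------------------------------------

    def predict_logits(self, signal: np.ndarray) -> np.ndarray:
        """Run one single-channel signal (length L >= min_input_len).

        Returns the L x n_classes logit matrix.
        """
        signal = np.asarray(signal, dtype=np.float32)
        if signal.ndim != 1:
            raise ValueError("predict_logits expects a 1D signal")
        if signal.shape[0] < self.cfg.min_input_len:
            raise ValueError(
                f"input length {signal.shape[0]} is below the minimum "
                f"supported length {self.cfg.min_input_len}")
        was_training = self._training
        self.train(False)
        logits = self.forward(signal[None, None, :])[0].T
        if was_training:
            self.train(True)
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite logits")
        return np.ascontiguousarray(logits)

    # -- accounting -------------------------------------------------------

    def _conv_shapes(self, L):
        """Yield (conv, L_out) for every convolution in one forward pass."""
        pad = self._pad_len(L)
        L = L + pad
        yield self.stem.conv, self.stem.conv.out_len(L)
        lev_len = L
        enc_lens = []
        for a, dn in self.enc:
            yield a.conv, a.conv.out_len(lev_len)
            enc_lens.append(lev_len)
            lev_len = dn.conv.out_len(lev_len)
            yield dn.conv, lev_len
        yield self.bottleneck.conv, lev_len
        for i, (up, proj, a, b) in enumerate(self.dec):
            lev_len = 2 * lev_len
            yield proj.conv, lev_len
            yield a.conv, lev_len
            yield b.conv, lev_len
        yield self.head, lev_len

    def count_flops(self, L: int) -> int:
        """Multiply-accumulate count of one forward pass on a length-L input.

        One MAC is counted as one FLOP; per convolution the cost is
        kernel_size * C_in * C_out * L_out.
        """
        total = 0
        for conv, lo in self._conv_shapes(L):
            total += conv.k * conv.cin * conv.cout * lo
        return int(total)

    def count_flops_windowed(self, total_len: int, window_len: int) -> int:
        """MAC count when the input is processed in fixed-length windows."""
        n_full, rem = divmod(total_len, window_len)
        total = n_full * self.count_flops(window_len)
        if rem:
            total += self.count_flops(window_len)  # final window is padded
        return int(total)

    # -- checkpointing ----------------------------------------------------

    def state_arrays(self):
        arrs = {}
        for i, p in enumerate(self.parameters()):
            arrs[f"param_{i}"] = p
        bn_idx = 0
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm1d):
                arrs[f"bn_{bn_idx}_mean"] = layer.running_mean
                arrs[f"bn_{bn_idx}_var"] = layer.running_var
                bn_idx += 1
        return arrs

    def save(self, path):
        np.savez(path, **self.state_arrays())
        with open(str(path) + ".json", "w") as fh:
            json.dump(dataclasses.asdict(self.cfg), fh, indent=1)

    def load_state(self, path):
        data = np.load(path)
        for i, p in enumerate(self.parameters()):
            p[...] = data[f"param_{i}"]
        bn_idx = 0
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = data[f"bn_{bn_idx}_mean"]
                layer.running_var[...] = data[f"bn_{bn_idx}_var"]
                bn_idx += 1
        return self


def build_unet(cfg: UNetConfig | None = None) -> UNet1d:
    """Construct the segmentation network (default: the 836,387-parameter
    configuration)."""
    return UNet1d(cfg or UNetConfig())


def load_unet(path) -> UNet1d:
    """Load a checkpoint written by :meth:`UNet1d.save`."""
    with open(str(path) + ".json") as fh:
        cfg = UNetConfig(**json.load(fh))
    model = UNet1d(cfg)
    model.load_state(path)
    model.train(False)
    return model
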