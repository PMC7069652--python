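"""A small 1D convolutional network for pixel-spectrum classification.

Six weight layers: three strided 1D convolutions (kernel 7, channels
8/16/32), two fully connected layers (64, 32) and a softmax output over the
four spectral classes. Inputs are standardised per sample (zero mean, unit
variance along the spectrum) before the first convolution, which makes the
classifier invariant to per-spectrum offsets and scalings — background
errors shift and rescale spectra exactly that way, which is why a network
of this form is robust across background-correction conditions.

Training is plain stochastic gradient descent with a fixed learning rate on
the cross-entropy loss, in shuffled mini-batches. Everything is numpy; the
convolutions run as im2col matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralCNN"]


def _im2col(x: np.ndarray, kernel: int, stride: int, pad: int) -> np.ndarray:
    """(B, C, L) -> (B, C, L_out, kernel) sliding windows."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=2)
    return windows[:, :, ::stride, :]


def _col2im(dcols: np.ndarray, length: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter window gradients back to the input."""
    b, c, l_out, kernel = dcols.shape
    dxp = np.zeros((b, c, length + 2 * pad))
    for j in range(kernel):
        dxp[:, :, j : j + stride * l_out : stride] += dcols[:, :, :, j]
    return dxp[:, :, pad : pad + length] if pad else dxp


def _conv_out_len(length: int, kernel: int, stride: int, pad: int) -> int:
    return (length + 2 * pad - kernel) // stride + 1


@dataclass
class _Conv1D:
    w: np.ndarray  # (C_out, C_in, kernel)
    b: np.ndarray
    stride: int
    pad: int
    _cols: np.ndarray | None = field(default=None, repr=False)
    _in_len: int = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cols = _im2col(x, self.w.shape[2], self.stride, self.pad)
        self._in_len = x.shape[2]
        return np.einsum("bclk,ock->bol", self._cols, self.w, optimize=True) + self.b[:, None]

    def backward(self, dout: np.ndarray, lr: float) -> np.ndarray:
        dw = np.einsum("bol,bclk->ock", dout, self._cols, optimize=True)
        db = dout.sum(axis=(0, 2))
        dcols = np.einsum("bol,ock->bclk", dout, self.w, optimize=True)
        dx = _col2im(dcols, self._in_len, self.stride, self.pad)
        n = dout.shape[0]
        self.w -= lr * dw / n
        self.b -= lr * db / n
        return dx


@dataclass
class _Dense:
    w: np.ndarray  # (n_in, n_out)
    b: np.ndarray
    _x: np.ndarray | None = field(default=None, repr=False)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray, lr: float) -> np.ndarray:
        dw = self._x.T @ dout
        db = dout.sum(axis=0)
        dx = dout @ self.w.T
        n = dout.shape[0]
        self.w -= lr * dw / n
        self.b -= lr * db / n
        return dx


class SpectralCNN:
    """3 conv + 2 dense + softmax classifier over 1D spectra."""

    KERNEL = 7
    STRIDE = 2
    PAD = 3
    CONV_CHANNELS = (8, 16, 32)
    DENSE_UNITS = (64, 32)

    def __init__(self, n_channels: int, n_classes: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_channels = n_channels
        self.n_classes = n_classes
        self.convs: list[_Conv1D] = []
        c_in, length = 1, n_channels
        for c_out in self.CONV_CHANNELS:
            fan_in = c_in * self.KERNEL
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, self.KERNEL))
            self.convs.append(_Conv1D(w, np.zeros(c_out), self.STRIDE, self.PAD))
            length = _conv_out_len(length, self.KERNEL, self.STRIDE, self.PAD)
            c_in = c_out
        self.flat_dim = c_in * length
        self.denses: list[_Dense] = []
        n_in = self.flat_dim
        for n_out in (*self.DENSE_UNITS, n_classes):
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
            self.denses.append(_Dense(w, np.zeros(n_out)))
            n_in = n_out
        self._relu_masks: list[np.ndarray] = []
        self._conv_shape: tuple[int, ...] = ()

    @staticmethod
    def _standardize(x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        return (x - mu) / (sd + 1e-8)

    def _forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self._standardize(np.asarray(x, dtype=float))[:, None, :]
        masks = []
        for conv in self.convs:
            h = conv.forward(h)
            mask = h > 0
            h = h * mask
            masks.append(mask)
        self._conv_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        for dense in self.denses[:-1]:
            h = dense.forward(h)
            mask = h > 0
            h = h * mask
            masks.append(mask)
        logits = self.denses[-1].forward(h)
        if train:
            self._relu_masks = masks
        return logits

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss_and_grad_step(self, x: np.ndarray, y: np.ndarray, lr: float) -> float:
        """One SGD step on a mini-batch; returns the mean cross-entropy."""
        logits = self._forward(x, train=True)
        probs = self._softmax(logits)
        n = x.shape[0]
        loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-12))
        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        masks = self._relu_masks
        d = self.denses[-1].backward(dlogits, lr)
        for i, dense in enumerate(reversed(self.denses[:-1])):
            d = d * masks[len(self.convs) + len(self.denses) - 2 - i]
            d = dense.backward(d, lr)
        d = d.reshape(self._conv_shape)
        for i, conv in enumerate(reversed(self.convs)):
            d = d * masks[len(self.convs) - 1 - i]
            d = conv.backward(d, lr)
        return float(loss)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        lr: float = 0.01,
        batch_size: int = 200,
        max_epochs: int = 20,
        seed: int = 0,
        early_stop_accuracy: float = 1.0,
    ) -> list[float]:
        """SGD training; stops early once the epoch training accuracy
        reaches ``early_stop_accuracy``. Returns per-epoch accuracies."""
        rng = np.random.default_rng(seed)
        n = x.shape[0]
        history = []
        for _ in range(max_epochs):
            order = rng.permutation(n)
            correct = 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                self.loss_and_grad_step(x[idx], y[idx], lr)
                correct += int((self.predict(x[idx]) == y[idx]).sum())
            history.append(correct / n)
            if history[-1] >= early_stop_accuracy:
                break
        return history

    def predict(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        out = np.empty(x.shape[0], dtype=np.int64)
        for start in range(0, x.shape[0], batch_size):
            logits = self._forward(x[start : start + batch_size])
            out[start : start + batch_size] = logits.argmax(axis=1)
        return out
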