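"""Encoder/decoder multilayer perceptrons and the reconstruction loss.

The encoder maps standardized predictors X (n x p) to a latent
representation Z (n x d) through fully connected layers with tanh
activations after every layer except the last; the decoder mirrors the
architecture back to p outputs, again with a linear final layer so that
standardized data outside [-1, 1] can be reconstructed.  The default
encoder for the motivating setting (p=76, d=4) has hidden widths 64 and 16.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import numpy as np

from . import _autodiff as ad

__all__ = [
    "MLPSpec", "AutoencoderParams", "encoder_spec", "init_params",
    "encode", "decode", "reconstruction_loss",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class MLPSpec:
    """Widths of the encoder from input to latent; tanh between layers."""

    layer_widths: tuple
    activation: str = "tanh"

    def __post_init__(self):
        if len(self.layer_widths) < 2:
            raise ValueError("layer_widths needs at least input and output width")
        if any(w <= 0 for w in self.layer_widths):
            raise ValueError(f"layer widths must be positive: {self.layer_widths}")
        if self.activation != "tanh":
            raise ValueError(f"unsupported activation {self.activation!r}")

    @property
    def p(self) -> int:
        return self.layer_widths[0]

    @property
    def d(self) -> int:
        return self.layer_widths[-1]

    def decoder_widths(self) -> tuple:
        return tuple(reversed(self.layer_widths))


def encoder_spec(p: int, d: int, hidden=(64, 16)) -> MLPSpec:
    return MLPSpec(layer_widths=(p, *hidden, d))


@dataclass
class AutoencoderParams:
    """Weight matrices (fan_in x fan_out) and bias vectors of both MLPs."""

    spec: MLPSpec
    enc_weights: List[np.ndarray] = field(default_factory=list)
    enc_biases: List[np.ndarray] = field(default_factory=list)
    dec_weights: List[np.ndarray] = field(default_factory=list)
    dec_biases: List[np.ndarray] = field(default_factory=list)

    def flat(self):
        return (list(self.enc_weights) + list(self.enc_biases)
                + list(self.dec_weights) + list(self.dec_biases))


def init_params(spec: MLPSpec, seed: int = 0) -> AutoencoderParams:
    """Uniform fan-in-scaled initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    rng = np.random.default_rng(seed)
    params = AutoencoderParams(spec=spec)
    for widths, w_list, b_list in (
            (spec.layer_widths, params.enc_weights, params.enc_biases),
            (spec.decoder_widths(), params.dec_weights, params.dec_biases)):
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            w_list.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            b_list.append(rng.uniform(-bound, bound, size=fan_out))
    return params


def _mlp_numpy(X: np.ndarray, weights, biases) -> np.ndarray:
    h = X
    last = len(weights) - 1
    for i, (W, b) in enumerate(zip(weights, biases)):
        h = h @ W + b
        if i < last:
            h = np.tanh(h)
    return h


def mlp_tensor(h: "ad.Tensor", weights, biases) -> "ad.Tensor":
    """Tensor-graph forward pass shared by training and gradient checks."""
    last = len(weights) - 1
    for i, (W, b) in enumerate(zip(weights, biases)):
        h = ad.matmul(h, ad.astensor(W)) + b
        if i < last:
            h = ad.tanh(h)
    return h


def encode(X: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.spec.p:
        raise ValueError(
            f"encoder expects p={params.spec.p} columns, got {X.shape[1]}")
    return _mlp_numpy(X, params.enc_weights, params.enc_biases)


def decode(Z: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != params.spec.d:
        raise ValueError(
            f"decoder expects d={params.spec.d} columns, got {Z.shape[1]}")
    return _mlp_numpy(Z, params.dec_weights, params.dec_biases)


def reconstruction_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Mean squared reconstruction error, ||X - X_hat||_F^2 / (n p)."""
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    return float(np.mean((X - X_hat) ** 2))


# ---------------------------------------------------------------------------
# checkpoint serialization (plain JSON: portable and diff-able)


def save_checkpoint(params: AutoencoderParams, path, extra: dict | None = None) -> None:
    payload = {
        "layer_widths": list(params.spec.layer_widths),
        "activation": params.spec.activation,
        "enc_weights": [w.tolist() for w in params.enc_weights],
        "enc_biases": [b.tolist() for b in params.enc_biases],
        "dec_weights": [w.tolist() for w in params.dec_weights],
        "dec_biases": [b.tolist() for b in params.dec_biases],
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path) -> tuple[AutoencoderParams, dict]:
    payload = json.loads(Path(path).read_text())
    spec = MLPSpec(layer_widths=tuple(payload["layer_widths"]),
                   activation=payload["activation"])
    params = AutoencoderParams(
        spec=spec,
        enc_weights=[np.asarray(w) for w in payload["enc_weights"]],
        enc_biases=[np.asarray(b) for b in payload["enc_biases"]],
        dec_weights=[np.asarray(w) for w in payload["dec_weights"]],
        dec_biases=[np.asarray(b) for b in payload["dec_biases"]],
    )
    return params, payload["extra"]
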