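"""Gated recurrent unit cell, stacked sequence encoder/decoder, and the
single-modality deep recurrent auto-encoder (DRA) with greedy layer-wise
pretraining.

The cell follows the update-gate convention in which z gates the *previous*
state:

    z_t = sigma(W_xz' x_t + W_hz' h_{t-1} + b_z)
    r_t = sigma(W_xr' x_t + W_hr' h_{t-1} + b_r)
    g_t = tanh (W_xg' x_t + W_hg'(r_t * h_{t-1}) + b_g)
    h_t = z_t * h_{t-1} + (1 - z_t) * g_t

so h_t is an elementwise convex combination of the old state and the
candidate. Per-layer output activations (ReLU on hidden layers, Sigmoid on
the reconstruction layer) and optional batch normalization are applied to the
hidden sequence a layer emits to its successor; the recurrence itself uses
the raw gate equations above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, BatchNorm, Tensor, concatenate, relu, sigmoid, tanh

__all__ = [
    "GRULayerParams",
    "GRULayer",
    "GRUStack",
    "StackSpec",
    "DRAParams",
    "PretrainConfig",
    "gru_cell_step",
    "run_stack",
    "encode",
    "decode",
    "reconstruct",
    "pretrain_layers",
    "init_gru_layer",
    "build_dra",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Raised when a training loss becomes non-finite."""


@dataclass
class GRULayerParams:
    """Gate weight matrices and biases of one GRU layer.

    Input-to-hidden matrices are (input_dim, units); hidden-to-hidden are
    (units, units); biases are (units,). Stored as autodiff tensors so the
    same arrays serve forward evaluation and training.
    """

    W_xz: Tensor
    W_xr: Tensor
    W_xg: Tensor
    W_hz: Tensor
    W_hr: Tensor
    W_hg: Tensor
    b_z: Tensor
    b_r: Tensor
    b_g: Tensor

    def __post_init__(self):
        d, u = self.W_xz.shape
        ok = (
            self.W_xr.shape == (d, u) and self.W_xg.shape == (d, u)
            and self.W_hz.shape == (u, u) and self.W_hr.shape == (u, u)
            and self.W_hg.shape == (u, u)
            and self.b_z.shape == (u,) and self.b_r.shape == (u,)
            and self.b_g.shape == (u,)
        )
        if not ok:
            raise ValueError("inconsistent GRU parameter shapes")
        for t in self.tensors():
            if not np.isfinite(t.data).all():
                raise ValueError("non-finite GRU parameter")

    @property
    def input_dim(self) -> int:
        return self.W_xz.shape[0]

    @property
    def units(self) -> int:
        return self.W_xz.shape[1]

    def tensors(self) -> list[Tensor]:
        return [self.W_xz, self.W_xr, self.W_xg,
                self.W_hz, self.W_hr, self.W_hg,
                self.b_z, self.b_r, self.b_g]


def init_gru_layer(rng: np.random.Generator, input_dim: int, units: int) -> GRULayerParams:
    """Fan-in-scaled uniform initialization."""
    def mat(d_in, d_out):
        bound = 1.0 / np.sqrt(d_in)
        return Tensor(rng.uniform(-bound, bound, size=(d_in, d_out)), requires_grad=True)

    return GRULayerParams(
        W_xz=mat(input_dim, units), W_xr=mat(input_dim, units), W_xg=mat(input_dim, units),
        W_hz=mat(units, units), W_hr=mat(units, units), W_hg=mat(units, units),
        b_z=Tensor(np.zeros(units), requires_grad=True),
        b_r=Tensor(np.zeros(units), requires_grad=True),
        b_g=Tensor(np.zeros(units), requires_grad=True),
    )


def gru_cell_step(params: GRULayerParams, x_t, h_prev):
    """One GRU step. Returns (h_t, (z_t, r_t, g_t)).

    Accepts plain arrays (vector or (batch, dim)) for functional evaluation,
    or autodiff tensors during training; the arithmetic is identical.
    """
    tape = isinstance(x_t, Tensor) or isinstance(h_prev, Tensor)
    if tape:
        x_t = x_t if isinstance(x_t, Tensor) else Tensor(x_t)
        h_prev = h_prev if isinstance(h_prev, Tensor) else Tensor(h_prev)
        W = params
    else:
        x_t = np.asarray(x_t, dtype=np.float64)
        h_prev = np.asarray(h_prev, dtype=np.float64)

        class W:  # plain-array view of the parameters
            pass

        for name, t in zip(
            ("W_xz", "W_xr", "W_xg", "W_hz", "W_hr", "W_hg", "b_z", "b_r", "b_g"),
            params.tensors(),
        ):
            setattr(W, name, t.data)

    if x_t.shape[-1] != params.input_dim or h_prev.shape[-1] != params.units:
        raise ValueError(
            f"dimension mismatch: x has {x_t.shape[-1]} (expected {params.input_dim}), "
            f"h has {h_prev.shape[-1]} (expected {params.units})"
        )

    z = sigmoid(x_t @ W.W_xz + h_prev @ W.W_hz + W.b_z)
    r = sigmoid(x_t @ W.W_xr + h_prev @ W.W_hr + W.b_r)
    g = tanh(x_t @ W.W_xg + (r * h_prev) @ W.W_hg + W.b_g)
    h = z * h_prev + (1 - z) * g
    return h, (z, r, g)


_ACTIVATIONS = {"linear": lambda x: x, "relu": relu, "sigmoid": sigmoid, "tanh": tanh}


@dataclass
class GRULayer:
    """One stack layer: GRU params + output activation + optional batch norm."""

    params: GRULayerParams
    activation: str = "relu"
    batch_norm: BatchNorm | None = None

    def __post_init__(self):
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    def trainable(self) -> list[Tensor]:
        out = self.params.tensors()
        if self.batch_norm is not None:
            out = out + self.batch_norm.params
        return out


@dataclass
class GRUStack:
    """Ordered GRU layers; layer k consumes layer k-1's full output sequence."""

    layers: list[GRULayer] = field(default_factory=list)

    def __post_init__(self):
        for prev, cur in zip(self.layers, self.layers[1:]):
            if cur.params.input_dim != prev.params.units:
                raise ValueError("layer input dim must equal previous layer units")

    def trainable(self) -> list[Tensor]:
        return [t for layer in self.layers for t in layer.trainable()]


@dataclass(frozen=True)
class StackSpec:
    """Architecture of one stack half (units, activations, batch-norm flags)."""

    units: tuple[int, ...]
    activations: tuple[str, ...]
    batch_norm: tuple[bool, ...]

    def build(self, input_dim: int, rng: np.random.Generator) -> GRUStack:
        layers = []
        d = input_dim
        for u, act, bn in zip(self.units, self.activations, self.batch_norm):
            layers.append(GRULayer(
                params=init_gru_layer(rng, d, u),
                activation=act,
                batch_norm=BatchNorm(u) if bn else None,
            ))
            d = u
        return GRUStack(layers)


def default_encoder_spec(input_dim: int) -> StackSpec:
    """Three GRU layers (input_dim -> 20 -> 16), ReLU, batch norm after 2 and 3."""
    return StackSpec(units=(input_dim, 20, 16),
                     activations=("relu", "relu", "relu"),
                     batch_norm=(False, True, True))


def default_decoder_spec(output_dim: int) -> StackSpec:
    """Mirror image (16 -> 20 -> output_dim), Sigmoid output, batch norm after 5 and 6."""
    return StackSpec(units=(16, 20, output_dim),
                     activations=("relu", "relu", "sigmoid"),
                     batch_norm=(True, True, False))


def _layer_forward(layer: GRULayer, X, training: bool, tape: bool):
    """Run one layer over a (batch, T, dim) block; returns (batch, T, units)."""
    batch, T, _ = X.shape
    if tape:
        h = Tensor(np.zeros((batch, layer.params.units)))
        outs = []
        for t in range(T):
            h, _ = gru_cell_step(layer.params, X[:, t, :], h)
            outs.append(h.reshape(batch, 1, layer.params.units))
        seq = concatenate(outs, axis=1)
        seq = _ACTIVATIONS[layer.activation](seq)
        if layer.batch_norm is not None:
            flat = seq.reshape(batch * T, layer.params.units)
            flat = layer.batch_norm(flat, training=training)
            seq = flat.reshape(batch, T, layer.params.units)
        return seq
    h = np.zeros((batch, layer.params.units))
    seq = np.empty((batch, T, layer.params.units))
    for t in range(T):
        h, _ = gru_cell_step(layer.params, X[:, t, :], h)
        seq[:, t, :] = h
    seq = _ACTIVATIONS[layer.activation](seq)
    if layer.batch_norm is not None:
        flat = layer.batch_norm(seq.reshape(batch * T, -1), training=False)
        seq = flat.reshape(batch, T, -1)
    return seq


def run_stack(stack: GRUStack, X, training: bool = False, tape: bool = False):
    """Run a stack over input sequences.

    X may be (T, dim) for a single sequence or (batch, T, dim). Returns
    (per-layer output sequences, per-layer final hidden states), shaped like
    the input (batch axis dropped if it was absent).
    """
    single = (X.ndim == 2) if not isinstance(X, Tensor) else (X.data.ndim == 2)
    if single:
        X = X.reshape(1, *X.shape)
    if (X.shape[1] if not isinstance(X, Tensor) else X.data.shape[1]) < 1:
        raise ValueError("empty sequence")
    seqs, finals = [], []
    cur = X if isinstance(X, Tensor) else np.asarray(X, dtype=np.float64)
    for layer in stack.layers:
        cur = _layer_forward(layer, cur, training=training, tape=tape)
        seqs.append(cur)
        finals.append(cur[:, -1, :])
    if single and not tape:
        seqs = [s[0] for s in seqs]
        finals = [f[0] for f in finals]
    return seqs, finals


@dataclass
class DRAParams:
    """Single-modality deep recurrent auto-encoder.

    The encoder's final hidden state is projected by a linear map to the
    coupling-layer width (`code_dim`, default 10); the decoder receives the
    code repeated at every time step and reconstructs the input sequence.
    """

    encoder: GRUStack
    decoder: GRUStack
    proj_W: Tensor
    proj_b: Tensor

    def __post_init__(self):
        enc_out = self.encoder.layers[-1].params.units
        if self.proj_W.shape != (enc_out, self.code_dim):
            raise ValueError("projection shape inconsistent with encoder output")
        if self.decoder.layers[0].params.input_dim != self.code_dim:
            raise ValueError("decoder input dim must equal code_dim")

    @property
    def code_dim(self) -> int:
        return self.proj_W.shape[1]

    @property
    def input_dim(self) -> int:
        return self.encoder.layers[0].params.input_dim

    def trainable(self) -> list[Tensor]:
        return (self.encoder.trainable() + self.decoder.trainable()
                + [self.proj_W, self.proj_b])


def build_dra(input_dim: int, rng: np.random.Generator, code_dim: int = 10,
              encoder_spec: StackSpec | None = None,
              decoder_spec: StackSpec | None = None) -> DRAParams:
    encoder_spec = encoder_spec or default_encoder_spec(input_dim)
    decoder_spec = decoder_spec or default_decoder_spec(input_dim)
    enc = encoder_spec.build(input_dim, rng)
    dec = decoder_spec.build(code_dim, rng)
    enc_out = enc.layers[-1].params.units
    bound = 1.0 / np.sqrt(enc_out)
    proj_W = Tensor(rng.uniform(-bound, bound, size=(enc_out, code_dim)), requires_grad=True)
    proj_b = Tensor(np.zeros(code_dim), requires_grad=True)
    return DRAParams(enc, dec, proj_W, proj_b)


def encode(dra: DRAParams, X, training: bool = False, tape: bool = False):
    """Code vector(s): final encoder hidden state through the linear coupling
    projection. X is (T, dim) or (batch, T, dim)."""
    _, finals = run_stack(dra.encoder, X, training=training, tape=tape)
    h_last = finals[-1]
    if tape:
        return h_last @ dra.proj_W + dra.proj_b
    return h_last @ dra.proj_W.data + dra.proj_b.data


def decode(dra: DRAParams, code, T: int, training: bool = False, tape: bool = False):
    """Reconstruction from a code: the code is repeated as a T-step input
    sequence to the decoder stack."""
    if T <= 0:
        raise ValueError("T must be positive")
    if tape:
        code2 = code if isinstance(code, Tensor) else Tensor(code)
        if code2.data.ndim == 1:
            code2 = code2.reshape(1, -1)
        batch, cd = code2.shape
        rep = concatenate([code2.reshape(batch, 1, cd)] * T, axis=1)
        seqs, _ = run_stack(dra.decoder, rep, training=training, tape=True)
        return seqs[-1]
    code = np.asarray(code, dtype=np.float64)
    single = code.ndim == 1
    if single:
        code = code.reshape(1, -1)
    rep = np.repeat(code[:, None, :], T, axis=1)
    seqs, _ = run_stack(dra.decoder, rep, training=training)
    out = seqs[-1]
    return out[0] if single and out.ndim == 3 else out


def reconstruct(dra: DRAParams, X, training: bool = False, tape: bool = False):
    T = X.shape[-2] if not isinstance(X, Tensor) else X.data.shape[-2]
    code = encode(dra, X, training=training, tape=tape)
    return decode(dra, code, T, training=training, tape=tape)


@dataclass(frozen=True)
class PretrainConfig:
    """Greedy layer-wise pretraining settings."""

    steps: int = 60
    batch_size: int = 32
    lr: float = 0.001
    seed: int = 0


def pretrain_layers(features: np.ndarray, spec: StackSpec,
                    config: PretrainConfig) -> tuple[GRUStack, list[list[float]]]:
    """Greedy layer-wise pretraining of an encoder stack.

    Each layer is trained as a shallow recurrent auto-encoder: the GRU layer
    maps its input sequence to a hidden sequence, and a throwaway per-timestep
    affine readout reconstructs the input; the squared-error loss trains both.
    Layer k's training input is the frozen hidden sequence of layer k-1.

    Returns the stack and the per-layer loss traces.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 3 or features.shape[0] < 1:
        raise ValueError("features must be (n_epochs, T, dim) with n_epochs >= 1")
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_batch = (np.random.default_rng(s) for s in ss.spawn(2))

    n, T, _ = features.shape
    cur = features
    layers: list[GRULayer] = []
    traces: list[list[float]] = []
    for li, (u, act, bn) in enumerate(
        zip(spec.units, spec.activations, spec.batch_norm), start=1
    ):
        d = cur.shape[2]
        layer = GRULayer(params=init_gru_layer(rng_init, d, u),
                         activation=act, batch_norm=BatchNorm(u) if bn else None)
        readout_W = Tensor(rng_init.uniform(-1, 1, size=(u, d)) / np.sqrt(u),
                           requires_grad=True)
        readout_b = Tensor(np.zeros(d), requires_grad=True)
        opt = Adam(layer.trainable() + [readout_W, readout_b], lr=config.lr)
        trace: list[float] = []
        for step in range(config.steps):
            idx = rng_batch.choice(n, size=min(config.batch_size, n), replace=False)
            xb = Tensor(cur[idx])
            hidden = _layer_forward(layer, xb, training=True, tape=True)
            recon = hidden @ readout_W + readout_b
            loss = ((recon - xb) ** 2).mean()
            if not np.isfinite(loss.item()):
                raise DivergenceError(f"pretraining diverged at layer {li}")
            trace.append(loss.item())
            opt.zero_grad()
            loss.backward()
            opt.step()
        traces.append(trace)
        # frozen forward pass feeds the next layer
        cur = _layer_forward(layer, cur, training=False, tape=False)
        layers.append(layer)
    return GRUStack(layers), traces
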