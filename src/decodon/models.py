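"""Neural decoders mapping codons to 21-class distributions.

Five families share one forward/backward contract:

* ``MLP-LINEAR`` — fully connected perceptron on one-hot input (64- or
  12-bit), no activation anywhere except the final softmax; the end-to-end
  pre-softmax map is affine, so deciphering reduces to a single 21 x 64
  matrix.
* ``MLP-EMBED`` — a learnable 64 x d codon embedding feeding hidden layers
  with ReLU or tanh activations.
* ``RNN`` / ``GRU`` / ``LSTM`` — stacked recurrent cells (2 by default) that
  read a codon as three 4-bit nucleotide timesteps and emit a single 21-class
  output after the third step.  Hidden (and cell) state is re-initialised for
  every codon: codons are translated independently, so no memory crosses a
  codon boundary.

Everything is plain NumPy with hand-written gradients; backward passes are
validated against finite differences in the test suite.  Recurrent
state-transition matrices are initialised orthogonally (semi-orthogonal when
non-square) to keep gradients well-conditioned over the 3-step unroll.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .encoding import (
    NUC4_TABLE,
    EmbeddingSpec,
    EncodingScheme,
    encode_batch,
)
from .genetic_code import AA_INDEX, CODONS, standard_code

FAMILIES = ("MLP-LINEAR", "MLP-EMBED", "RNN", "GRU", "LSTM")
RECURRENT_FAMILIES = ("RNN", "GRU", "LSTM")


class ModelConfigError(ValueError):
    """The model specification is internally inconsistent."""


@dataclass
class ModelSpec:
    """Declarative description of a decoder.

    ``input_scheme`` applies to MLP-LINEAR (OHE64 or OHE12); recurrent
    families always read NUC4-SEQ3; MLP-EMBED takes ``embedding_dim``
    instead.  ``activation`` is forced to ``none`` for MLP-LINEAR and to
    ``tanh`` (by cell construction) for recurrent families.
    """

    family: str
    hidden_sizes: List[int] = field(default_factory=lambda: [64])
    input_scheme: Optional[str] = None
    embedding_dim: Optional[int] = None
    activation: str = "none"
    stacked_cells: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ModelConfigError(f"unknown family {self.family!r}")
        if any(h < 1 for h in self.hidden_sizes):
            raise ModelConfigError("hidden sizes must be positive")
        if self.family == "MLP-LINEAR":
            if self.activation not in ("none",):
                raise ModelConfigError("MLP-LINEAR is fully linear (activation none)")
            if self.embedding_dim is not None:
                raise ModelConfigError("MLP-LINEAR does not take an embedding")
            if self.input_scheme is None:
                self.input_scheme = "OHE64"
            if self.input_scheme not in ("OHE64", "OHE12"):
                raise ModelConfigError(
                    f"MLP-LINEAR needs OHE64 or OHE12 input, got {self.input_scheme!r}"
                )
        elif self.family == "MLP-EMBED":
            if self.embedding_dim is None:
                raise ModelConfigError("MLP-EMBED requires embedding_dim")
            if self.input_scheme is not None:
                raise ModelConfigError(
                    "MLP-EMBED consumes codon indices through its embedding; "
                    "fixed one-hot input_scheme is inconsistent"
                )
            if self.activation not in ("relu", "tanh", "none"):
                raise ModelConfigError(f"unknown activation {self.activation!r}")
        else:  # recurrent
            if self.input_scheme not in (None, "NUC4-SEQ3"):
                raise ModelConfigError(
                    f"{self.family} reads NUC4-SEQ3 timesteps, got {self.input_scheme!r}"
                )
            self.input_scheme = "NUC4-SEQ3"
            self.activation = "tanh"
            if self.stacked_cells < 1:
                raise ModelConfigError("stacked_cells must be >= 1")
            if len(set(self.hidden_sizes)) != 1:
                # hidden_sizes gives the (uniform) cell width, replicated per cell
                raise ModelConfigError(
                    "recurrent families use one hidden width for all stacked cells"
                )


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    """(Semi-)orthogonal matrix: orthonormal rows or columns, whichever fits."""
    big = max(rows, cols)
    a = rng.standard_normal((big, min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))  # fix sign ambiguity for determinism
    out = q[:rows, :cols] if rows >= cols else q[:cols, :rows].T
    return np.ascontiguousarray(out)


def _dense_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.standard_normal((fan_in, fan_out)) / np.sqrt(fan_in)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shift-invariant for numerical stability."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


_ACTS = {
    "none": (lambda x: x, lambda x, y: np.ones_like(y)),
    "relu": (lambda x: np.maximum(x, 0.0), lambda x, y: (x > 0).astype(float)),
    "tanh": (np.tanh, lambda x, y: 1.0 - y * y),
}


class Model:
    """Shared surface: parameter list, forward to logits, manual backward."""

    spec: ModelSpec
    params: Dict[str, np.ndarray]

    def param_items(self) -> List[Tuple[str, np.ndarray]]:
        return sorted(self.params.items())

    def prepare(self, codon_idx: np.ndarray) -> np.ndarray:
        """Map canonical codon indices to this model's input tensor."""
        raise NotImplementedError

    def forward_logits(self, inputs: np.ndarray, cache: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dlogits: np.ndarray) -> Dict[str, np.ndarray]:
        """Gradients w.r.t. every parameter given d(loss)/d(logits)."""
        raise NotImplementedError

    def predict_proba(self, codon_idx: np.ndarray) -> np.ndarray:
        return softmax(self.forward_logits(self.prepare(np.asarray(codon_idx))))


class LinearMLP(Model):
    """Fully linear perceptron: chained affine maps, softmax at the end."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.scheme = EncodingScheme(spec.input_scheme)
        rng = np.random.default_rng(spec.seed)
        dims = [self.scheme.width] + list(spec.hidden_sizes) + [21]
        self.params = {}
        for i in range(len(dims) - 1):
            self.params[f"W{i}"] = _dense_init(rng, dims[i], dims[i + 1])
            self.params[f"b{i}"] = np.zeros(dims[i + 1])
        self.n_layers = len(dims) - 1
        self._cache: Optional[List[np.ndarray]] = None

    def prepare(self, codon_idx: np.ndarray) -> np.ndarray:
        return encode_batch(codon_idx, self.scheme)

    def forward_logits(self, inputs: np.ndarray, cache: bool = False) -> np.ndarray:
        a = np.atleast_2d(np.asarray(inputs, dtype=float))
        acts = [a]
        for i in range(self.n_layers):
            a = a @ self.params[f"W{i}"] + self.params[f"b{i}"]
            acts.append(a)
        if cache:
            self._cache = acts
        return a

    def backward(self, dlogits: np.ndarray) -> Dict[str, np.ndarray]:
        acts = self._cache
        grads = {}
        d = dlogits
        for i in reversed(range(self.n_layers)):
            grads[f"W{i}"] = acts[i].T @ d
            grads[f"b{i}"] = d.sum(axis=0)
            if i > 0:
                d = d @ self.params[f"W{i}"].T
        return grads

    def collapse(self) -> Tuple[np.ndarray, np.ndarray]:
        """Collapse the affine chain into one input->21 map (A, b).

        ``logits == X @ A + b`` exactly; with OHE64 input, ``A.T`` is the
        21 x 64 deciphering matrix the trained network implements.
        """
        A = np.eye(self.scheme.width)
        b = np.zeros(self.scheme.width)
        for i in range(self.n_layers):
            W, bi = self.params[f"W{i}"], self.params[f"b{i}"]
            b = b @ W + bi
            A = A @ W
        return A, b


class EmbeddingMLP(Model):
    """Codon-index input -> learnable embedding -> activated hidden layers."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        d = spec.embedding_dim
        self.embedding = EmbeddingSpec(d=d, seed=spec.seed)
        self.params = {"E": self.embedding.matrix}
        dims = [d] + list(spec.hidden_sizes) + [21]
        for i in range(len(dims) - 1):
            self.params[f"W{i}"] = _dense_init(rng, dims[i], dims[i + 1])
            self.params[f"b{i}"] = np.zeros(dims[i + 1])
        self.n_layers = len(dims) - 1
        self.act, self.dact = _ACTS[spec.activation]
        self._cache = None

    def prepare(self, codon_idx: np.ndarray) -> np.ndarray:
        return np.asarray(codon_idx)

    def forward_logits(self, inputs: np.ndarray, cache: bool = False) -> np.ndarray:
        idx = np.atleast_1d(np.asarray(inputs, dtype=int))
        a = self.params["E"][idx]
        pres, acts = [], [a]
        for i in range(self.n_layers):
            z = a @ self.params[f"W{i}"] + self.params[f"b{i}"]
            pres.append(z)
            a = z if i == self.n_layers - 1 else self.act(z)
            acts.append(a)
        if cache:
            self._cache = (idx, pres, acts)
        return a

    def backward(self, dlogits: np.ndarray) -> Dict[str, np.ndarray]:
        idx, pres, acts = self._cache
        grads = {}
        d = dlogits
        for i in reversed(range(self.n_layers)):
            grads[f"W{i}"] = acts[i].T @ d
            grads[f"b{i}"] = d.sum(axis=0)
            d = d @ self.params[f"W{i}"].T
            if i > 0:
                d = d * self.dact(pres[i - 1], acts[i])
        dE = np.zeros_like(self.params["E"])
        np.add.at(dE, idx, d)
        grads["E"] = dE
        return grads


class _RecurrentModel(Model):
    """Common scaffolding for the 3-timestep recurrent readers."""

    GATES: int  # pre-activation blocks per cell (1 for RNN, 3 GRU, 4 LSTM)

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.hidden = spec.hidden_sizes[0]
        self.layers = spec.stacked_cells
        rng = np.random.default_rng(spec.seed)
        self.params = {}
        h = self.hidden
        for l in range(self.layers):
            fan_in = 4 if l == 0 else h
            for g in range(self.GATES):
                self.params[f"Wx{l}_{g}"] = _orthogonal(rng, fan_in, h)
                self.params[f"Wh{l}_{g}"] = _orthogonal(rng, h, h)
                self.params[f"bx{l}_{g}"] = np.zeros(h)
                self.params[f"bh{l}_{g}"] = np.zeros(h)
        self.params["Wo"] = _dense_init(rng, h, 21)
        self.params["bo"] = np.zeros(21)
        self._cache = None

    def prepare(self, codon_idx: np.ndarray) -> np.ndarray:
        return NUC4_TABLE[np.asarray(codon_idx)]

    def forward_logits(self, inputs: np.ndarray, cache: bool = False) -> np.ndarray:
        x = np.asarray(inputs, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != 3 or x.shape[2] != 4:
            raise ValueError(
                f"recurrent input must be (batch, 3, 4) nucleotide timesteps, got {x.shape}"
            )
        B = x.shape[0]
        states = self._init_states(B)
        caches = []
        for t in range(3):
            inp = x[:, t]
            step_cache = []
            for l in range(self.layers):
                out, states[l], c = self._cell_forward(l, inp, states[l])
                step_cache.append(c)
                inp = out
            caches.append(step_cache)
        logits = inp @ self.params["Wo"] + self.params["bo"]
        if cache:
            self._cache = (x, caches, inp)
        return logits

    def backward(self, dlogits: np.ndarray) -> Dict[str, np.ndarray]:
        x, caches, h_last = self._cache
        B = x.shape[0]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["Wo"] = h_last.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dstate = [self._zero_state_grad(B) for _ in range(self.layers)]
        for t in reversed(range(3)):
            d_above = dlogits @ self.params["Wo"].T if t == 2 else np.zeros(
                (B, self.hidden)
            )
            for l in reversed(range(self.layers)):
                dx, dstate[l] = self._cell_backward(
                    l, caches[t][l], d_above, dstate[l], grads
                )
                d_above = dx
        return grads

    # state plumbing -------------------------------------------------------
    def _init_states(self, B: int):
        raise NotImplementedError

    def _zero_state_grad(self, B: int):
        raise NotImplementedError

    def _cell_forward(self, l, x, state):
        """Return (output h, new state, cache)."""
        raise NotImplementedError

    def _cell_backward(self, l, cache, dh_out, dstate, grads):
        """Return (dx, dstate_prev); accumulate parameter grads in place."""
        raise NotImplementedError

    def _lin(self, l, g, x, h):
        return (
            x @ self.params[f"Wx{l}_{g}"]
            + self.params[f"bx{l}_{g}"]
            + h @ self.params[f"Wh{l}_{g}"]
            + self.params[f"bh{l}_{g}"]
        )

    def _lin_back(self, l, g, x, h, dpre, grads):
        grads[f"Wx{l}_{g}"] += x.T @ dpre
        grads[f"Wh{l}_{g}"] += h.T @ dpre
        grads[f"bx{l}_{g}"] += dpre.sum(axis=0)
        grads[f"bh{l}_{g}"] += dpre.sum(axis=0)
        return dpre @ self.params[f"Wx{l}_{g}"].T, dpre @ self.params[f"Wh{l}_{g}"].T


class ElmanRNN(_RecurrentModel):
    """Stacked Elman cells: h_t = tanh(Wx x_t + Wh h_{t-1} + b)."""

    GATES = 1

    def _init_states(self, B):
        return [np.zeros((B, self.hidden)) for _ in range(self.layers)]

    def _zero_state_grad(self, B):
        return np.zeros((B, self.hidden))

    def _cell_forward(self, l, x, h_prev):
        h = np.tanh(self._lin(l, 0, x, h_prev))
        return h, h, (x, h_prev, h)

    def _cell_backward(self, l, cache, dh_out, dh_next, grads):
        x, h_prev, h = cache
        dh = dh_out + dh_next
        dpre = dh * (1.0 - h * h)
        dx, dh_prev = self._lin_back(l, 0, x, h_prev, dpre, grads)
        return dx, dh_prev


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class GRUModel(_RecurrentModel):
    """Stacked gated recurrent units (reset/update gates, candidate state)."""

    GATES = 3  # 0: reset r, 1: update z, 2: candidate n

    def _init_states(self, B):
        return [np.zeros((B, self.hidden)) for _ in range(self.layers)]

    def _zero_state_grad(self, B):
        return np.zeros((B, self.hidden))

    def _cell_forward(self, l, x, h_prev):
        r = _sigmoid(self._lin(l, 0, x, h_prev))
        z = _sigmoid(self._lin(l, 1, x, h_prev))
        m = h_prev @ self.params[f"Wh{l}_2"] + self.params[f"bh{l}_2"]
        n = np.tanh(x @ self.params[f"Wx{l}_2"] + self.params[f"bx{l}_2"] + r * m)
        h = (1.0 - z) * n + z * h_prev
        return h, h, (x, h_prev, r, z, m, n)

    def _cell_backward(self, l, cache, dh_out, dh_next, grads):
        x, h_prev, r, z, m, n = cache
        dh = dh_out + dh_next
        dz = dh * (h_prev - n)
        dn = dh * (1.0 - z)
        dh_prev = dh * z
        dn_pre = dn * (1.0 - n * n)
        # candidate block: n = tanh(x Wx2 + bx2 + r * (h_prev Wh2 + bh2))
        grads[f"Wx{l}_2"] += x.T @ dn_pre
        grads[f"bx{l}_2"] += dn_pre.sum(axis=0)
        dx = dn_pre @ self.params[f"Wx{l}_2"].T
        dr = dn_pre * m
        dm = dn_pre * r
        grads[f"Wh{l}_2"] += h_prev.T @ dm
        grads[f"bh{l}_2"] += dm.sum(axis=0)
        dh_prev += dm @ self.params[f"Wh{l}_2"].T
        for g, dgate, gate in ((0, dr, r), (1, dz, z)):
            dpre = dgate * gate * (1.0 - gate)
            dxg, dhg = self._lin_back(l, g, x, h_prev, dpre, grads)
            dx += dxg
            dh_prev += dhg
        return dx, dh_prev


class LSTMModel(_RecurrentModel):
    """Stacked LSTM cells with input/forget/candidate/output gates."""

    GATES = 4  # 0: input i, 1: forget f, 2: candidate g, 3: output o

    def _init_states(self, B):
        return [
            (np.zeros((B, self.hidden)), np.zeros((B, self.hidden)))
            for _ in range(self.layers)
        ]

    def _zero_state_grad(self, B):
        return (np.zeros((B, self.hidden)), np.zeros((B, self.hidden)))

    def _cell_forward(self, l, x, state):
        h_prev, c_prev = state
        i = _sigmoid(self._lin(l, 0, x, h_prev))
        f = _sigmoid(self._lin(l, 1, x, h_prev))
        g = np.tanh(self._lin(l, 2, x, h_prev))
        o = _sigmoid(self._lin(l, 3, x, h_prev))
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        return h, (h, c), (x, h_prev, c_prev, i, f, g, o, tc)

    def _cell_backward(self, l, cache, dh_out, dstate, grads):
        x, h_prev, c_prev, i, f, g, o, tc = cache
        dh_next, dc_next = dstate
        dh = dh_out + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_prev = dc * f
        dx = np.zeros_like(x)
        dh_prev = np.zeros_like(h_prev)
        for gi, dgate, gate in ((0, di, i), (1, df, f), (3, do, o)):
            dpre = dgate * gate * (1.0 - gate)
            dxg, dhg = self._lin_back(l, gi, x, h_prev, dpre, grads)
            dx += dxg
            dh_prev += dhg
        dg_pre = dg * (1.0 - g * g)
        dxg, dhg = self._lin_back(l, 2, x, h_prev, dg_pre, grads)
        dx += dxg
        dh_prev += dhg
        return dx, (dh_prev, dc_prev)


_FAMILY_CLASSES = {
    "MLP-LINEAR": LinearMLP,
    "MLP-EMBED": EmbeddingMLP,
    "RNN": ElmanRNN,
    "GRU": GRUModel,
    "LSTM": LSTMModel,
}


def build_model(spec: ModelSpec) -> Model:
    """Construct a decoder with deterministic, seed-driven initialisation."""
    return _FAMILY_CLASSES[spec.family](spec)


def forward(model: Model, inputs: np.ndarray) -> np.ndarray:
    """Run a prepared input batch through the model to simplex rows."""
    return softmax(model.forward_logits(inputs))


def recurrent_read(model: Model, timesteps: np.ndarray) -> np.ndarray:
    """Read one codon (or a batch) as exactly 3 nucleotide timesteps.

    Hidden state starts from zero, and only the distribution emitted after
    the third timestep is exposed.
    """
    if not isinstance(model, _RecurrentModel):
        raise ModelConfigError("recurrent_read requires an RNN/GRU/LSTM model")
    x = np.asarray(timesteps, dtype=float)
    single = x.ndim == 2
    probs = softmax(model.forward_logits(x))
    return probs[0] if single else probs


def oracle_model() -> LinearMLP:
    """A hand-built linear decoder that implements the standard code exactly.

    One affine 64->21 layer with logit +20 on each codon's reference class
    and -20 elsewhere; its argmax table is the genetic code with near-1
    probabilities.  Used as a fixed point for evaluation logic.
    """
    spec = ModelSpec(family="MLP-LINEAR", hidden_sizes=[], input_scheme="OHE64")
    model = LinearMLP(spec)
    code = standard_code()
    W = np.full((64, 21), -20.0)
    for ci, codon in enumerate(CODONS):
        W[ci, AA_INDEX[code[codon]]] = 20.0
    model.params["W0"] = W
    model.params["b0"] = np.zeros(21)
    return model


def save_model(model: Model, path: str | Path) -> None:
    """Checkpoint spec + weights to a single ``.npz`` archive."""
    meta = json.dumps(asdict(model.spec))
    np.savez(path, __spec__=np.array(meta), **model.params)


def load_model(path: str | Path) -> Model:
    with np.load(path, allow_pickle=False) as data:
        spec = ModelSpec(**json.loads(str(data["__spec__"])))
        model = build_model(spec)
        for k in model.params:
            model.params[k] = data[k]
    if isinstance(model, EmbeddingMLP):
        model.embedding.matrix = model.params["E"]
    return model
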