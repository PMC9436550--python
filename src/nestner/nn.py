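"""Neural building blocks on top of the autodiff engine.

Contains the generic layers the recogniser is assembled from: embedding
tables, linear maps, dropout, a character CNN with max-over-time pooling, a
stacked bidirectional LSTM with state-holding masks for padded batches, and
the Adam optimiser.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def xavier_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int | None = None, fan_out: int | None = None) -> np.ndarray:
    fan_in = fan_in if fan_in is not None else shape[0]
    fan_out = fan_out if fan_out is not None else shape[-1]
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Minimal parameter container with recursive traversal."""

    training: bool = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(xavier_uniform(rng, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, n_items: int, dim: int, rng: np.random.Generator,
                 init: np.ndarray | None = None):
        table = init if init is not None else rng.uniform(-0.1, 0.1, size=(n_items, dim))
        self.table = Tensor(table, requires_grad=True)

    def __call__(self, index: np.ndarray) -> Tensor:
        return ad.embedding(self.table, index)


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode or at p=0."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        if not self.training or self.p == 0.0 or rng is None:
            return x
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class CharCNN(Module):
    """Character-level word encoder: 1-D convolutions of several widths over
    character embeddings, max-pooled over positions and concatenated.

    Words shorter than a filter width are padded so every width yields at
    least one window; windows that would extend past a word's real characters
    are masked out of the max, making each word's vector independent of the
    batch it appears in.
    """

    def __init__(self, n_chars: int, char_dim: int, widths: tuple[int, ...],
                 n_filters: int, rng: np.random.Generator):
        self.widths = tuple(widths)
        self.n_filters = n_filters
        self.emb = Embedding(n_chars, char_dim, rng)
        self.filters = [Linear(w * char_dim, n_filters, rng) for w in self.widths]

    @property
    def out_dim(self) -> int:
        return self.n_filters * len(self.widths)

    def __call__(self, char_ids: np.ndarray, word_lens: np.ndarray) -> Tensor:
        """char_ids: (B, T, Lc) padded char indices; word_lens: (B, T)."""
        B, T, Lc = char_ids.shape
        flat_ids = char_ids.reshape(B * T, Lc)
        flat_lens = word_lens.reshape(B * T)
        x = self.emb(flat_ids)  # (BT, Lc, dc)
        pooled = []
        for w, lin in zip(self.widths, self.filters):
            P = Lc - w + 1
            windows = ad.concat(
                [ad.reshape(x[:, k:k + w, :], (B * T, 1, w * self.emb.table.shape[1]))
                 for k in range(P)], axis=1)  # (BT, P, w*dc)
            scores = ad.relu(lin(windows))  # (BT, P, F)
            eff = np.maximum(flat_lens, w)  # short words use their padding
            valid = np.arange(P)[None, :] <= (eff - w)[:, None]
            mask = np.where(valid, 0.0, -1e9)[:, :, None]
            pooled.append(ad.tmax(scores + Tensor(mask), axis=1))
        return ad.reshape(ad.concat(pooled, axis=-1), (B, T, self.out_dim))


class LSTMDirection(Module):
    """One direction of an LSTM layer, unrolled over time with update masks
    so padded positions hold their state (forget-gate bias initialised to 1)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.Wx = Tensor(xavier_uniform(rng, (n_in, 4 * hidden), fan_in=n_in,
                                        fan_out=hidden), requires_grad=True)
        self.Wh = Tensor(xavier_uniform(rng, (hidden, 4 * hidden), fan_in=hidden,
                                        fan_out=hidden), requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget gate
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, token_mask: np.ndarray, reverse: bool) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outputs: list[Tensor | None] = [None] * T
        steps = range(T - 1, -1, -1) if reverse else range(T)
        for t in steps:
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = ad.sigmoid(z[:, 0 * H:1 * H])
            f = ad.sigmoid(z[:, 1 * H:2 * H])
            g = ad.tanh(z[:, 2 * H:3 * H])
            o = ad.sigmoid(z[:, 3 * H:4 * H])
            c_new = f * c + i * g
            h_new = o * ad.tanh(c_new)
            m = Tensor(token_mask[:, t:t + 1].astype(float))
            c = m * c_new + (1.0 - m) * c
            h = m * h_new + (1.0 - m) * h
            outputs[t] = h
        return ad.stack(outputs, axis=1)  # (B, T, H)


class BiLSTM(Module):
    """Stack of bidirectional LSTM layers; `size` is the total output width
    (half per direction).  Dropout is applied between layers only."""

    def __init__(self, n_in: int, size: int, n_layers: int, dropout: float,
                 rng: np.random.Generator):
        if size % 2:
            raise ValueError("BiLSTM size must be even (split across directions)")
        self.size = size
        half = size // 2
        self.forward_layers = []
        self.backward_layers = []
        d = n_in
        for _ in range(n_layers):
            self.forward_layers.append(LSTMDirection(d, half, rng))
            self.backward_layers.append(LSTMDirection(d, half, rng))
            d = size
        self.dropout = Dropout(dropout)

    def __call__(self, x: Tensor, token_mask: np.ndarray,
                 rng: np.random.Generator | None = None) -> Tensor:
        out = x
        n = len(self.forward_layers)
        for layer, (fwd, bwd) in enumerate(zip(self.forward_layers, self.backward_layers)):
            hf = fwd(out, token_mask, reverse=False)
            hb = bwd(out, token_mask, reverse=True)
            out = ad.concat([hf, hb], axis=-1)
            if layer < n - 1:
                out = self.dropout(out, rng)
        return out


class Adam:
    """Adam with bias correction; operates on a fixed parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
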