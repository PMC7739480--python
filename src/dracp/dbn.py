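"""Deep belief network encoder: stacked restricted Boltzmann machines.

An RBM over m visible and n hidden binary units has energy

    E(v, h) = -a'v - b'h - v'Wh

joint distribution p(v,h) = exp(-E)/Z, and factorised sigmoid conditionals
p(h_j=1|v) = sigmoid(b_j + sum_i v_i W_ij) (and symmetrically for v|h).
Each RBM is trained by contrastive divergence (CD-k, default k=1); the stack
is trained greedily layer by layer, feeding each layer's hidden activation
probabilities to the next as data.  At encode time the stack is used purely
as a deterministic feed-forward recognition network (no sampling), so
encodings are reproducible and bounded in (0, 1).

Feature vectors here are frequencies in [0, 1] and are fed as soft Bernoulli
probabilities rather than binarised.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit as sigmoid

#: Above this many total units, exact enumeration (2^(m+n) states) is refused.
ENUMERATION_LIMIT = 20


@dataclass
class RBMParams:
    """Weights and biases of one RBM: W is m x n, a visible bias, b hidden."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray
    recon_errors: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.shape != (self.a.size, self.b.size):
            raise ValueError(
                f"shape mismatch: W {self.W.shape}, a {self.a.shape}, b {self.b.shape}"
            )
        if not (
            np.isfinite(self.W).all()
            and np.isfinite(self.a).all()
            and np.isfinite(self.b).all()
        ):
            raise ValueError("RBM parameters must be finite")

    @property
    def m(self) -> int:
        return self.a.size

    @property
    def n(self) -> int:
        return self.b.size


def init_rbm(m: int, n: int, seed: int, scale: float = 0.01) -> RBMParams:
    """Small-Gaussian weight init, zero biases; deterministic given seed."""
    rng = np.random.default_rng(seed)
    return RBMParams(W=scale * rng.standard_normal((m, n)), a=np.zeros(m), b=np.zeros(n))


def rbm_energy(params: RBMParams, v: np.ndarray, h: np.ndarray) -> float:
    """E(v, h) = -a'v - b'h - v'Wh for one (v, h) configuration."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (params.m,) or h.shape != (params.n,):
        raise ValueError(
            f"state shapes {v.shape}/{h.shape} do not match RBM ({params.m},{params.n})"
        )
    return float(-params.a @ v - params.b @ h - v @ params.W @ h)


def _all_states(k: int) -> np.ndarray:
    return np.array(list(itertools.product((0.0, 1.0), repeat=k)))


def rbm_partition_function(params: RBMParams) -> float:
    """Z by exhaustive enumeration; refuses when m + n > ENUMERATION_LIMIT."""
    if params.m + params.n > ENUMERATION_LIMIT:
        raise ValueError(
            f"partition function is intractable for m+n={params.m + params.n} > "
            f"{ENUMERATION_LIMIT}; use rbm_hidden_probs/rbm_visible_probs instead"
        )
    # Z = sum_v exp(-F(v)) via the free energy, 2^m terms instead of 2^(m+n)
    V = _all_states(params.m)
    return float(np.exp(-rbm_free_energy(params, V)).sum())


def rbm_joint_probability(params: RBMParams, v: np.ndarray, h: np.ndarray) -> float:
    """Exact p(v, h) = exp(-E(v,h)) / Z for small RBMs."""
    Z = rbm_partition_function(params)
    return float(np.exp(-rbm_energy(params, v, h)) / Z)


def rbm_free_energy(params: RBMParams, V: np.ndarray) -> np.ndarray:
    """F(v) = -a'v - sum_j log(1 + exp(b_j + (v'W)_j)), rowwise."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    act = params.b + V @ params.W
    return -(V @ params.a) - np.logaddexp(0.0, act).sum(axis=1)


def rbm_log_likelihood(params: RBMParams, V: np.ndarray) -> float:
    """Exact mean log p(v) over rows of V (enumeration-bounded)."""
    logZ = np.log(rbm_partition_function(params))
    return float(np.mean(-rbm_free_energy(params, V) - logZ))


def rbm_hidden_probs(params: RBMParams, V: np.ndarray) -> np.ndarray:
    """p(h_j = 1 | v) = sigmoid(b_j + sum_i v_i W_ij), rowwise over V."""
    V = np.asarray(V, dtype=float)
    if V.shape[-1] != params.m:
        raise ValueError(f"visible dimension {V.shape[-1]} != {params.m}")
    return sigmoid(params.b + V @ params.W)


def rbm_visible_probs(params: RBMParams, H: np.ndarray) -> np.ndarray:
    """p(v_i = 1 | h) = sigmoid(a_i + sum_j W_ij h_j), rowwise over H."""
    H = np.asarray(H, dtype=float)
    if H.shape[-1] != params.n:
        raise ValueError(f"hidden dimension {H.shape[-1]} != {params.n}")
    return sigmoid(params.a + H @ params.W.T)


def train_rbm(
    data: np.ndarray,
    n_hidden: int,
    epochs: int = 200,
    learning_rate: float = 0.5,
    cd_steps: int = 1,
    batch_size: int = 10,
    seed: int = 0,
    init: RBMParams | None = None,
) -> RBMParams:
    """Train one RBM by contrastive divergence (CD-k).

    Data rows are samples with entries in [0, 1], used directly as soft
    visible probabilities.  One Gibbs chain per sample: hidden states are
    sampled, the visible reconstruction uses probabilities.  Per-epoch mean
    squared reconstruction error is recorded on the returned params.
    Deterministic given ``seed``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if data.min() < 0 or data.max() > 1:
        raise ValueError("data entries must lie in [0, 1]")
    n_samples, m = data.shape
    rng = np.random.default_rng(seed)
    params = init if init is not None else init_rbm(m, n_hidden, seed)
    if params.m != m or params.n != n_hidden:
        raise ValueError("init params shape does not match data / n_hidden")
    W, a, b = params.W.copy(), params.a.copy(), params.b.copy()

    recon_errors: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n_samples)
        sq_err = 0.0
        for start in range(0, n_samples, batch_size):
            V0 = data[order[start : start + batch_size]]
            ph0 = sigmoid(b + V0 @ W)
            Hk = (rng.random(ph0.shape) < ph0).astype(float)
            for step in range(cd_steps):
                Vk = sigmoid(a + Hk @ W.T)
                phk = sigmoid(b + Vk @ W)
                if step < cd_steps - 1:
                    Hk = (rng.random(phk.shape) < phk).astype(float)
            nb = V0.shape[0]
            lr = learning_rate / nb
            W += lr * (V0.T @ ph0 - Vk.T @ phk)
            a += lr * (V0 - Vk).sum(axis=0)
            b += lr * (ph0 - phk).sum(axis=0)
            sq_err += float(((V0 - Vk) ** 2).sum())
        recon_errors.append(sq_err / (n_samples * m))
    return RBMParams(W=W, a=a, b=b, recon_errors=recon_errors)


@dataclass
class DBNModel:
    """A greedily trained RBM stack used as a feed-forward encoder."""

    layers: list[RBMParams]
    layer_sizes: list[int]
    training_meta: dict

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("DBN needs at least one RBM layer")
        sizes = [self.layers[0].m] + [l.n for l in self.layers]
        if sizes != list(self.layer_sizes):
            raise ValueError(
                f"layer_sizes {self.layer_sizes} inconsistent with RBM shapes {sizes}"
            )
        for lower, upper in zip(self.layers[:-1], self.layers[1:]):
            if lower.n != upper.m:
                raise ValueError("adjacent RBMs do not chain: hidden != next visible")

    @property
    def n_input(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_encoded(self) -> int:
        return self.layer_sizes[-1]

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "layers": [
                {"W": l.W.tolist(), "a": l.a.tolist(), "b": l.b.tolist()}
                for l in self.layers
            ],
            "training_meta": dict(self.training_meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DBNModel":
        layers = [
            RBMParams(W=np.array(l["W"]), a=np.array(l["a"]), b=np.array(l["b"]))
            for l in d["layers"]
        ]
        return cls(layers=layers, layer_sizes=list(d["layer_sizes"]),
                   training_meta=dict(d.get("training_meta", {})))


def train_dbn(
    data: np.ndarray,
    layer_sizes: Sequence[int],
    epochs: int = 200,
    learning_rate: float = 0.5,
    cd_steps: int = 1,
    batch_size: int = 10,
    seed: int = 0,
) -> DBNModel:
    """Greedy layer-wise DBN pretraining.

    Trains the first RBM on the data, replaces the data by its hidden
    activation probabilities, and repeats for each subsequent layer.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    layer_sizes = list(layer_sizes)
    if len(layer_sizes) < 2:
        raise ValueError("layer_sizes needs at least [n_visible, n_hidden]")
    if layer_sizes[0] != data.shape[1]:
        raise ValueError(
            f"layer_sizes[0]={layer_sizes[0]} != data columns {data.shape[1]}"
        )
    layers: list[RBMParams] = []
    current = data
    for depth, (m, n) in enumerate(zip(layer_sizes[:-1], layer_sizes[1:])):
        rbm = train_rbm(
            current,
            n_hidden=n,
            epochs=epochs,
            learning_rate=learning_rate,
            cd_steps=cd_steps,
            batch_size=batch_size,
            seed=seed + depth,
        )
        layers.append(rbm)
        current = rbm_hidden_probs(rbm, current)
    meta = {
        "epochs": epochs,
        "learning_rate": learning_rate,
        "cd_steps": cd_steps,
        "batch_size": batch_size,
        "seed": seed,
    }
    return DBNModel(layers=layers, layer_sizes=layer_sizes, training_meta=meta)


def encode(model: DBNModel, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass of activation probabilities through the stack."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_input:
        raise ValueError(
            f"input has {X.shape[1]} columns; DBN expects {model.n_input}"
        )
    for layer in model.layers:
        X = rbm_hidden_probs(layer, X)
    return X
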