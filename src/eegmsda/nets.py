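"""Shared-extractor / per-source-subnet / per-source-head backbone.

The model has three stages.  A shared extractor f maps every domain's feature
vector into a common space (domain-invariant features).  N unshared subnets
F_n, one per source domain, map the common features into N specific spaces
(domain-specific features, written x~^n).  N heads O_n turn specific features
into class-probability rows, so classifier n is G_n = O_n o F_n o f.

All stages are fully connected.  The spectral feature vectors the model
consumes are already a fixed grid of band log-powers per channel, and dense
layers over that grid train quickly and keep the gradient flow of the
multi-head objective easy to audit; ``input_layout`` records the
(channels, points-per-channel) geometry of the vector for validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = ["ModelConfig", "ModelState", "common_features", "specific_features", "classify"]


@dataclass(frozen=True)
class ModelConfig:
    """Backbone hyperparameters.

    ``input_layout`` is (channels, points_per_channel); their product must be
    the feature-vector length (e.g. (61, 27) for 1647 band-power features).
    """

    n_sources: int
    n_classes: int = 2
    input_layout: tuple = (61, 27)
    hidden_dim: int = 128
    common_dim: int = 64
    specific_dim: int = 64
    dropout: float = 0.0

    def __post_init__(self):
        if self.n_sources < 2:
            raise ValueError("need at least 2 source domains")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.input_layout) != 2 or min(self.input_layout) < 1:
            raise ValueError("input_layout must be (channels, points_per_channel)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def input_dim(self) -> int:
        return int(self.input_layout[0] * self.input_layout[1])


def _he(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


@dataclass
class ModelState:
    """Parameters of the shared extractor, the N subnets and the N heads."""

    config: ModelConfig
    params: dict = field(default_factory=dict)
    step: int = 0
    seed: int = 0
    # per-feature standardization fitted on the source domains
    norm_mean: np.ndarray | None = None
    norm_std: np.ndarray | None = None

    @classmethod
    def initialize(cls, config: ModelConfig, seed: int = 0) -> "ModelState":
        rng = np.random.default_rng(seed)
        d, h, cdim, sdim = config.input_dim, config.hidden_dim, config.common_dim, config.specific_dim
        p: dict[str, Tensor] = {
            "common.W1": Tensor(_he(rng, d, h), requires_grad=True),
            "common.b1": Tensor(np.zeros(h), requires_grad=True),
            "common.W2": Tensor(_he(rng, h, cdim), requires_grad=True),
            "common.b2": Tensor(np.zeros(cdim), requires_grad=True),
        }
        for n in range(config.n_sources):
            p[f"sub{n}.W"] = Tensor(_he(rng, cdim, sdim), requires_grad=True)
            p[f"sub{n}.b"] = Tensor(np.zeros(sdim), requires_grad=True)
            # small random head init: supervised gradient reaches the lower
            # layers from the first step (an exactly-zero head blocks it)
            p[f"head{n}.W"] = Tensor(
                rng.normal(0.0, 0.01, size=(sdim, config.n_classes)), requires_grad=True
            )
            p[f"head{n}.b"] = Tensor(np.zeros(config.n_classes), requires_grad=True)
        return cls(config=config, params=p, seed=seed)

    # ---- forward passes (Tensor in, Tensor out) -------------------------

    def _check_input(self, x: Tensor) -> None:
        if x.shape[-1] != self.config.input_dim:
            raise ValueError(
                f"feature length {x.shape[-1]} != layout product {self.config.input_dim}"
            )

    def common(self, x, rng: np.random.Generator | None = None) -> Tensor:
        """Shared extractor f; pass a Generator to enable training dropout."""
        x = as_tensor(x)
        self._check_input(x)
        if self.norm_mean is not None:
            x = (x - Tensor(self.norm_mean)) * Tensor(1.0 / self.norm_std)
        p = self.params
        h = (x @ p["common.W1"] + p["common.b1"]).relu()
        if rng is not None and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            mask = rng.random(h.shape) < keep
            h = h * Tensor(mask / keep)
        return (h @ p["common.W2"] + p["common.b2"]).relu()

    def specific(self, common, n: int) -> Tensor:
        """Subnet F_n applied to common features."""
        self._check_source(n)
        p = self.params
        return (as_tensor(common) @ p[f"sub{n}.W"] + p[f"sub{n}.b"]).relu()

    def head(self, specific, n: int) -> Tensor:
        """Head O_n: affine layer + softmax rows."""
        self._check_source(n)
        p = self.params
        logits = as_tensor(specific) @ p[f"head{n}.W"] + p[f"head{n}.b"]
        shift = Tensor(logits.data.max(axis=1, keepdims=True))  # detached max, stability
        e = (logits - shift).exp()
        return e / e.sum(axis=1, keepdims=True)

    def _check_source(self, n: int) -> None:
        if not 0 <= n < self.config.n_sources:
            raise IndexError(f"source index {n} out of range [0, {self.config.n_sources})")

    def parameters(self) -> list:
        return list(self.params.values())

    # ---- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: npz arrays + embedded JSON config."""
        arrays = {k: v.data for k, v in self.params.items()}
        if self.norm_mean is not None:
            arrays["__norm_mean__"] = self.norm_mean
            arrays["__norm_std__"] = self.norm_std
        cfg = asdict(self.config)
        cfg["input_layout"] = list(cfg["input_layout"])
        header = {"config": cfg, "step": self.step, "seed": self.seed}
        arrays["__meta__"] = np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8
        ).copy()
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> "ModelState":
        with np.load(path) as z:
            header = json.loads(bytes(z["__meta__"]).decode())
            cfg = header["config"]
            cfg["input_layout"] = tuple(cfg["input_layout"])
            config = ModelConfig(**cfg)
            state = cls(config=config, step=header["step"], seed=header["seed"])
            special = {"__meta__", "__norm_mean__", "__norm_std__"}
            state.params = {
                k: Tensor(z[k], requires_grad=True) for k in z.files if k not in special
            }
            if "__norm_mean__" in z.files:
                state.norm_mean = z["__norm_mean__"]
                state.norm_std = z["__norm_std__"]
        return state


# ---- inference-mode conveniences (numpy in, numpy out) -------------------


def common_features(x: np.ndarray, state: ModelState) -> np.ndarray:
    """Domain-invariant features of a batch (inference mode, no dropout)."""
    return state.common(np.asarray(x)).data


def specific_features(common: np.ndarray, n: int, state: ModelState) -> np.ndarray:
    """Domain-specific features x~^n of a batch of common features."""
    return state.specific(np.asarray(common), n).data


def classify(specific: np.ndarray, n: int, state: ModelState) -> np.ndarray:
    """Class-probability rows from head n; each row sums to 1."""
    return state.head(np.asarray(specific), n).data
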