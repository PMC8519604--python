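"""Training objective, optimization loop, ensemble prediction and evaluation.

The total objective combines three terms:

    L_total = L_c + mu * L_local + gamma * L_global

where L_c sums each source domain's mean cross-entropy, L_local is the
label-conditional MMD aligning every (source, target) pair per class, and
L_global is the similarity-weighted discrepancy between the per-source
classifiers on target samples.  One subject is one source domain; the target
subject contributes only unlabeled samples, of which a configurable fraction
(the auxiliary ratio) participates in the alignment terms.

Prediction integrates the N classifier outputs with agreement-proportional
weights derived from the pairwise discrepancy table; evaluation reports
confusion-matrix metrics with the fatigue class (label 1) as positive.  The
leave-one-subject-out harness runs the full cycle once per held-out subject.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, confusion_matrix, precision_recall_fscore_support

from .autodiff import Adam, Tensor, as_tensor
from .discrepancy import discrepancy_table, global_loss
from .local_mmd import KernelSpec, llmmd, median_heuristic_sigmas
from .nets import ModelConfig, ModelState

__all__ = [
    "TrainConfig",
    "LossBundle",
    "MetricsRow",
    "supervised_loss",
    "total_loss",
    "train",
    "predict",
    "evaluate",
    "loso_experiment",
]

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow common deep-UDA practice."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_iterations: int = 500
    mu: float = 0.5
    gamma: float = 0.5
    aux_ratio: float = 1.0
    seed: int = 0
    kernel: KernelSpec | None = None  # None -> per-batch median heuristic
    llmmd_mode: str = "weighted"
    ramp: bool = True        # ramp (mu, gamma) 0 -> target while the pseudo-labels warm up
    ramp_frac: float = 0.25  # fraction of iterations the ramp spans
    uniform_ensemble: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 <= self.aux_ratio <= 1:
            raise ValueError("aux_ratio must be in [0, 1]")
        if self.batch_size < 1 or self.max_iterations < 0:
            raise ValueError("counts must be positive")


@dataclass
class LossBundle:
    """Loss terms at one iteration, with the trade-offs in effect."""

    L_c: float
    L_local: float
    L_global: float
    L_total: float
    iteration: int
    mu: float
    gamma: float


@dataclass
class MetricsRow:
    """Confusion-matrix metrics (percent) for one evaluated subject."""

    subject_id: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _onehot(labels, n_classes: int) -> np.ndarray:
    y = np.asarray(labels)
    if y.ndim == 2:  # already one-hot
        return y.astype(np.float64)
    return np.eye(n_classes)[y.astype(int)]


def supervised_loss(predictions: list, labels: list):
    """Sum over domains of the mean cross-entropy -sum_c y log p."""
    if len(predictions) != len(labels):
        raise ValueError("one label set per prediction set required")
    plain = not any(isinstance(p, Tensor) for p in predictions)
    total = None
    for p, y in zip(predictions, labels):
        pt = as_tensor(p)
        yt = np.asarray(y, dtype=np.float64)
        if pt.shape != yt.shape:
            raise ValueError("prediction/label shape mismatch")
        ce = -(Tensor(yt) * pt.clip_min(_PROB_FLOOR).log()).sum(axis=1).mean()
        total = ce if total is None else total + ce
    return total.item() if plain else total


def total_loss(L_c, L_local, L_global, mu: float, gamma: float):
    """The affine combination L_c + mu L_local + gamma L_global."""
    return L_c + mu * L_local + gamma * L_global


def _domain_arrays(d, n_classes: int):
    """Accept FeatureMatrix or DomainBatch; return (features, one-hot labels)."""
    x = np.asarray(d.features, dtype=np.float64)
    y = getattr(d, "labels", None)
    return x, None if y is None else _onehot(y, n_classes)


def train(
    sources: list,
    target_unlabeled,
    config: TrainConfig = TrainConfig(),
    model_config: ModelConfig | None = None,
):
    """Optimize the full objective; returns ``(ModelState, history)``.

    ``sources`` are labeled per-domain datasets (FeatureMatrix/DomainBatch);
    ``target_unlabeled`` contributes features only — any labels it carries
    are never read.
    """
    N = len(sources)
    if N < 2:
        raise ValueError("need at least 2 source domains")
    if model_config is None:
        dim = np.asarray(sources[0].features).shape[1]
        model_config = ModelConfig(n_sources=N, input_layout=(1, dim))
    if model_config.n_sources != N:
        model_config = dataclasses.replace(model_config, n_sources=N)
    C = model_config.n_classes

    xs, ys = zip(*(_domain_arrays(s, C) for s in sources))
    if any(y is None for y in ys):
        raise ValueError("all source domains must be labeled")
    xt = np.asarray(target_unlabeled.features, dtype=np.float64)
    dims = {x.shape[1] for x in xs} | {xt.shape[1]}
    if len(dims) != 1:
        raise ValueError("inconsistent feature dimensions across domains")

    # independent streams so the batch schedule is invariant to whether the
    # auxiliary pool or dropout consume random numbers
    ss = np.random.SeedSequence(config.seed)
    rng, rng_aux, rng_drop = (np.random.default_rng(s) for s in ss.spawn(3))
    state = ModelState.initialize(model_config, seed=config.seed)
    # standardize per feature on the pooled sources; the target reuses the
    # source statistics (its own are off-limits only in the sense that no
    # labels exist — using unlabeled target rows would also be legitimate,
    # but source-only statistics keep the target fully held out)
    pooled = np.concatenate(xs, axis=0)
    state.norm_mean = pooled.mean(axis=0)
    state.norm_std = np.maximum(pooled.std(axis=0), 1e-8)
    opt = Adam(state.parameters(), lr=config.learning_rate)

    n_aux = int(round(config.aux_ratio * len(xt)))
    aux_pool = rng_aux.choice(len(xt), size=n_aux, replace=False) if n_aux else np.array([], int)
    b = config.batch_size
    history: list[LossBundle] = []

    for it in range(1, config.max_iterations + 1):
        if config.ramp and config.ramp_frac > 0:
            f = min(1.0, it / (config.ramp_frac * config.max_iterations))
        else:
            f = 1.0
        mu_t, gamma_t = config.mu * f, config.gamma * f
        align = len(aux_pool) > 0 and (mu_t > 0 or gamma_t > 0)

        batches, ybatch = [], []
        for x, y in zip(xs, ys):
            idx = rng.choice(len(x), b, replace=len(x) < b)
            batches.append(x[idx])
            ybatch.append(y[idx])
        tb = (
            xt[aux_pool[rng_aux.choice(len(aux_pool), b, replace=len(aux_pool) < b)]]
            if align
            else np.empty((0, xt.shape[1]))
        )

        stacked = np.concatenate(batches + ([tb] if len(tb) else []), axis=0)
        common = state.common(Tensor(stacked), rng_drop if model_config.dropout > 0 else None)
        bounds = np.cumsum([0] + [len(p) for p in batches])
        common_src = [common[int(bounds[n]) : int(bounds[n + 1])] for n in range(N)]
        common_t = common[int(bounds[-1]) :] if len(tb) else None

        spec_src, probs_src, spec_t, probs_t = [], [], [], []
        for n in range(N):
            s = state.specific(common_src[n], n)
            spec_src.append(s)
            probs_src.append(state.head(s, n))
            if common_t is not None:
                st = state.specific(common_t, n)
                spec_t.append(st)
                probs_t.append(state.head(st, n))

        L_c = supervised_loss(probs_src, ybatch)

        if align and mu_t > 0:
            per_dom = None
            for n in range(N):
                kspec = config.kernel or median_heuristic_sigmas(
                    spec_src[n].data, spec_t[n].data
                )
                res = llmmd(
                    [spec_src[n]], [ybatch[n]], [spec_t[n]], [probs_t[n]],
                    spec=kspec, mode=config.llmmd_mode,
                )
                per_dom = res.total if per_dom is None else per_dom + res.total
            L_local = per_dom * (1.0 / N)
        else:
            L_local = Tensor(0.0)

        if align and gamma_t > 0 and N >= 2:
            L_global = global_loss(probs_t)
        else:
            L_global = Tensor(0.0)

        L_tot = L_c + mu_t * L_local + gamma_t * L_global
        opt.zero_grad()
        L_tot.backward()
        opt.step()
        state.step = it
        history.append(
            LossBundle(
                L_c=L_c.item(), L_local=L_local.item(), L_global=L_global.item(),
                L_total=L_tot.item(), iteration=it, mu=mu_t, gamma=gamma_t,
            )
        )
    return state, history


def predict(state: ModelState, target_feats: np.ndarray, uniform: bool = False):
    """Weighted-ensemble prediction on target features.

    Returns ``(labels, probs_list, ensemble_probs)``.  Classifier n's weight
    is proportional to sum_{m != n} (1 - omega_mn) — classifiers whose row of
    similarity weights signals agreement with the others count more; pass
    ``uniform=True`` for a plain average.  Argmax ties break toward the lower
    class index.
    """
    if state.step == 0:
        raise RuntimeError("model is untrained; call train() first")
    x = np.asarray(target_feats, dtype=np.float64)
    common = state.common(x).data
    N = state.config.n_sources
    probs = [state.head(state.specific(common, n), n).data for n in range(N)]
    if uniform or N < 2:
        w = np.full(N, 1.0 / N)
    else:
        omega = discrepancy_table(probs).omega
        raw = np.array([(1.0 - omega[n]).sum() - 1.0 for n in range(N)])  # skip diagonal
        w = raw / raw.sum() if raw.sum() > 0 else np.full(N, 1.0 / N)
    ensemble = sum(wn * p for wn, p in zip(w, probs))
    return np.argmax(ensemble, axis=1), probs, ensemble


def evaluate(predictions, truth, subject_id: str = "") -> MetricsRow:
    """Confusion-matrix metrics in percent, fatigue (label 1) positive."""
    y_pred = np.asarray(predictions)
    y_true = np.asarray(truth)
    if len(y_pred) == 0 or len(y_pred) != len(y_true):
        raise ValueError("predictions and truth must be equal-length and non-empty")
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    acc = accuracy_score(y_true, y_pred)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="binary", pos_label=1, zero_division=0
    )
    return MetricsRow(
        subject_id=subject_id,
        accuracy=100 * acc, precision=100 * prec, recall=100 * rec, f1=100 * f1,
        tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn),
    )


def loso_experiment(
    subject_features: list,
    config: TrainConfig = TrainConfig(),
    model_config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Leave-one-subject-out: each subject in turn is the unlabeled target.

    ``subject_features`` is a list of labeled FeatureMatrix, one per subject.
    Returns a DataFrame with one MetricsRow per subject plus an 'Avg' row.
    """
    S = len(subject_features)
    if S < 3:
        raise ValueError("leave-one-subject-out needs at least 3 subjects")
    from .features import FeatureMatrix  # local import avoids a cycle

    rows = []
    for i, held in enumerate(subject_features):
        sources = [fm for j, fm in enumerate(subject_features) if j != i]
        target = FeatureMatrix(held.features, None, subject_id=held.subject_id)
        fold_cfg = dataclasses.replace(config, seed=config.seed + i)
        state, _ = train(sources, target, fold_cfg, model_config)
        labels, _, _ = predict(state, target.features, uniform=config.uniform_ensemble)
        row = evaluate(labels, held.labels, subject_id=held.subject_id or f"N{i + 1}")
        rows.append(row.to_dict())
    df = pd.DataFrame(rows)
    avg = df.drop(columns="subject_id").mean(numeric_only=True)
    avg["subject_id"] = "Avg"
    return pd.concat([df, avg.to_frame().T], ignore_index=True)[df.columns]
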