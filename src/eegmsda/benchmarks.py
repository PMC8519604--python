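"""Reproducible desk-scale benchmark experiments.

Two frozen experiment definitions exercise the full method end to end on
synthetic data:

* the **blob adaptation benchmark** — five shifted source domains plus an
  unlabeled target, comparing the full objective against the supervised-only
  ablation (mu = gamma = 0) over a few seeds;
* the **synthetic LOSO benchmark** — a 15-subject cohort run through feature
  extraction and leave-one-subject-out evaluation.

Both return everything needed to report accuracies and loss trajectories.
The conditions (shift magnitude, sizes, iteration budget) are fixed here so
every consumer measures the same experiment.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .features import extract_features, FeatureMatrix
from .nets import ModelConfig
from .simulate import BlobSpec, CohortSpec, make_blob_domains, simulate_cohort
from .training import TrainConfig, evaluate, loso_experiment, predict, train

__all__ = [
    "BLOB_BENCHMARK_SPEC",
    "BLOB_MODEL_CONFIG",
    "LOSO_MODEL_CONFIG",
    "blob_adaptation_benchmark",
    "cohort_feature_matrices",
    "synthetic_loso_benchmark",
]

#: Five source domains + target, translation-dominant moderate shift.
BLOB_BENCHMARK_SPEC = BlobSpec(
    n_domains=6, n_classes=2, n_per_class=100, dim=10,
    class_separation=3.0, domain_shift_scale=1.5,
)

BLOB_MODEL_CONFIG = ModelConfig(
    n_sources=5, input_layout=(1, 10), hidden_dim=32, common_dim=16, specific_dim=16
)

LOSO_MODEL_CONFIG = ModelConfig(
    n_sources=14, input_layout=(61, 27), hidden_dim=64, common_dim=64, specific_dim=64
)


def blob_adaptation_benchmark(
    seeds=(0, 1, 2), iterations: int = 500, batch_size: int = 32, tradeoff: float = 0.5
) -> dict:
    """Full objective vs supervised-only ablation on shifted blob domains.

    Returns a dict with per-seed target accuracies for both variants, their
    means, and for the full variant the first-iteration and smoothed
    (window 50) final total loss.
    """
    out = {
        "adapted": [], "ablation": [],
        "first_loss": [], "smoothed_final_loss": [],
    }
    for seed in seeds:
        spec = dataclasses.replace(BLOB_BENCHMARK_SPEC, seed=int(seed))
        domains, y_true = make_blob_domains(spec)
        for key, mu in (("ablation", 0.0), ("adapted", tradeoff)):
            cfg = TrainConfig(
                max_iterations=iterations, batch_size=batch_size,
                seed=int(seed), mu=mu, gamma=mu,
            )
            state, hist = train(domains[:-1], domains[-1], cfg, BLOB_MODEL_CONFIG)
            labels, _, _ = predict(state, domains[-1].features)
            out[key].append(evaluate(labels, y_true).accuracy)
            if key == "adapted":
                tail = [h.L_total for h in hist[-50:]]
                out["first_loss"].append(hist[0].L_total)
                out["smoothed_final_loss"].append(float(np.mean(tail)))
    out["adapted_mean"] = float(np.mean(out["adapted"]))
    out["ablation_mean"] = float(np.mean(out["ablation"]))
    return out


def cohort_feature_matrices(spec: CohortSpec) -> list[FeatureMatrix]:
    """Simulate a cohort and run the full feature pipeline per subject."""
    subjects, _ = simulate_cohort(spec)
    return [
        extract_features(
            {0: s["awake"], 1: s["fatigue"]}, subject_id=s["subject_id"]
        )
        for s in subjects
    ]


def synthetic_loso_benchmark(
    seed: int = 0,
    segments_per_class: int = 120,
    iterations: int = 500,
    batch_size: int = 16,
):
    """Leave-one-subject-out on a 15-subject synthetic cohort.

    The per-subject segment count and batch size are reduced relative to the
    full cohort geometry; the cross-subject structure (15 subjects, 61
    channels, both classes) is kept.  Returns ``(metrics table, config,
    feature matrices)`` so individual folds can be reproduced.
    """
    spec = CohortSpec(segments_per_class=segments_per_class, seed=int(seed))
    mats = cohort_feature_matrices(spec)
    cfg = TrainConfig(max_iterations=iterations, batch_size=batch_size, seed=int(seed))
    table = loso_experiment(mats, cfg, LOSO_MODEL_CONFIG)
    return table, cfg, mats
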