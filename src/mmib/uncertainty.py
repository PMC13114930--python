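"""Entropy-based uncertainty: selective prediction and OOD detection.

The per-sample predictive entropy H(q(.|z)) ranks predictions by model
uncertainty.  Selective prediction retains the lowest-entropy fraction
(the coverage) and defers the rest; the comparison baseline retains a
uniformly random subset of the same size.  Out-of-distribution detection
trains with one class held out and compares mean predictive entropy on
in-distribution test samples against the held-out population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import MultimodalDataset
from .infocore import predictive_entropy

DEFAULT_COVERAGES = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3)


@dataclass
class DeferralCurve:
    coverages: list[float]
    accuracy_retained: list[float]
    accuracy_random: list[float]
    entropy_threshold: list[float]


def deferral_curve(
    pred_probs: np.ndarray,
    labels: np.ndarray,
    coverages=DEFAULT_COVERAGES,
    seed: int = 0,
    n_random_draws: int = 100,
) -> DeferralCurve:
    """Accuracy on retained predictions as high-entropy cases are deferred.

    At coverage c the ceil(c*n) lowest-entropy samples are retained (ties
    broken by stable input order); the random baseline averages accuracy
    over uniform subsets of the same size.
    """
    p = np.asarray(pred_probs, dtype=float)
    y = np.asarray(labels)
    coverages = sorted(coverages, reverse=True)
    if not coverages or coverages[0] > 1.0 or coverages[-1] <= 0.0:
        raise ValueError("coverages must lie in (0, 1]")
    n = p.shape[0]
    if n == 0:
        raise ValueError("empty prediction set")
    h = predictive_entropy(p)
    order = np.argsort(h, kind="stable")
    correct = (p.argmax(axis=1) == y).astype(float)
    rng = np.random.default_rng(seed)
    acc_ret, acc_rand, thresholds = [], [], []
    for c in coverages:
        m = int(np.ceil(c * n))
        keep = order[:m]
        acc_ret.append(float(correct[keep].mean()))
        thresholds.append(float(h[order[m - 1]]))
        draws = [
            correct[rng.choice(n, size=m, replace=False)].mean()
            for _ in range(n_random_draws)
        ]
        acc_rand.append(float(np.mean(draws)))
    return DeferralCurve(list(coverages), acc_ret, acc_rand, thresholds)


@dataclass
class OODReport:
    mean_entropy_id: float
    mean_entropy_ood: float
    ratio: float
    thresholds: list[float]
    detection_rate_ood: list[float]
    false_alarm_rate_id: list[float]


def ood_entropy_protocol(
    model_factory,
    data: MultimodalDataset,
    held_out_class: int,
    threshold_grid: list[float] | None = None,
    seed: int = 0,
) -> OODReport:
    """Held-out-class OOD protocol.

    The model is trained with ``held_out_class`` removed (remaining classes
    re-indexed); mean predictive entropy is compared between in-distribution
    test samples and the held-out population, plus a sweep of simple
    entropy-threshold detection rates.
    """
    y = data.labels
    if held_out_class not in np.unique(y):
        raise ValueError(f"class {held_out_class} not present")
    if np.unique(y).size < 2:
        raise ValueError("held-out class is the only class")
    id_mask = y != held_out_class
    remap = {c: i for i, c in enumerate(sorted(np.unique(y[id_mask])))}
    id_data = data.take(np.flatnonzero(id_mask))
    id_data = MultimodalDataset(
        id_data.modalities,
        np.array([remap[c] for c in id_data.labels]),
        id_data.split,
        dict(id_data.metadata),
    )
    if id_data.split is None:
        id_data = id_data.with_split(0.3, seed=seed)
    model = model_factory(id_data, seed)
    _, id_test = id_data.train_test()
    ood_data = data.take(np.flatnonzero(~id_mask))
    h_id = predictive_entropy(model.predict_proba(id_test))
    h_ood = predictive_entropy(model.predict_proba(ood_data))
    mean_id, mean_ood = float(h_id.mean()), float(h_ood.mean())
    if threshold_grid is None:
        threshold_grid = list(np.quantile(h_id, [0.5, 0.75, 0.9, 0.95]))
    det = [float((h_ood > t).mean()) for t in threshold_grid]
    fa = [float((h_id > t).mean()) for t in threshold_grid]
    return OODReport(
        mean_entropy_id=mean_id,
        mean_entropy_ood=mean_ood,
        ratio=mean_ood / max(mean_id, 1e-12),
        thresholds=[float(t) for t in threshold_grid],
        detection_rate_ood=det,
        false_alarm_rate_id=fa,
    )


def cross_entropy_gap(
    pred_probs: np.ndarray, true_cond_probs: np.ndarray
) -> float:
    """Mean KL( p(y|x) || q(y|x) ): model mismatch against the true conditional.

    Computable only when the true conditional is known (synthetic
    generators); nonnegative by Gibbs' inequality.
    """
    p = np.asarray(true_cond_probs, dtype=float)
    q = np.clip(np.asarray(pred_probs, dtype=float), 1e-300, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * (np.log(p) - np.log(q)), 0.0)
    return float(terms.sum(axis=1).mean())
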