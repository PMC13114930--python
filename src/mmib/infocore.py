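"""Closed-form and plug-in information-theoretic primitives.

Everything here is an exact (oracle-grade) computation on explicit
probability objects: categorical entropy, KL divergence between diagonal
Gaussians, plug-in mutual information on discrete joint distributions, and
the expected calibration error.  All information quantities are in nats.

These functions are the reference against which the estimator modules
(:mod:`mmib.mi_estimation`, :mod:`mmib.vmib`) are tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: probabilities below this are treated as exact zeros in plug-in estimators
ZERO_PROB = 1e-15

#: tolerance for "sums to one" validation
NORM_TOL = 1e-9


def validate_prob_vector(p: np.ndarray) -> np.ndarray:
    """Validate and return a probability vector (entries >= 0, sum to 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("probability vector must be 1-D and non-empty")
    if np.any(p < -NORM_TOL):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities must sum to 1 (got {p.sum():.6g})")
    return np.clip(p, 0.0, None)


@dataclass
class DiagGaussian:
    """Diagonal Gaussian with mean vector and strictly positive variances."""

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.var = np.atleast_1d(np.asarray(self.var, dtype=float))
        if self.mean.shape != self.var.shape:
            raise ValueError("mean and variance must have the same shape")
        if np.any(self.var <= 0):
            raise ValueError("variances must be strictly positive")

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass
class DiscreteJoint:
    """Exact joint pmf over a product of finite supports.

    ``pmf`` is an n-dimensional array, one axis per variable; ``names``
    optionally labels the axes.  Serves as the brute-force MI oracle.
    """

    pmf: np.ndarray
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.pmf = np.asarray(self.pmf, dtype=float)
        if np.any(self.pmf < -NORM_TOL):
            raise ValueError("pmf entries must be non-negative")
        if abs(self.pmf.sum() - 1.0) > 1e-6:
            raise ValueError("pmf must sum to 1")
        self.pmf = np.clip(self.pmf, 0.0, None)
        if self.names is not None and len(self.names) != self.pmf.ndim:
            raise ValueError("one name per pmf axis required")

    @property
    def n_vars(self) -> int:
        return self.pmf.ndim

    def marginal(self, axes: Sequence[int]) -> np.ndarray:
        """Marginal pmf over ``axes`` (order preserved)."""
        axes = tuple(axes)
        drop = tuple(a for a in range(self.pmf.ndim) if a not in axes)
        m = self.pmf.sum(axis=drop) if drop else self.pmf
        # reorder to the requested axis order
        order = np.argsort(np.argsort(axes))
        return np.moveaxis(m, range(m.ndim), order) if m.ndim > 1 else m


def entropy_categorical(p: np.ndarray) -> float:
    """Shannon entropy H(p) = -sum p log p in nats, with 0*log 0 := 0."""
    p = validate_prob_vector(p)
    pz = p[p > ZERO_PROB]
    return float(-(pz * np.log(pz)).sum())


def _entropy_table(pmf: np.ndarray) -> float:
    p = pmf[pmf > ZERO_PROB]
    return float(-(p * np.log(p)).sum())


def kl_diag_gaussian(q: DiagGaussian, r: DiagGaussian) -> float:
    """KL(q || r) between diagonal Gaussians, in nats.

    Closed form: 0.5 * sum( log(vr/vq) + (vq + (mq-mr)^2)/vr - 1 ).
    """
    if q.dim != r.dim:
        raise ValueError("dimension mismatch between q and r")
    return float(
        0.5
        * np.sum(
            np.log(r.var / q.var) + (q.var + (q.mean - r.mean) ** 2) / r.var - 1.0
        )
    )


def plugin_mi_discrete(
    joint: DiscreteJoint,
    groups: tuple[Sequence[int], Sequence[int]] | None = None,
) -> float:
    """Plug-in mutual information I(block1; block2) in nats.

    ``groups`` partitions the pmf axes into two blocks; by default the last
    axis is one block (the target) and all other axes the other.  Computed
    as H(block1) + H(block2) - H(joint), exact on the pmf table.
    """
    nd = joint.pmf.ndim
    if groups is None:
        groups = (tuple(range(nd - 1)), (nd - 1,))
    g1, g2 = (tuple(g) for g in groups)
    if not g1 or not g2:
        raise ValueError("both variable blocks must be non-empty")
    if sorted(g1 + g2) != list(range(nd)):
        raise ValueError("groups must partition all pmf axes")
    h1 = _entropy_table(joint.marginal(g1))
    h2 = _entropy_table(joint.marginal(g2))
    h12 = _entropy_table(joint.pmf)
    return max(0.0, h1 + h2 - h12)


def conditional_mi_discrete(
    joint: DiscreteJoint,
    axes_a: Sequence[int],
    axes_b: Sequence[int],
    axes_cond: Sequence[int],
) -> float:
    """Conditional MI I(A; B | C) by conditioning-and-averaging, in nats."""
    axes_a, axes_b, axes_cond = tuple(axes_a), tuple(axes_b), tuple(axes_cond)
    if not axes_cond:
        sub = joint.marginal(axes_a + axes_b)
        sub_j = DiscreteJoint(sub)
        na = len(axes_a)
        return plugin_mi_discrete(
            sub_j, (tuple(range(na)), tuple(range(na, sub.ndim)))
        )
    keep = axes_cond + axes_a + axes_b
    table = joint.marginal(keep)
    nc, na = len(axes_cond), len(axes_a)
    flat_c = table.reshape(int(np.prod(table.shape[:nc])), *table.shape[nc:])
    out = 0.0
    for slab in flat_c:
        pc = slab.sum()
        if pc <= ZERO_PROB:
            continue
        cond = DiscreteJoint(slab / pc)
        out += pc * plugin_mi_discrete(
            cond, (tuple(range(na)), tuple(range(na, slab.ndim)))
        )
    return float(out)


def predictive_entropy(pred_probs: np.ndarray) -> np.ndarray:
    """Per-row Shannon entropy of predicted class distributions, in nats."""
    p = np.asarray(pred_probs, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    pz = np.clip(p, ZERO_PROB, None)
    h = -(np.where(p > ZERO_PROB, p * np.log(pz), 0.0)).sum(axis=1)
    return h


def expected_calibration_error(
    pred_probs: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 10,
) -> float:
    """Expected calibration error with equal-width confidence bins on [0,1].

    Confidence is the top-1 predicted probability; ECE is the sample-weighted
    mean over bins of |bin accuracy - bin mean confidence|.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    p = np.asarray(pred_probs, dtype=float)
    y = np.asarray(labels)
    if p.ndim != 2 or p.shape[0] == 0:
        raise ValueError("pred_probs must be a non-empty samples x classes matrix")
    if y.shape[0] != p.shape[0]:
        raise ValueError("labels and pred_probs row counts differ")
    conf = p.max(axis=1)
    correct = (p.argmax(axis=1) == y).astype(float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-inclusive bins so confidence 1.0 falls in the last bin
    idx = np.clip(np.searchsorted(edges, conf, side="left") - 1, 0, n_bins - 1)
    n = conf.size
    ece = 0.0
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        gap = abs(correct[mask].mean() - conf[mask].mean())
        ece += mask.sum() / n * gap
    return float(ece)


def empirical_label_distribution(labels: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Empirical class frequencies as a ProbVector."""
    y = np.asarray(labels).astype(int)
    k = int(y.max()) + 1 if n_classes is None else n_classes
    counts = np.bincount(y, minlength=k).astype(float)
    return counts / counts.sum()
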