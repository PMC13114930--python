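"""Classifier-based mutual-information lower bounds and their decomposition.

The workhorse bound is  I(X;Y) >= H(Y) + E[log q(y|x)]  for any classifier
q, evaluated on held-out folds of a stratified cross-validation.  Subset
bounds over modality groups feed the pairwise interaction proxies

    R_ij = I(X_i;Y) + I(X_j;Y) - I(X_i,X_j;Y)   (redundancy)
    S_ij = -R_ij                                 (synergy)

S > 0 indicates predictive information that is only accessible jointly;
S < 0 indicates overlapping (redundant) content.  Because these are
differences of lower bounds they are directional indicators, not exact
quantities; raw values are reported unclamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import copy

import numpy as np
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier

from .datasets import MultimodalDataset
from .infocore import empirical_label_distribution, entropy_categorical


@dataclass
class ProbeProtocol:
    """Cross-validation and probe-classifier settings for MI bounds.

    Early stopping monitors the validation *log-loss* (the quantity the MI
    bound is built from) on an 80/20 stratified split within the training
    fold, restoring the best iterate; stopping on accuracy would freeze the
    probe long before its probabilities sharpen, systematically loosening
    the bound.
    """

    n_folds: int = 5
    hidden_units: int = 256
    max_iter: int = 300
    early_stopping: bool = True
    validation_fraction: float = 0.2
    patience: int = 15
    alpha: float = 1e-4
    standardize: bool = True

    def make_probe(self, seed: int) -> MLPClassifier:
        return MLPClassifier(
            hidden_layer_sizes=(self.hidden_units,),
            max_iter=self.max_iter,
            alpha=self.alpha,
            random_state=seed,
        )


def _fit_probe(
    x: np.ndarray, y: np.ndarray, protocol: ProbeProtocol, seed: int
) -> MLPClassifier:
    """Fit the probe, early-stopping on validation log-loss if configured."""
    probe = protocol.make_probe(seed)
    classes = np.unique(y)
    if not protocol.early_stopping:
        probe.fit(x, y)
        return probe
    xt, xv, yt, yv = train_test_split(
        x,
        y,
        test_size=protocol.validation_fraction,
        stratify=y,
        random_state=seed,
    )
    best_loss = np.inf
    best_state = None
    stall = 0
    for _ in range(protocol.max_iter):
        probe.partial_fit(xt, yt, classes=classes)
        loss = log_loss(yv, probe.predict_proba(xv), labels=classes)
        if loss < best_loss - 1e-4:
            best_loss = loss
            best_state = (copy.deepcopy(probe.coefs_), copy.deepcopy(probe.intercepts_))
            stall = 0
        else:
            stall += 1
            if stall >= protocol.patience:
                break
    if best_state is not None:
        probe.coefs_, probe.intercepts_ = best_state
    return probe


@dataclass
class MIEstimate:
    """An MI lower-bound estimate with cross-fold dispersion."""

    value: float
    std: float
    n_folds: int
    estimator: str = "separate-classifier"
    per_fold: list[float] = field(default_factory=list)

    @property
    def flagged_negative(self) -> bool:
        """Raw bound below zero: reported unclamped but flagged."""
        return self.value < 0


def classifier_mi_bound(
    features: np.ndarray,
    labels: np.ndarray,
    protocol: ProbeProtocol | None = None,
    seed: int = 0,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> MIEstimate:
    """Cross-validated classifier bound on I(X;Y), in nats.

    Per held-out fold: H(Y) (full-data empirical label entropy) plus the
    mean log predicted probability of the true class.  ``folds`` may supply
    precomputed fold index pairs so that two bounds share fold assignments
    (as the transfer-entropy estimator requires).
    """
    protocol = protocol or ProbeProtocol()
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[0] != np.shape(labels)[0]:
        x = x.T
    y = np.asarray(labels).astype(int)
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain non-finite values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    h_y = entropy_categorical(empirical_label_distribution(y))
    if folds is None:
        skf = StratifiedKFold(protocol.n_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(x, y))
    per_fold = []
    for i, (tr, te) in enumerate(folds):
        xt, xe = x[tr], x[te]
        if protocol.standardize:
            mu = xt.mean(axis=0)
            sd = np.maximum(xt.std(axis=0), 1e-8)
            xt, xe = (xt - mu) / sd, (xe - mu) / sd
        probe = _fit_probe(xt, y[tr], protocol, seed * 1009 + i)
        logp = np.log(np.clip(probe.predict_proba(xe), 1e-12, None))
        # probe classes may be a subset in unlucky folds; map columns
        col = {c: j for j, c in enumerate(probe.classes_)}
        ll = np.array(
            [logp[r, col[c]] if c in col else np.log(1e-12) for r, c in enumerate(y[te])]
        )
        per_fold.append(h_y + float(ll.mean()))
    per_fold_arr = np.array(per_fold)
    return MIEstimate(
        value=float(per_fold_arr.mean()),
        std=float(per_fold_arr.std(ddof=1)) if len(per_fold) > 1 else 0.0,
        n_folds=len(per_fold),
        estimator="separate-classifier",
        per_fold=per_fold,
    )


def synergy_proxy(i_joint: float, i_1: float, i_2: float) -> float:
    """S = I(X1,X2;Y) - I(X1;Y) - I(X2;Y); the redundancy proxy is -S."""
    return float(i_joint - i_1 - i_2)


def redundancy_proxy(i_joint: float, i_1: float, i_2: float) -> float:
    return -synergy_proxy(i_joint, i_1, i_2)


def pct_of_entropy(mi: float, label_entropy: float) -> float:
    """MI as a percentage of the label entropy H(Y)."""
    if label_entropy <= 0:
        raise ValueError("label entropy must be positive")
    return 100.0 * mi / label_entropy


def _key(subset) -> tuple[str, ...]:
    return tuple(sorted(subset))


@dataclass
class InfoDecomposition:
    """MI bounds per modality subset plus pairwise synergy proxies."""

    subset_mi: dict[tuple[str, ...], MIEstimate]
    label_entropy: float
    pairwise_synergy: dict[tuple[str, str], float] = field(default_factory=dict)

    def mi(self, subset) -> MIEstimate:
        k = _key(subset)
        if k not in self.subset_mi:
            raise KeyError(f"no MI estimate for subset {k}")
        return self.subset_mi[k]

    def pct(self, subset) -> float:
        return pct_of_entropy(self.mi(subset).value, self.label_entropy)


def decompose_information(
    data: MultimodalDataset,
    subsets: list[list[str]] | None = None,
    protocol: ProbeProtocol | None = None,
    seed: int = 0,
    estimator: str = "separate",
    masked_model=None,
) -> InfoDecomposition:
    """MI bound per modality subset, plus all computable pairwise proxies.

    estimator="separate" trains a fresh probe classifier per subset (the
    default protocol); estimator="masked" scores every subset with one
    modality-dropout-trained VMIB (``masked_model``), zeroing unobserved
    blocks, which keeps bound tightness consistent across subsets.
    """
    names = data.modality_names
    if subsets is None:
        subsets = [[n] for n in names] + [list(p) for p in combinations(names, 2)]
        if len(names) > 2:
            subsets.append(list(names))
    for s in subsets:
        if not s:
            raise ValueError("empty modality subset")
        unknown = [n for n in s if n not in names]
        if unknown:
            raise KeyError(f"unknown modalities {unknown}")
    protocol = protocol or ProbeProtocol()
    subset_mi: dict[tuple[str, ...], MIEstimate] = {}
    if estimator == "separate":
        # shared fold assignments across subsets: consistent comparisons
        skf = StratifiedKFold(protocol.n_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(np.zeros((data.n_samples, 1)), data.labels))
        for s in subsets:
            subset_mi[_key(s)] = classifier_mi_bound(
                data.subset_matrix(s), data.labels, protocol, seed=seed, folds=folds
            )
    elif estimator == "masked":
        if masked_model is None:
            from .vmib import VMIBConfig, train_vmib

            if data.split is None:
                data = data.with_split(0.3, seed=seed)
            masked_model = train_vmib(
                data, VMIBConfig(seed=seed), modality_dropout_p=0.3
            )
        _, test_set = (
            data.train_test() if data.split is not None else (data, data)
        )
        h_y = entropy_categorical(empirical_label_distribution(data.labels))
        for s in subsets:
            probs = masked_model.predict_proba(test_set, observed=list(s))
            ll = np.log(
                np.clip(probs[np.arange(test_set.n_samples), test_set.labels], 1e-12, None)
            )
            subset_mi[_key(s)] = MIEstimate(
                value=h_y + float(ll.mean()),
                std=0.0,
                n_folds=1,
                estimator="masked-single-model",
            )
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    h_y = entropy_categorical(empirical_label_distribution(data.labels))
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in combinations(names, 2):
        ka, kb, kab = _key([a]), _key([b]), _key([a, b])
        if ka in subset_mi and kb in subset_mi and kab in subset_mi:
            pairwise[(a, b)] = synergy_proxy(
                subset_mi[kab].value, subset_mi[ka].value, subset_mi[kb].value
            )
    return InfoDecomposition(subset_mi, h_y, pairwise)


def info_loss_imiss(decomp: InfoDecomposition, observed: list[str]) -> float:
    """Imiss(S): predictive information lost when only S is observed.

    max(0, MI(full set) - MI(S)) from the decomposition's bounds; the raw
    difference can be negative (differences of lower bounds) and is clamped.
    """
    full_key = max(decomp.subset_mi, key=len)
    obs = decomp.mi(observed)
    full = decomp.subset_mi[full_key]
    if _key(observed) == full_key:
        return 0.0
    return max(0.0, full.value - obs.value)
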