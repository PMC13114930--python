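"""Fusion-collapse and adaptation diagnostics.

Fusion collapse — a multimodal representation that leans on a single
modality — is diagnosed through the empirical modality-conditioned
predictive gap

    G~_i = max(0, AUC(all modalities) - AUC(modality i ablated)),

an operational proxy for the information-theoretic gap
G_i = I(Z;Y) - I(Z;Y | X^(i)).  The balance index is the normalized
entropy of the gap distribution: B = H(G~ / sum G~) / ln M, 1.0 meaning
perfectly balanced reliance, 0 meaning total collapse onto one modality.
Both quantities are most interpretable in redundancy-dominated settings; a
warning is attached when positive synergy proxies suggest otherwise.

Adaptation diagnostics compare strategies for fitting a pretrained VMIB to
a small labeled dataset, reporting the AUC change against the shift in the
mean posterior-to-prior KL (how much the adapted encoder re-expands its
input sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datasets import MultimodalDataset
from .infocore import entropy_categorical
from .vmib import TrainedVMIB, evaluate_model, train_vmib

ADAPTATION_STRATEGIES = ("scratch", "linear_probe", "full_finetune", "partial_finetune")


@dataclass
class GapProfile:
    """Per-modality predictive gaps (AUC units) and their balance index."""

    gaps: dict[str, float]
    balance: float
    n_seeds: int
    auc_full: float
    synergy_warning: bool = False


def balance_index(gaps: np.ndarray) -> float:
    """Normalized entropy of the gap distribution, in [0, 1].

    B = H(gaps / sum) / ln M with 0*ln 0 = 0; B := 0 for an all-zero gap
    vector (degenerate: no measurable predictive reliance).  Permutation-
    and scale-invariant.
    """
    g = np.asarray(gaps, dtype=float)
    if g.size < 2:
        raise ValueError("need gaps for at least 2 modalities")
    if np.any(g < 0):
        raise ValueError("gaps must be non-negative")
    total = g.sum()
    if total == 0:
        return 0.0
    p = g / total
    return float(entropy_categorical(p) / np.log(g.size))


def reliance_share(gaps: dict[str, float], modality: str) -> float:
    """Fraction of total predictive reliance carried by one modality."""
    total = sum(gaps.values())
    if total == 0:
        raise ValueError("all gaps are zero")
    return gaps[modality] / total


def predictive_gap_profile(
    model_factory,
    data: MultimodalDataset,
    seeds: list[int],
    synergy_values: dict | None = None,
) -> GapProfile:
    """Seed-averaged ablation gaps G~_i and their balance index.

    ``model_factory(data, seed) -> TrainedVMIB`` trains (or retrieves) one
    model per seed; each modality is zero-ablated at inference.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    names = data.modality_names
    gaps = {n: [] for n in names}
    aucs = []
    for seed in seeds:
        model = model_factory(data, seed)
        ev_full = evaluate_model(model, data)
        aucs.append(ev_full["auc"])
        for n in names:
            observed = [m for m in names if m != n]
            ev_abl = evaluate_model(model, data, observed=observed)
            gaps[n].append(max(0.0, ev_full["auc"] - ev_abl["auc"]))
    mean_gaps = {n: float(np.mean(v)) for n, v in gaps.items()}
    warn = bool(
        synergy_values and any(s > 0 for s in synergy_values.values())
    )
    return GapProfile(
        gaps=mean_gaps,
        balance=balance_index(np.array(list(mean_gaps.values()))),
        n_seeds=len(seeds),
        auc_full=float(np.mean(aucs)),
        synergy_warning=warn,
    )


@dataclass
class AdaptationReport:
    strategy: str
    auc: float
    delta_auc: float
    delta_kl: float
    efficiency: float


def _trainable_names(model: TrainedVMIB, strategy: str) -> set[str] | None:
    if strategy in {"scratch", "full_finetune"}:
        return None  # everything trains
    pred = set(model.predictor.param_names())
    if strategy == "linear_probe":
        return pred
    # partial fine-tune: final layer of each encoder + posterior head + predictor
    names = set(pred) | set(model.posterior.param_names())
    for enc in model.encoders.values():
        last = enc.n_layers - 1
        names |= {f"{enc.prefix}.W{last}", f"{enc.prefix}.b{last}"}
    return names


def _finetune(
    model: TrainedVMIB,
    data: MultimodalDataset,
    epochs: int,
    lr: float,
    seed: int,
    trainable: set[str] | None,
) -> TrainedVMIB:
    """Continue training a cloned model on a small dataset (no re-init)."""
    from ._nn import Adam, cosine_lr
    from .vmib import loss_and_grads

    out = model.clone()
    if epochs == 0:
        return out
    train_set, _ = data.train_test()
    blocks_all = out.standardize(train_set.modalities)
    y = train_set.labels
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    opt = Adam(out.params, lr=lr, trainable=trainable)
    lam = out.config.lambda_compress
    n = y.shape[0]
    bs = min(out.config.batch_size, n)
    for epoch in range(epochs):
        lr_t = cosine_lr(lr, epoch, epochs)
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            blocks = [b[idx] for b in blocks_all]
            _, grads = loss_and_grads(out, blocks, y[idx], lam, rng=rng)
            opt.step(out.params, grads, lr=lr_t)
    return out


def adaptation_report(
    pretrained: TrainedVMIB,
    data_small: MultimodalDataset,
    strategy: str,
    epochs: int = 40,
    lr: float = 1e-3,
    seed: int = 0,
    eval_data: MultimodalDataset | None = None,
) -> AdaptationReport:
    """Adapt a pretrained model to a small labeled dataset and audit the shift.

    delta_kl is the change (after - before) in the mean posterior-to-prior
    KL on a fixed evaluation set; efficiency = delta_auc / max(|delta_kl|,
    0.01), predictive gain per nat of input-sensitivity shift.
    """
    if strategy not in ADAPTATION_STRATEGIES:
        raise ValueError(f"strategy must be one of {ADAPTATION_STRATEGIES}")
    if data_small.split is None:
        raise ValueError("data_small needs a train/test split")
    eval_data = eval_data if eval_data is not None else data_small.train_test()[1]
    kl_before = pretrained.mean_posterior_kl(eval_data)
    auc_before = evaluate_model(pretrained, data_small)["auc"]
    if strategy == "scratch":
        if epochs == 0:
            adapted = pretrained.clone()
        else:
            cfg = replace(pretrained.config, epochs=epochs, seed=seed)
            adapted = train_vmib(data_small, cfg)
    else:
        adapted = _finetune(
            pretrained,
            data_small,
            epochs=epochs,
            lr=lr,
            seed=seed,
            trainable=_trainable_names(pretrained, strategy),
        )
    kl_after = adapted.mean_posterior_kl(eval_data)
    auc_after = evaluate_model(adapted, data_small)["auc"]
    delta_auc = auc_after - auc_before
    delta_kl = kl_after - kl_before
    return AdaptationReport(
        strategy=strategy,
        auc=auc_after,
        delta_auc=delta_auc,
        delta_kl=delta_kl,
        efficiency=delta_auc / max(abs(delta_kl), 0.01),
    )
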