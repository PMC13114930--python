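"""Missing-modality robustness: training strategies and ablation evaluation.

Two mechanisms make a VMIB degrade gracefully when modality blocks are
absent at inference time:

* modality dropout — whole blocks are zeroed at random during training
  (each sample always keeps at least one block), a Monte-Carlo surrogate of
  the consistency objective;
* a posterior consistency penalty — the forward KL from the full-input
  posterior to each masked-input posterior, ramped in over a warmup, which
  pushes partial-observation representations to cover the full-information
  posterior.

Evaluation zeroes unobserved blocks post-standardization (mirroring the
training mechanism) and pairs each observed subset's AUC with the intrinsic
information loss Imiss(S) from the MI decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import spearmanr

from .datasets import MultimodalDataset
from .infocore import DiagGaussian, kl_diag_gaussian
from .mi_estimation import InfoDecomposition, info_loss_imiss
from .vmib import TrainedVMIB, VMIBConfig, _dropout_mask_blocks, evaluate_model, train_vmib


@dataclass
class RobustnessConfig:
    """Strategy and knobs for robust VMIB training."""

    strategy: str = "standard"  # standard | dropout | consistency
    dropout_prob: float = 0.3
    gamma: float = 0.05
    warmup_epochs: int = 30
    subsets: list[list[str]] | None = None  # default: size M-1 + singletons

    def __post_init__(self) -> None:
        if self.strategy not in {"standard", "dropout", "consistency"}:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def default_penalty_subsets(names: list[str]) -> list[list[str]]:
    """All proper subsets of size M-1 plus all singletons."""
    out = [list(c) for c in combinations(names, len(names) - 1)] if len(names) > 1 else []
    out += [[n] for n in names]
    # deduplicate while preserving order (M=2 makes them coincide)
    seen, uniq = set(), []
    for s in out:
        k = tuple(s)
        if k not in seen:
            seen.add(k)
            uniq.append(s)
    return uniq


def apply_modality_dropout(
    blocks: list[np.ndarray], p: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Independently zero each modality block per sample with probability p.

    A sample losing every block gets one uniformly chosen block restored, so
    no all-zero multimodal input ever reaches the encoder.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p == 0.0:
        return [b.copy() for b in blocks]
    return _dropout_mask_blocks(blocks, p, rng)


def consistency_penalty(full: DiagGaussian, partial: DiagGaussian) -> float:
    """Forward KL( q(z|full) || q(z|partial) ), full posterior first."""
    return kl_diag_gaussian(full, partial)


def train_robust_vmib(
    data: MultimodalDataset,
    vmib_config: VMIBConfig,
    robustness_config: RobustnessConfig,
) -> TrainedVMIB:
    """Train the configured variant; deterministic given the seed."""
    rc = robustness_config
    if rc.strategy == "standard":
        return train_vmib(data, vmib_config)
    if rc.strategy == "dropout":
        return train_vmib(data, vmib_config, modality_dropout_p=rc.dropout_prob)
    subsets = (
        rc.subsets
        if rc.subsets is not None
        else default_penalty_subsets(data.modality_names)
    )
    if not subsets:
        raise ValueError("consistency strategy requires a non-empty subset collection")
    return train_vmib(
        data, vmib_config, consistency=(rc.gamma, rc.warmup_epochs, subsets)
    )


@dataclass
class AblationResult:
    observed_subset: tuple[str, ...]
    auc: float
    accuracy: float
    imiss: float

    def __post_init__(self) -> None:
        if not self.observed_subset:
            raise ValueError("observed subset must contain at least one modality")


def evaluate_ablation_grid(
    model: TrainedVMIB,
    data: MultimodalDataset,
    decomp: InfoDecomposition | None,
    subsets: list[list[str]] | None = None,
) -> list[AblationResult]:
    """Test AUC/accuracy with unobserved blocks zeroed, paired with Imiss."""
    names = data.modality_names
    if subsets is None:
        subsets = [list(names)] + default_penalty_subsets(names)
    out = []
    for s in subsets:
        ev = evaluate_model(model, data, observed=list(s))
        imiss = 0.0
        if decomp is not None:
            imiss = info_loss_imiss(decomp, list(s))
        out.append(
            AblationResult(
                observed_subset=tuple(sorted(s)),
                auc=ev["auc"],
                accuracy=ev["accuracy"],
                imiss=imiss,
            )
        )
    return out


def imiss_auc_correlation(results: list[AblationResult]) -> float:
    """Spearman correlation between Imiss(S) and the AUC drop across subsets."""
    full = max(results, key=lambda r: len(r.observed_subset))
    drops = [full.auc - r.auc for r in results]
    imiss = [r.imiss for r in results]
    rho = spearmanr(imiss, drops).statistic
    return float(rho)
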