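"""Synthetic multimodal generators with known information structure.

Four families, each bit-reproducible from its seed and carrying its full
configuration (and any analytically known quantity) in dataset metadata:

* small discrete joints (XOR / binary symmetric channel / copy /
  independent) with their exact pmf, the brute-force oracle fixtures;
* a two-Gaussian-modality Bernoulli-logistic model with a tunable
  multiplicative interaction, the canonical synergy testbed;
* a latent-class multi-omics-like generator with per-modality
  signal-to-noise and configurable redundancy (which modalities read the
  same latent coordinates), used for dominance/robustness studies;
* a coupled autoregressive longitudinal process whose transfer entropy is
  known in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import expit

from .datasets import LongitudinalDataset, MultimodalDataset
from .infocore import DiscreteJoint


# ---------------------------------------------------------------- discrete

def gen_discrete_joint(
    kind: str, n: int = 2000, seed: int = 0, flip_prob: float = 0.1
) -> tuple[DiscreteJoint, MultimodalDataset]:
    """Exact pmf plus an i.i.d. sample from it.

    Kinds: ``xor`` (Y = X1 xor X2, fair independent bits), ``bsc`` (binary
    symmetric channel with the given flip probability, uniform input),
    ``copy`` (Y = X1; X2 an independent fair bit), ``independent``.
    """
    if kind == "bsc":
        if not 0.0 <= flip_prob <= 1.0:
            raise ValueError("flip probability must be in [0, 1]")
        pmf = np.array(
            [[(1 - flip_prob) / 2, flip_prob / 2], [flip_prob / 2, (1 - flip_prob) / 2]]
        )
        joint = DiscreteJoint(pmf, names=("x1", "y"))
        var_names = ["x1"]
    elif kind in {"xor", "copy", "independent"}:
        pmf = np.zeros((2, 2, 2))
        for x1 in (0, 1):
            for x2 in (0, 1):
                if kind == "xor":
                    y = x1 ^ x2
                    pmf[x1, x2, y] = 0.25
                elif kind == "copy":
                    pmf[x1, x2, x1] = 0.25
                else:
                    pmf[x1, x2, :] = 0.125
        joint = DiscreteJoint(pmf, names=("x1", "x2", "y"))
        var_names = ["x1", "x2"]
    else:
        raise ValueError(f"unknown joint kind {kind!r}")
    rng = np.random.default_rng(seed)
    flat = joint.pmf.ravel()
    draws = rng.choice(flat.size, size=n, p=flat)
    states = np.array(np.unravel_index(draws, joint.pmf.shape)).T.astype(float)
    modalities = {nm: states[:, [j]] for j, nm in enumerate(var_names)}
    labels = states[:, -1].astype(int)
    data = MultimodalDataset(
        modalities,
        labels,
        metadata={"generator": "discrete_joint", "kind": kind, "seed": seed, "n": n},
    )
    return joint, data


# ------------------------------------------------------------- interaction

@dataclass
class InteractionGenConfig:
    """Two standard-normal modalities with a Bernoulli-logistic target.

    Y | X1, X2 ~ Bernoulli( sigmoid(beta1*X1 + beta2*X2 + alpha*X1*X2) );
    alpha >= 0 controls the strength of the purely synergistic interaction.
    """

    n: int = 5000
    beta1: float = 0.5
    beta2: float = 0.5
    alpha: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.alpha < 0:
            raise ValueError("n must be >= 1 and alpha >= 0")


def gen_interaction(config: InteractionGenConfig) -> MultimodalDataset:
    rng = np.random.default_rng(config.seed)
    x1 = rng.standard_normal(config.n)
    x2 = rng.standard_normal(config.n)
    p = expit(config.beta1 * x1 + config.beta2 * x2 + config.alpha * x1 * x2)
    y = (rng.random(config.n) < p).astype(int)
    return MultimodalDataset(
        {"x1": x1[:, None], "x2": x2[:, None]},
        y,
        metadata={"generator": "interaction", "config": config.__dict__ | {}},
    )


def interaction_label_rate(config: InteractionGenConfig, order: int = 64) -> float:
    """Analytic E[P(Y=1)] by 2-D Gauss-Hermite quadrature (oracle)."""
    nodes, weights = hermegauss(order)
    w = weights / weights.sum()
    g1, g2 = np.meshgrid(nodes, nodes)
    ww = np.outer(w, w)
    p = expit(config.beta1 * g1 + config.beta2 * g2 + config.alpha * g1 * g2)
    return float((ww * p).sum())


# ------------------------------------------------------------ latent class

@dataclass
class ModalitySpec:
    """One modality of the latent-class generator.

    ``snr`` scales the signal loading relative to unit observation noise;
    ``latent_coords`` lists which latent coordinates the modality reads
    (shared coordinates across modalities create redundancy).
    """

    name: str
    dim: int
    snr: float
    latent_coords: list[int] = field(default_factory=lambda: [0, 1])

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")


def _default_modalities() -> list[ModalitySpec]:
    # multi-omics-like shape: one dominant block, one redundant copy of the
    # same latent signal, one weaker block reading separate coordinates
    return [
        ModalitySpec("m1", dim=10, snr=3.0, latent_coords=[0, 1, 2, 3]),
        ModalitySpec("m2", dim=10, snr=1.0, latent_coords=[0, 1, 2, 3]),
        ModalitySpec("m3", dim=8, snr=0.6, latent_coords=[4, 5]),
    ]


@dataclass
class LatentClassGenConfig:
    n: int = 2000
    n_classes: int = 5
    latent_dim: int = 8
    class_separation: float = 2.0
    class_prior: tuple[float, ...] | None = None
    modalities: list[ModalitySpec] = field(default_factory=_default_modalities)
    test_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for spec in self.modalities:
            if max(spec.latent_coords, default=-1) >= self.latent_dim:
                raise ValueError(
                    f"modality {spec.name!r} reads latent coordinates beyond latent_dim"
                )
        if self.class_prior is not None and len(self.class_prior) != self.n_classes:
            raise ValueError("class_prior length must equal n_classes")


def gen_latent_class(config: LatentClassGenConfig) -> MultimodalDataset:
    """Class-conditional latent Gaussians observed through noisy linear maps."""
    rng = np.random.default_rng(config.seed)
    prior = (
        np.array(config.class_prior, dtype=float)
        if config.class_prior is not None
        else np.array([0.35, 0.25, 0.18, 0.13, 0.09][: config.n_classes])
    )
    prior = prior / prior.sum()
    y = rng.choice(config.n_classes, size=config.n, p=prior)
    class_means = (
        rng.standard_normal((config.n_classes, config.latent_dim))
        * config.class_separation
    )
    u = class_means[y] + rng.standard_normal((config.n, config.latent_dim))
    modalities: dict[str, np.ndarray] = {}
    for spec in config.modalities:
        coords = np.array(spec.latent_coords, dtype=int)
        if coords.size:
            w = rng.standard_normal((coords.size, spec.dim)) / np.sqrt(coords.size)
            signal = u[:, coords] @ w
        else:
            signal = np.zeros((config.n, spec.dim))
        modalities[spec.name] = spec.snr * signal + rng.standard_normal(
            (config.n, spec.dim)
        )
    dominance = sorted(
        config.modalities,
        key=lambda s: -(s.snr * max(len(s.latent_coords), 1)),
    )
    data = MultimodalDataset(
        modalities,
        y,
        metadata={
            "generator": "latent_class",
            "dominance_order": [s.name for s in dominance],
            "seed": config.seed,
            "n": config.n,
        },
    )
    return data.with_split(config.test_fraction, seed=config.seed + 1)


# -------------------------------------------------------------- coupled AR

@dataclass
class CoupledARGenConfig:
    """Longitudinal generator: severity driven by a coupled AR(1) source.

    Per subject: driver X_t = rho*X_{t-1} + N(0, sigma_x^2); latent severity
    S_t = a*S_{t-1} + b*X_{t-1} + N(0, sigma_y^2).  Stage is severity
    thresholded into 3 levels (mirroring CDR 0 / 0.5 / >=1); per-visit
    modality j observes severity through stage-scheduled noise, so each
    modality can be made maximally informative at a designed stage.
    """

    n_subjects: int = 150
    n_visits: int = 5
    a: float = 0.7
    b: float = 0.8
    rho: float = 0.5
    sigma_x: float = 1.0
    sigma_y: float = 0.5
    stage_thresholds: tuple[float, float] = (0.0, 1.2)
    stage_noise: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"cog": (1.5, 0.3, 1.5), "img": (0.3, 1.5, 1.5)}
    )
    burn_in: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (abs(self.a) < 1 and abs(self.rho) < 1):
            raise ValueError("non-stationary parameters: need |a| < 1 and |rho| < 1")
        if self.n_visits < 2:
            raise ValueError("need at least 2 visits per subject")


def gen_coupled_ar(config: CoupledARGenConfig) -> LongitudinalDataset:
    from .temporal import gaussian_ar_te_closed_form  # analytic TE attachment

    rng = np.random.default_rng(config.seed)
    rows = []
    t0, t1 = config.stage_thresholds
    for subj in range(config.n_subjects):
        x = s = 0.0
        for t in range(config.burn_in + config.n_visits):
            x_new = config.rho * x + rng.normal(0.0, config.sigma_x)
            s_new = config.a * s + config.b * x + rng.normal(0.0, config.sigma_y)
            x, s = x_new, s_new
            if t < config.burn_in:
                continue
            stage = 0 if s <= t0 else (1 if s <= t1 else 2)
            row = {
                "subject": subj,
                "visit": t - config.burn_in,
                "driver": x,
                "severity": s,
                "stage": stage,
            }
            for name, sched in config.stage_noise.items():
                row[name] = s + rng.normal(0.0, sched[stage])
            rows.append(row)
    te = gaussian_ar_te_closed_form(
        config.a, config.b, config.sigma_x, config.sigma_y, rho=config.rho
    )
    return LongitudinalDataset(
        pd.DataFrame(rows),
        modality_columns=["driver", *config.stage_noise.keys()],
        target_column="severity",
        metadata={
            "generator": "coupled_ar",
            "analytic_te": te,
            "seed": config.seed,
            "config": {
                "a": config.a,
                "b": config.b,
                "rho": config.rho,
                "sigma_x": config.sigma_x,
                "sigma_y": config.sigma_y,
            },
        },
    )
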