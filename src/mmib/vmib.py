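"""Variational multimodal information bottleneck (VMIB).

The model compresses M heterogeneous feature blocks X^(1:M) into a shared
stochastic latent Z and predicts a categorical target Y from Z:

    per-modality encoder MLPs -> concatenation fusion -> diagonal-Gaussian
    posterior q(z|x) -> one reparameterized sample -> MLP predictor q(y|z)

trained on the objective

    L = E[-log q(y|z)] + lambda * E[ KL( q(z|x) || N(0, I) ) ],

where ``lambda`` trades prediction against compression.  The KL term upper-
bounds I(Z;X) and ``H(Y) - cross-entropy`` lower-bounds I(Z;Y), so a trained
model directly yields a point in the information plane.

The network is implemented in numpy with hand-derived gradients (see
:mod:`mmib._nn`); training supports modality dropout and a posterior
consistency penalty, which the :mod:`mmib.robustness` module configures.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score, roc_auc_score

from ._nn import MLP, Adam, ParamDict, cosine_lr, softmax, softmax_nll
from .datasets import MultimodalDataset
from .infocore import DiagGaussian, empirical_label_distribution, entropy_categorical

LOGVAR_CLIP = 10.0


class TrainingError(RuntimeError):
    """Raised when optimization diverges; carries the last finite epoch."""

    def __init__(self, msg: str, last_good_epoch: int | None = None):
        super().__init__(msg)
        self.last_good_epoch = last_good_epoch


@dataclass
class VMIBConfig:
    """Hyper-parameters of the VMIB model and its training loop."""

    latent_dim: int = 32
    hidden_units: int = 256
    encoder_depth: int = 2
    predictor_hidden: int = 64
    dropout_rate: float = 0.3
    lambda_compress: float = 0.01
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 128
    schedule: str = "cosine"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.epochs < 1:
            raise ValueError("latent_dim and epochs must be >= 1")
        if self.lambda_compress < 0:
            raise ValueError("lambda_compress must be >= 0")


@dataclass
class TrainedVMIB:
    """A trained VMIB: parameters, architecture handles, scalers, history."""

    config: VMIBConfig
    modality_names: list[str]
    dims: dict[str, int]
    n_classes: int
    params: ParamDict
    encoders: dict[str, MLP]
    posterior: MLP
    predictor: MLP
    scaler_mean: dict[str, np.ndarray]
    scaler_std: dict[str, np.ndarray]
    history: list[dict] = field(default_factory=list)

    def clone(self) -> "TrainedVMIB":
        out = copy.copy(self)
        out.params = {k: v.copy() for k, v in self.params.items()}
        out.history = list(self.history)
        return out

    def standardize(
        self, modalities: dict[str, np.ndarray], observed: list[str] | None = None
    ) -> np.ndarray:
        """Standardize with training statistics; zero-impute unobserved blocks."""
        blocks = []
        for name in self.modality_names:
            x = np.atleast_2d(np.asarray(modalities[name], dtype=float))
            z = (x - self.scaler_mean[name]) / self.scaler_std[name]
            if observed is not None and name not in observed:
                z = np.zeros_like(z)
            blocks.append(z)
        return blocks

    def encode(
        self,
        blocks: list[np.ndarray],
        train: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Posterior (mu, logvar) from standardized modality blocks."""
        hs, caches = [], []
        for name, x in zip(self.modality_names, blocks):
            h, c = self.encoders[name].forward(x, self.params, train=train, rng=rng)
            hs.append(h)
            caches.append(c)
        hcat = np.hstack(hs)
        stats, pcache = self.posterior.forward(hcat, self.params, train=train, rng=rng)
        d = self.config.latent_dim
        mu, logvar = stats[:, :d], np.clip(stats[:, d:], -LOGVAR_CLIP, LOGVAR_CLIP)
        return mu, logvar, (caches, pcache)

    def encode_backward(self, dmu, dlogvar, cache, grads) -> None:
        caches, pcache = cache
        dstats = np.hstack([dmu, dlogvar])
        dhcat = self.posterior.backward(dstats, pcache, self.params, grads)
        start = 0
        for name, c in zip(self.modality_names, caches):
            width = self.encoders[name].sizes[-1]
            self.encoders[name].backward(dhcat[:, start : start + width], c, self.params, grads)
            start += width

    def posteriors_for(
        self, data: MultimodalDataset, observed: list[str] | None = None
    ) -> list[DiagGaussian]:
        """Per-sample posterior q(z|x) as DiagGaussian objects."""
        blocks = self.standardize(data.modalities, observed)
        mu, logvar, _ = self.encode(blocks, train=False)
        return [DiagGaussian(m, np.exp(lv)) for m, lv in zip(mu, logvar)]

    def latent_means(
        self, data: MultimodalDataset, observed: list[str] | None = None
    ) -> np.ndarray:
        blocks = self.standardize(data.modalities, observed)
        mu, _, _ = self.encode(blocks, train=False)
        return mu

    def predict_proba(
        self, data: MultimodalDataset, observed: list[str] | None = None
    ) -> np.ndarray:
        """Class probabilities from the posterior mean (deterministic eval)."""
        z = self.latent_means(data, observed)
        logits, _ = self.predictor.forward(z, self.params, train=False)
        return softmax(logits)

    def mean_posterior_kl(
        self, data: MultimodalDataset, observed: list[str] | None = None
    ) -> float:
        """Mean KL( q(z|x) || N(0,I) ) over samples, in nats."""
        blocks = self.standardize(data.modalities, observed)
        mu, logvar, _ = self.encode(blocks, train=False)
        kl = 0.5 * (mu**2 + np.exp(logvar) - logvar - 1.0).sum(axis=1)
        return float(kl.mean())


def _build_model(data: MultimodalDataset, config: VMIBConfig) -> TrainedVMIB:
    rng = np.random.default_rng(config.seed)
    names = data.modality_names
    dims = data.dims
    h = config.hidden_units
    encoders = {
        name: MLP(
            f"enc.{name}",
            [dims[name]] + [h] * config.encoder_depth,
            dropout=config.dropout_rate,
        )
        for name in names
    }
    posterior = MLP("post", [h * len(names), 2 * config.latent_dim])
    predictor = MLP(
        "pred", [config.latent_dim, config.predictor_hidden, data.n_classes]
    )
    params: ParamDict = {}
    for enc in encoders.values():
        params.update(enc.init_params(rng))
    params.update(posterior.init_params(rng))
    params.update(predictor.init_params(rng))
    train = data.take(~data.split) if data.split is not None else data
    mean = {n: train.modalities[n].mean(axis=0) for n in names}
    std = {
        n: np.maximum(train.modalities[n].std(axis=0), 1e-8) for n in names
    }
    return TrainedVMIB(
        config=config,
        modality_names=names,
        dims=dims,
        n_classes=data.n_classes,
        params=params,
        encoders=encoders,
        posterior=posterior,
        predictor=predictor,
        scaler_mean=mean,
        scaler_std=std,
    )


def gaussian_kl_standard(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Mean over batch of KL( N(mu, e^logvar) || N(0, I) )."""
    return float(0.5 * (mu**2 + np.exp(logvar) - logvar - 1.0).sum(axis=1).mean())


def vmib_loss(
    model: TrainedVMIB,
    blocks: list[np.ndarray],
    labels: np.ndarray,
    lam: float,
    rng: np.random.Generator,
    train: bool = True,
) -> tuple[float, float, float]:
    """Objective value on one (already standardized) batch: (loss, nll, kl)."""
    mu, logvar, _ = model.encode(blocks, train=train, rng=rng)
    eps = rng.standard_normal(mu.shape) if train else 0.0
    z = mu + np.exp(0.5 * logvar) * eps if train else mu
    logits, _ = model.predictor.forward(z, model.params, train=train, rng=rng)
    nll, _ = softmax_nll(logits, labels)
    kl = gaussian_kl_standard(mu, logvar)
    return nll + lam * kl, nll, kl


def _consistency_grads(mu_f, lv_f, mu_p, lv_p):
    """Forward-KL consistency penalty and its four gradients.

    penalty = mean over batch of KL( N(mu_f, e^lv_f) || N(mu_p, e^lv_p) ),
    full-information posterior first (mean-seeking direction).
    """
    vf, vp = np.exp(lv_f), np.exp(lv_p)
    dm = mu_f - mu_p
    pen = 0.5 * (lv_p - lv_f + (vf + dm**2) / vp - 1.0).sum(axis=1).mean()
    n = mu_f.shape[0]
    dmu_f = dm / vp / n
    dmu_p = -dm / vp / n
    dlv_f = 0.5 * (vf / vp - 1.0) / n
    dlv_p = 0.5 * (1.0 - (vf + dm**2) / vp) / n
    return float(pen), dmu_f, dmu_p, dlv_f, dlv_p


def loss_and_grads(
    model: TrainedVMIB,
    blocks: list[np.ndarray],
    labels: np.ndarray,
    lam: float,
    rng: np.random.Generator | None = None,
    eps: np.ndarray | None = None,
    gamma_t: float = 0.0,
    subsets: list[list[str]] | None = None,
) -> tuple[dict, ParamDict]:
    """One training step's objective and parameter gradients.

    Returns ``({'loss', 'nll', 'kl', 'consistency'}, grads)``.  ``eps`` may
    pin the reparameterization noise (finite-difference gradient checks);
    otherwise it is drawn from ``rng``.  When ``gamma_t > 0`` the forward-KL
    posterior-consistency penalty over the masked-input ``subsets`` is added,
    with gradients flowing through both the full and the masked encoder
    passes.
    """
    grads: ParamDict = {}
    names = model.modality_names
    mu, logvar, cache = model.encode(blocks, train=True, rng=rng)
    if eps is None:
        eps = rng.standard_normal(mu.shape)
    sigma = np.exp(0.5 * logvar)
    z = mu + sigma * eps
    logits, pred_cache = model.predictor.forward(z, model.params, train=True, rng=rng)
    nll, dlogits = softmax_nll(logits, labels)
    kl = gaussian_kl_standard(mu, logvar)
    dz = model.predictor.backward(dlogits, pred_cache, model.params, grads)
    b = mu.shape[0]
    dmu = dz.copy()
    dlv = dz * eps * 0.5 * sigma
    if lam > 0.0:
        dmu += lam * mu / b
        dlv += lam * 0.5 * (np.exp(logvar) - 1.0) / b
    pen = 0.0
    if gamma_t > 0.0 and subsets:
        w = gamma_t / len(subsets)
        for subset in subsets:
            masked = [
                blk if nm in subset else np.zeros_like(blk)
                for nm, blk in zip(names, blocks)
            ]
            mu_p, lv_p, cache_p = model.encode(masked, train=True, rng=rng)
            p_val, dmf, dmp, dlf, dlp = _consistency_grads(mu, logvar, mu_p, lv_p)
            pen += p_val / len(subsets)
            dmu += w * dmf
            dlv += w * dlf
            model.encode_backward(w * dmp, w * dlp, cache_p, grads)
    model.encode_backward(dmu, dlv, cache, grads)
    loss = nll + lam * kl + gamma_t * pen
    return {"loss": loss, "nll": nll, "kl": kl, "consistency": pen}, grads


def _dropout_mask_blocks(
    blocks: list[np.ndarray], p: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Zero whole modality blocks per sample with prob p; keep >= 1 modality."""
    n = blocks[0].shape[0]
    m = len(blocks)
    drop = rng.random((n, m)) < p
    all_dropped = drop.all(axis=1)
    if all_dropped.any():
        restore = rng.integers(0, m, size=int(all_dropped.sum()))
        drop[np.flatnonzero(all_dropped), restore] = False
    return [b * (~drop[:, [j]]) for j, b in enumerate(blocks)]


def train_vmib(
    data: MultimodalDataset,
    config: VMIBConfig,
    modality_dropout_p: float = 0.0,
    consistency: tuple[float, int, list[list[str]]] | None = None,
) -> TrainedVMIB:
    """Train a VMIB; deterministic given (data, config, seed).

    ``consistency`` = (gamma, warmup_epochs, subsets): adds the forward-KL
    posterior-consistency penalty averaged over the masked-input subsets,
    with gamma ramped linearly from 0 over the warmup epochs.
    """
    if data.split is None:
        data = data.with_split(0.3, seed=config.seed)
    train_set, _ = data.train_test()
    if train_set.n_samples == 0 or len(np.unique(train_set.labels)) < 2:
        raise ValueError("training split must be non-empty with >= 2 classes")
    model = _build_model(data, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    blocks_all = model.standardize(train_set.modalities)
    y_all = train_set.labels
    n = y_all.shape[0]
    lam = config.lambda_compress
    opt = Adam(model.params, lr=config.learning_rate)
    last_good = -1
    for epoch in range(config.epochs):
        lr = (
            cosine_lr(config.learning_rate, epoch, config.epochs)
            if config.schedule == "cosine"
            else config.learning_rate
        )
        if consistency is not None:
            gamma_full, warmup, subsets = consistency
            gamma_t = gamma_full * min(1.0, (epoch + 1) / max(warmup, 1))
        order = rng.permutation(n)
        ep_nll = ep_kl = ep_pen = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            blocks = [b[idx] for b in blocks_all]
            yb = y_all[idx]
            if modality_dropout_p > 0.0:
                blocks = _dropout_mask_blocks(blocks, modality_dropout_p, rng)
            comps, grads = loss_and_grads(
                model,
                blocks,
                yb,
                lam,
                rng=rng,
                gamma_t=gamma_t if consistency is not None else 0.0,
                subsets=subsets if consistency is not None else None,
            )
            if not np.isfinite(comps["loss"]):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}", last_good_epoch=last_good
                )
            opt.step(model.params, grads, lr=lr)
            ep_nll += comps["nll"]
            ep_kl += comps["kl"]
            ep_pen += comps["consistency"]
            n_batches += 1
        last_good = epoch
        model.history.append(
            {
                "epoch": epoch,
                "nll": ep_nll / n_batches,
                "kl": ep_kl / n_batches,
                "consistency": ep_pen / n_batches,
                "lr": lr,
            }
        )
    return model


@dataclass
class InfoPlanePoint:
    """One point of a compression sweep: bounds and test metrics at one lambda."""

    lam: float
    compression_bound: float  # mean KL(q(z|x) || prior), upper-bounds I(Z;X)
    prediction_bound: float  # H(Y) - test cross-entropy, lower-bounds I(Z;Y)
    prediction_bound_train: float
    accuracy: float
    auc: float
    seed: int


def macro_ovr_auc(labels: np.ndarray, probs: np.ndarray, n_classes: int | None = None) -> float:
    """Macro-averaged one-vs-rest AUC; falls back over classes absent in y."""
    k = probs.shape[1] if n_classes is None else n_classes
    y = np.asarray(labels)
    if k == 2:
        return float(roc_auc_score(y, probs[:, 1]))
    present = np.unique(y)
    aucs = []
    for c in present:
        if 0 < (y == c).sum() < y.size:
            aucs.append(roc_auc_score((y == c).astype(int), probs[:, c]))
    if not aucs:
        raise ValueError("AUC undefined: test split has a single class")
    return float(np.mean(aucs))


def _cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    n = labels.shape[0]
    return float(-np.log(np.clip(probs[np.arange(n), labels], 1e-300, None)).mean())


def evaluate_model(
    model: TrainedVMIB, data: MultimodalDataset, observed: list[str] | None = None
) -> dict:
    """Test-split metrics and information bounds of a trained model."""
    train_set, test_set = data.train_test()
    probs = model.predict_proba(test_set, observed)
    probs_tr = model.predict_proba(train_set, observed)
    h_y = entropy_categorical(empirical_label_distribution(data.labels, model.n_classes))
    return {
        "accuracy": float((probs.argmax(axis=1) == test_set.labels).mean()),
        "auc": macro_ovr_auc(test_set.labels, probs, model.n_classes),
        "compression_bound": model.mean_posterior_kl(test_set, observed),
        "prediction_bound": h_y - _cross_entropy(probs, test_set.labels),
        "prediction_bound_train": h_y - _cross_entropy(probs_tr, train_set.labels),
        "label_entropy": h_y,
    }


def information_plane_sweep(
    data: MultimodalDataset,
    base_config: VMIBConfig,
    lambda_grid: list[float],
) -> list[InfoPlanePoint]:
    """Train one model per lambda (fresh derived seed each) and record bounds."""
    if not lambda_grid or any(l < 0 for l in lambda_grid):
        raise ValueError("lambda grid must be non-empty with values >= 0")
    points = []
    for i, lam in enumerate(sorted(lambda_grid)):
        seed = int(
            np.random.SeedSequence([base_config.seed, 1000 + i]).generate_state(1)[0]
            % (2**31)
        )
        cfg = replace(base_config, lambda_compress=float(lam), seed=seed)
        try:
            model = train_vmib(data, cfg)
        except TrainingError as err:
            raise TrainingError(f"sweep point lambda={lam} failed: {err}") from err
        ev = evaluate_model(model, data)
        points.append(
            InfoPlanePoint(
                lam=float(lam),
                compression_bound=ev["compression_bound"],
                prediction_bound=ev["prediction_bound"],
                prediction_bound_train=ev["prediction_bound_train"],
                accuracy=ev["accuracy"],
                auc=ev["auc"],
                seed=seed,
            )
        )
    return points


def probe_retention(
    model: TrainedVMIB, data: MultimodalDataset, modality_name: str
) -> float:
    """Linear-probe R^2 from latent means back to one modality's features.

    Fit on the train split, score on the test split, average R^2 over
    non-constant feature columns, clamp to [-1, 1].
    """
    if modality_name not in model.modality_names:
        raise KeyError(modality_name)
    train_set, test_set = data.train_test()
    z_tr = model.latent_means(train_set)
    z_te = model.latent_means(test_set)
    x_tr = train_set.modalities[modality_name]
    x_te = test_set.modalities[modality_name]
    keep = x_tr.std(axis=0) > 1e-12
    if not keep.any():
        raise ValueError(f"all features of {modality_name!r} are constant")
    reg = LinearRegression().fit(z_tr, x_tr[:, keep])
    pred = reg.predict(z_te)
    r2 = r2_score(x_te[:, keep], pred, multioutput="uniform_average")
    return float(np.clip(r2, -1.0, 1.0))


def representation_entropy(latents: np.ndarray, ridge: float = 1e-6) -> float:
    """Gaussian-approximation differential entropy of a latent sample, nats.

    H = 0.5 * ln( (2 pi e)^d * det(Cov + ridge I) ); an upper bound on the
    true differential entropy for the fitted mean/covariance.
    """
    z = np.atleast_2d(np.asarray(latents, dtype=float))
    n, d = z.shape
    if n < d + 2:
        raise ValueError(
            f"need at least d+2={d + 2} samples for a {d}-D covariance; "
            "reduce dimension or use ridge-only mode with more samples"
        )
    cov = np.cov(z, rowvar=False).reshape(d, d) + ridge * np.eye(d)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("covariance is not positive definite")
    return float(0.5 * (d * np.log(2 * np.pi * np.e) + logdet))
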