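"""Transfer entropy and sequential prediction on longitudinal records.

Transfer entropy from a source modality X to a target process Y,

    TE_{X->Y} = I( X_{t-k:t-1} ; Y_t | Y_{t-l:t-1} ),

measures the predictive information the source's recent history adds beyond
the target's own past.  Two estimator backends are provided:

* ``classifier`` — for discrete targets, the difference of two classifier
  MI bounds (history+source vs history alone) sharing fold assignments;
* ``linear-gaussian`` — for continuous targets, the residual-variance ratio
  0.5*ln( Var(Y_t | Y_hist) / Var(Y_t | Y_hist, X_hist) ) from two least-
  squares fits, which is the exact conditional MI when the process is
  jointly Gaussian (as in the coupled-AR generator).

The sequential prediction ladder and stage-conditioned discriminability
follow the next-visit protocol: subject-level cross-validation, logistic
regression, modalities added one at a time to the target-history baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .datasets import LongitudinalDataset
from .mi_estimation import ProbeProtocol, classifier_mi_bound

MIN_PAIRS = 30


@dataclass
class TEEstimate:
    """A transfer-entropy estimate (nats); raw value may be slightly negative."""

    source: str
    value: float
    k: int
    ell: int
    estimator: str
    n_pairs: int

    @property
    def flagged_negative(self) -> bool:
        """TE is nonnegative in theory; a negative raw value is estimation noise."""
        return self.value < 0


def _is_discrete(y: np.ndarray) -> bool:
    u = np.unique(y)
    return u.size <= 10 and np.allclose(u, np.round(u))


def estimate_transfer_entropy(
    data: LongitudinalDataset,
    source_modality: str,
    k: int = 1,
    ell: int = 1,
    estimator: str = "auto",
    protocol: ProbeProtocol | None = None,
    seed: int = 0,
) -> TEEstimate:
    """TE from one modality's history to the next target value."""
    if source_modality not in data.modality_columns:
        raise KeyError(source_modality)
    pairs = data.consecutive_pairs([source_modality], k=k, ell=ell)
    if len(pairs) < MIN_PAIRS:
        raise ValueError(f"need >= {MIN_PAIRS} history/target pairs, got {len(pairs)}")
    x_hist = pairs[[f"{source_modality}_lag{j}" for j in range(1, k + 1)]].to_numpy()
    y_hist = pairs[[f"target_lag{j}" for j in range(1, ell + 1)]].to_numpy()
    y = pairs["target_now"].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("constant target: transfer entropy undefined")
    if estimator == "auto":
        estimator = "classifier" if _is_discrete(y) else "linear-gaussian"
    if estimator == "classifier":
        yi = y.astype(int)
        protocol = protocol or ProbeProtocol(n_folds=5, hidden_units=32, max_iter=400)
        skf = StratifiedKFold(protocol.n_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(y_hist, yi))
        full = classifier_mi_bound(
            np.hstack([y_hist, x_hist]), yi, protocol, seed=seed, folds=folds
        )
        base = classifier_mi_bound(y_hist, yi, protocol, seed=seed, folds=folds)
        value = full.value - base.value
    elif estimator == "linear-gaussian":
        v1 = _ols_residual_var(y_hist, y)
        v2 = _ols_residual_var(np.hstack([y_hist, x_hist]), y)
        value = 0.5 * np.log(v1 / max(v2, 1e-300))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return TEEstimate(
        source=source_modality,
        value=float(value),
        k=k,
        ell=ell,
        estimator=estimator,
        n_pairs=len(pairs),
    )


def _ols_residual_var(x: np.ndarray, y: np.ndarray) -> float:
    # dof-corrected residual variance: without the n-p correction the
    # variance ratio acquires an O(k/2n) upward bias from in-sample fitting
    x1 = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(x1, y, rcond=None)
    r = y - x1 @ beta
    dof = max(len(y) - np.linalg.matrix_rank(x1), 1)
    return float(r @ r / dof)


def gaussian_ar_te_closed_form(
    a: float, b: float, sigma_x: float, sigma_y: float, rho: float = 0.0
) -> float:
    """Analytic TE (k = l = 1) for the stationary coupled AR(1) pair.

    Process: X_t = rho*X_{t-1} + N(0, sigma_x^2) and
    Y_t = a*Y_{t-1} + b*X_{t-1} + N(0, sigma_y^2).  From the stationary
    joint covariance,

        TE = 0.5 * ln( Var(Y_t | Y_{t-1}) / Var(Y_t | Y_{t-1}, X_{t-1}) ),

    where the denominator is sigma_y^2.  Invariant under common rescaling of
    both noise scales.
    """
    if not (abs(a) < 1 and abs(rho) < 1):
        raise ValueError("non-stationary parameters: need |a| < 1 and |rho| < 1")
    if sigma_x <= 0 or sigma_y <= 0:
        raise ValueError("noise scales must be positive")
    vx = sigma_x**2 / (1 - rho**2)
    cxy = rho * b * vx / (1 - a * rho)  # Cov(X_t, Y_t) at stationarity
    vy = (b**2 * vx + 2 * a * b * cxy + sigma_y**2) / (1 - a**2)
    cov_y1 = a * vy + b * cxy  # Cov(Y_t, Y_{t-1})
    var_y_given_hist = vy - cov_y1**2 / vy
    return float(0.5 * np.log(var_y_given_hist / sigma_y**2))


def permutation_null_te(
    data: LongitudinalDataset,
    source_modality: str,
    k: int = 1,
    ell: int = 1,
    n_shuffles: int = 20,
    seed: int = 0,
    **kwargs,
) -> np.ndarray:
    """Null TE distribution: source shuffled across time within each subject."""
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_shuffles):
        rec = data.records.copy()
        rec[source_modality] = (
            rec.groupby("subject")[source_modality]
            .transform(lambda v: v.to_numpy()[rng.permutation(len(v))])
        )
        shuffled = LongitudinalDataset(
            rec, data.modality_columns, data.target_column, dict(data.metadata)
        )
        out.append(
            estimate_transfer_entropy(
                shuffled, source_modality, k=k, ell=ell, seed=seed + s, **kwargs
            ).value
        )
    return np.array(out)


@dataclass
class LadderStep:
    features: list[str]
    auc: float
    auc_std: float


def sequential_ladder(
    data: LongitudinalDataset,
    modality_sets: list[str] | None = None,
    n_folds: int = 5,
    ell: int = 1,
    seed: int = 0,
    binarize=None,
) -> list[LadderStep]:
    """Next-visit prediction AUC as modalities join the autoregressive baseline.

    Step 0 uses target history only; each later step adds one modality's
    lagged values.  Folds are split BY SUBJECT (no subject straddles folds);
    the per-step model is a logistic regression.
    """
    modality_sets = modality_sets or data.modality_columns
    pairs = data.consecutive_pairs(modality_sets, k=1, ell=ell)
    binarize = binarize or (lambda y: (np.asarray(y) > 0).astype(int))
    y = binarize(pairs["target_now"].to_numpy())
    if np.unique(y).size < 2:
        raise ValueError("binarized target is constant")
    groups = pairs["subject"].to_numpy()
    base_cols = [f"target_lag{j}" for j in range(1, ell + 1)]
    steps_cols = [list(base_cols)]
    for m in modality_sets:
        steps_cols.append(steps_cols[-1] + [f"{m}_lag1"])
    cv = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(pairs, y, groups))
    out = []
    for cols in steps_cols:
        x = pairs[cols].to_numpy()
        aucs = []
        for tr, te in folds:
            if np.unique(y[te]).size < 2 or np.unique(y[tr]).size < 2:
                continue
            clf = LogisticRegression(max_iter=1000).fit(x[tr], y[tr])
            aucs.append(roc_auc_score(y[te], clf.predict_proba(x[te])[:, 1]))
        if not aucs:
            raise ValueError("no fold had both classes; increase data size")
        out.append(
            LadderStep(
                features=cols,
                auc=float(np.mean(aucs)),
                auc_std=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
            )
        )
    return out


def stage_discriminability(
    data: LongitudinalDataset,
    stage_column: str = "stage",
    binarize=None,
) -> pd.DataFrame:
    """Per current-stage, per-modality single-feature AUC for the next target.

    Within each stratum of the previous visit's stage, each modality's
    previous-visit value is scored as a raw ranking feature against the
    binarized next-visit target (orientation-free: max(AUC, 1-AUC)).
    Strata with a single outcome are marked not-estimable (NaN).
    """
    if stage_column not in data.records.columns:
        raise KeyError(stage_column)
    pairs = data.consecutive_pairs(list(data.modality_columns) + [stage_column], k=1, ell=1)
    binarize = binarize or (lambda y: (np.asarray(y) > 0).astype(int))
    y = binarize(pairs["target_now"].to_numpy())
    rows = []
    for stage, grp in pairs.groupby(f"{stage_column}_lag1"):
        yb = y[grp.index.to_numpy()]
        for m in data.modality_columns:
            feat = grp[f"{m}_lag1"].to_numpy()
            if np.unique(yb).size < 2:
                auc = np.nan
            elif np.std(feat) < 1e-12:
                auc = 0.5
            else:
                a = roc_auc_score(yb, feat)
                auc = max(a, 1.0 - a)
            rows.append({"stage": stage, "modality": m, "auc": auc, "n": len(grp)})
    return pd.DataFrame(rows)
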