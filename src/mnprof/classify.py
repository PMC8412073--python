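"""Healthy/sick subpopulation classifiers and their disease profiles.

Three classifier families are compared for detecting "sick" motor neurons
inside a mixed tissue population:

* **GMM on selected principal components** — label-independent: a 2-component
  Gaussian mixture fitted by EM on 1-3 component scores; tissue-origin labels
  are used only afterwards, to decide which mixture component is "sick".
* **Logistic regression (LR)** — label-dependent, fitted on standardized
  measurements by IRLS with an L2 penalty (intercept unpenalized).
* **Multi-layer perceptron (MLP)** — label-dependent, one hidden layer,
  seeded and bit-reproducible.

Every model outputs a per-cell pair ``(P, S)``: the disease probability
``P in (0, 1)`` and the raw log-odds-scale severity score ``S = logit(P)``
(for the GMM, ``S`` is the sick-vs-healthy weighted log density ratio, whose
logistic transform is exactly the posterior). Two cells can share ``P``
arbitrarily close to 1 yet differ widely in ``S``, which is why severity is
tracked separately from probability.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import multivariate_normal
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.neural_network import MLPClassifier

from .io import FeatureTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Gaussian mixture (label-independent)
# ---------------------------------------------------------------------------

@dataclass
class GmmModel:
    """2-component full-covariance Gaussian mixture on selected PC scores."""

    weights: np.ndarray  # (k,)
    means: np.ndarray  # (k, d)
    covariances: np.ndarray  # (k, d, d)
    loglik_trace: list[float]
    pc_indices: list[int] | None = None  # 0-based columns of the score matrix
    sick_component: int | None = None
    train_assignments: np.ndarray | None = None  # hard labels of training rows
    seed: int = 0


def _kmeanspp_centers(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centers = [x[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            [((x - c) ** 2).sum(axis=1) for c in centers], axis=0
        )
        tot = d2.sum()
        if tot <= 0:
            centers.append(x[rng.integers(n)])
        else:
            centers.append(x[rng.choice(n, p=d2 / tot)])
    return np.asarray(centers)


def _m_step(x: np.ndarray, resp: np.ndarray, reg: float):
    n, d = x.shape
    nk = resp.sum(axis=0) + 1e-12
    w = nk / n
    means = (resp.T @ x) / nk[:, None]
    covs = np.empty((resp.shape[1], d, d))
    for j in range(resp.shape[1]):
        dx = x - means[j]
        covs[j] = (resp[:, j][:, None] * dx).T @ dx / nk[j] + reg * np.eye(d)
    return w, means, covs


def _component_logpdf(x: np.ndarray, w, means, covs) -> np.ndarray:
    """(n, k) matrix of log w_j + log N(x | mu_j, Sigma_j)."""
    cols = [
        np.log(w[j]) + multivariate_normal(means[j], covs[j]).logpdf(x)
        for j in range(len(w))
    ]
    return np.column_stack(cols)


def _em_once(x, k, rng, tol, max_iter, reg):
    centers = _kmeanspp_centers(x, k, rng)
    d2 = ((x[:, None, :] - centers[None]) ** 2).sum(axis=-1)
    resp = np.zeros((x.shape[0], k))
    resp[np.arange(x.shape[0]), d2.argmin(axis=1)] = 1.0
    w, means, covs = _m_step(x, resp, reg)
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        logp = _component_logpdf(x, w, means, covs)
        per_cell = logsumexp(logp, axis=1)
        total = float(per_cell.sum())
        trace.append(total)
        resp = np.exp(logp - per_cell[:, None])
        if total - prev < tol:
            break
        prev = total
        w, means, covs = _m_step(x, resp, reg)
    return total, w, means, covs, resp, trace


def fit_gmm(
    x: np.ndarray,
    k: int = 2,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    reg: float = 1e-6,
    seed: int = 0,
    pc_indices: list[int] | None = None,
) -> GmmModel:
    """EM fit of a k-component mixture, best of ``n_init`` seeded restarts.

    Input is the cells x selected-PCs score matrix (1-D input is treated as a
    single column). A ridge ``reg`` is added to every covariance diagonal;
    the log-likelihood trace of the winning restart is retained.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in GMM input")
    if x.shape[0] < 10:
        raise ValueError("GMM needs at least 10 cells")
    if np.allclose(x, x[0], atol=1e-12):
        raise ValueError("degenerate input: all points identical")
    best = None
    for ss in np.random.SeedSequence(seed).spawn(n_init):
        rng = np.random.default_rng(ss)
        res = _em_once(x, k, rng, tol, max_iter, reg)
        if best is None or res[0] > best[0]:
            best = res
    total, w, means, covs, resp, trace = best
    return GmmModel(
        weights=w,
        means=means,
        covariances=covs,
        loglik_trace=trace,
        pc_indices=list(pc_indices) if pc_indices is not None else None,
        train_assignments=resp.argmax(axis=1),
        seed=seed,
    )


def orient_sick_component(model: GmmModel, conditions) -> GmmModel:
    """Decide which mixture component is the "sick" one.

    The sick component is the one whose hard-assigned training cells contain
    the larger fraction of disease-tissue (non-control) cells; an exact tie
    goes to the smaller-weight component (sick subpopulations are expected to
    be minorities) with a warning. *conditions* is the per-training-row
    condition label, or an annotation frame with a ``condition`` column.
    """
    if model.train_assignments is None:
        raise ValueError("model has no stored training assignments")
    if isinstance(conditions, pd.DataFrame):
        conditions = conditions["condition"]
    cond = np.asarray(conditions)
    if len(cond) != len(model.train_assignments):
        raise ValueError("condition labels not aligned with training rows")
    disease = cond != "control"
    frac = np.zeros(len(model.weights))
    for j in range(len(model.weights)):
        members = model.train_assignments == j
        frac[j] = disease[members].mean() if members.any() else 0.0
    if np.isclose(frac[0], frac[1]):
        sick = int(np.argmin(model.weights))
        warnings.warn(
            "disease-cell occupancy tied between components; "
            "choosing the smaller-weight component as sick",
            stacklevel=2,
        )
    else:
        sick = int(np.argmax(frac))
    return dataclasses.replace(model, sick_component=sick)


# ---------------------------------------------------------------------------
# Logistic regression (IRLS, L2)
# ---------------------------------------------------------------------------

@dataclass
class LrModel:
    coef: np.ndarray  # per standardized measurement
    intercept: float
    l2_strength: float
    feature_names: list[str] | None = None
    trained_conditions: tuple[str, ...] | None = None


def fit_logistic(
    x: np.ndarray,
    y: np.ndarray,
    lam: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-8,
    feature_names: list[str] | None = None,
) -> LrModel:
    """Penalized-likelihood logistic fit by IRLS (Newton with step halving).

    Minimizes -loglik + (lam/2)*||beta||^2 with the intercept unpenalized;
    exits when the gradient norm falls below ``tol``. With ``lam=0`` and
    separable data the optimum diverges and a clear error is raised.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n, p = x.shape
    Xa = np.column_stack([np.ones(n), x])
    pen = lam * np.r_[0.0, np.ones(p)]
    beta = np.zeros(p + 1)

    def penalized_ll(b):
        eta = Xa @ b
        return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * (pen * b * b).sum())

    ll = penalized_ll(beta)
    for _ in range(max_iter):
        eta = Xa @ beta
        mu = expit(eta)
        grad = Xa.T @ (y - mu) - pen * beta
        if np.linalg.norm(grad) < tol:
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (Xa * w[:, None]).T @ Xa + np.diag(pen + 1e-12)
        step = np.linalg.solve(H, grad)
        # step halving keeps the penalized likelihood non-decreasing
        t = 1.0
        while t > 1e-8:
            cand = beta + t * step
            if penalized_ll(cand) >= ll - 1e-12:
                beta, ll = cand, penalized_ll(cand)
                break
            t *= 0.5
        else:
            break
    else:
        raise RuntimeError(
            "IRLS did not converge: with lam=0 and separable data the optimum "
            "is at infinity; use a positive L2 strength"
        )
    if not np.isfinite(beta).all():
        raise RuntimeError("non-finite coefficients in logistic fit")
    return LrModel(
        coef=beta[1:],
        intercept=float(beta[0]),
        l2_strength=lam,
        feature_names=feature_names,
    )


# ---------------------------------------------------------------------------
# Multi-layer perceptron (one hidden layer; scikit-learn backend)
# ---------------------------------------------------------------------------

@dataclass
class MlpModel:
    estimator: MLPClassifier
    hidden: int
    l2_strength: float
    seed: int
    feature_names: list[str] | None = None
    trained_conditions: tuple[str, ...] | None = None

    @property
    def weights(self) -> tuple[np.ndarray, np.ndarray]:
        """(input->hidden matrix (p, h), hidden->output vector (h,))."""
        return self.estimator.coefs_[0], self.estimator.coefs_[1].ravel()


def fit_mlp(
    x: np.ndarray,
    y: np.ndarray,
    hidden: int = 25,
    l2: float = 1e-4,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-7,
    feature_names: list[str] | None = None,
) -> MlpModel:
    """One-hidden-layer perceptron; the same seed and config reproduce the
    same weights bit-for-bit (deterministic L-BFGS training)."""
    if hidden < 1:
        raise ValueError("hidden layer size must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    est = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        alpha=l2,
        solver="lbfgs",
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(x, y.astype(int))
    return MlpModel(
        estimator=est,
        hidden=hidden,
        l2_strength=l2,
        seed=seed,
        feature_names=feature_names,
    )


# ---------------------------------------------------------------------------
# Condition-censored training (sLR / sMLP)
# ---------------------------------------------------------------------------

def fit_censored(
    kind: str, table: FeatureTable, keep_conditions: set[str], **kwargs
) -> LrModel | MlpModel:
    """Fit LR or MLP on the subset of cells whose condition is kept.

    Censoring SOD1-mutant cells (keeping control + vcp) yields the sLR/sMLP
    classifiers that learn the VCP-specific phenotype with the same
    label-dependent machinery. Labels are disease (non-control) vs control
    within the kept rows; it is an error if censoring removes a class.
    """
    if kind not in ("lr", "mlp"):
        raise ValueError(f"kind must be 'lr' or 'mlp', got {kind!r}")
    keep = set(keep_conditions)
    observed = set(table.conditions)
    if not keep <= observed:
        raise ValueError(f"keep_conditions {sorted(keep - observed)} not observed")
    mask = table.conditions.isin(keep).to_numpy()
    y = (table.conditions[mask] != "control").to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("censoring eliminated a class (need control and disease)")
    x = table.values.to_numpy(dtype=float)[mask]
    names = table.measurement_names
    if kind == "lr":
        model = fit_logistic(x, y, feature_names=names, **kwargs)
    else:
        model = fit_mlp(x, y, feature_names=names, **kwargs)
    model.trained_conditions = tuple(sorted(keep))
    return model


# ---------------------------------------------------------------------------
# Disease profiles and ROC
# ---------------------------------------------------------------------------

def _mlp_raw_score(m: MlpModel, x: np.ndarray) -> np.ndarray:
    """Pre-activation of the output unit (log-odds for a logistic output)."""
    est = m.estimator
    h = x
    for W, b in zip(est.coefs_[:-1], est.intercepts_[:-1]):
        h = h @ W + b
        if est.activation == "relu":
            h = np.maximum(h, 0.0)
        elif est.activation == "tanh":
            h = np.tanh(h)
        elif est.activation == "logistic":
            h = expit(h)
        # 'identity' needs no transform
    return (h @ est.coefs_[-1] + est.intercepts_[-1]).ravel()


def predict_profile(model, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell disease probability P and raw severity score S.

    For LR/MLP, S is the pre-link linear predictor / output pre-activation
    and P = logistic(S). For the GMM, S is the sick-vs-healthy weighted log
    density ratio log[pi_s f_s / pi_h f_h]; logistic(S) is identically the
    sick-component posterior, so the same P/S relationship holds. P is
    strictly increasing in S by construction.

    For a GMM fitted with ``pc_indices``, *x* may be the full score matrix
    (columns are sliced) or the already-selected columns.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if isinstance(model, GmmModel):
        d = model.means.shape[1]
        if model.pc_indices is not None and x.shape[1] != d:
            x = x[:, model.pc_indices]
        if x.shape[1] != d:
            raise ValueError(f"expected {d} columns, got {x.shape[1]}")
        if model.sick_component is None:
            raise ValueError(
                "GMM not oriented; call orient_sick_component first"
            )
        logp = _component_logpdf(x, model.weights, model.means, model.covariances)
        sick = model.sick_component
        s = logp[:, sick] - logp[:, 1 - sick]
    elif isinstance(model, LrModel):
        if x.shape[1] != len(model.coef):
            raise ValueError(
                f"expected {len(model.coef)} columns, got {x.shape[1]}"
            )
        s = model.intercept + x @ model.coef
    elif isinstance(model, MlpModel):
        if x.shape[1] != model.estimator.coefs_[0].shape[0]:
            raise ValueError(
                f"expected {model.estimator.coefs_[0].shape[0]} columns, "
                f"got {x.shape[1]}"
            )
        s = _mlp_raw_score(model, x)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    return expit(s), s


def fit_predict_loao(
    kind: str, table: FeatureTable, **kwargs
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-animal-out (P, S) for every cell.

    Each animal's cells are scored by a model trained on all other animals,
    so predictions cannot memorize animal-specific offsets — the honest
    alternative to in-sample scoring when the per-cell calls matter (e.g.
    for re-labeling analyses). Labels are disease (non-control) vs control.
    """
    if kind not in ("lr", "mlp"):
        raise ValueError(f"kind must be 'lr' or 'mlp', got {kind!r}")
    x = table.values.to_numpy(dtype=float)
    y = (table.conditions != "control").to_numpy(dtype=float)
    samples = table.sample_ids.to_numpy()
    P = np.empty(len(y))
    S = np.empty(len(y))
    for sid in pd.unique(samples):
        held = samples == sid
        y_train = y[~held]
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                f"holding out {sid!r} leaves a single class in training"
            )
        if kind == "lr":
            m = fit_logistic(x[~held], y_train, **kwargs)
        else:
            m = fit_mlp(x[~held], y_train, **kwargs)
        P[held], S[held] = predict_profile(m, x[held])
    return P, S


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve and AUC (pairwise concordance probability, ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("ROC needs exactly two classes")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)
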