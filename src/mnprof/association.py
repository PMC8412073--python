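"""Phenotype contrasts and random-intercept mixed-model PC association.

Cells are nested within animals (or human donors), and animals differ
idiosyncratically, so regressing a per-cell response on a phenotype indicator
with ordinary least squares treats n_cells pseudo-replicates as independent
and inflates type-I error. The model used throughout is the random-intercept
linear mixed model

    y_ic = b0 + b1 * x_c + a_s(c) + e_ic,
    a_s ~ N(0, sigma_a^2),  e ~ N(0, sigma_e^2),

fitted by maximum likelihood via 1-D profile optimization over the variance
ratio lambda = sigma_a^2 / sigma_e^2 (for fixed lambda the GLS estimate of
the fixed effects and the ML residual variance are closed-form). The
phenotype effect is tested by a likelihood-ratio chi^2(1) against b1 = 0;
ML (not REML) is used because the nested models differ in fixed effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .spectra import Decomposition, n_components_for

logger = logging.getLogger(__name__)

#: condition -> indicator per contrast scheme.  comALS pools both mutant
#: mouse models against control; vcpALS isolates the dominant VCP-specific
#: phenotype (vcp vs everything else); sALS is the human contrast.
SCHEME_POSITIVE = {
    "comALS": frozenset({"sod1", "vcp"}),
    "vcpALS": frozenset({"vcp"}),
    "sALS": frozenset({"sals"}),
}
SCHEME_CONDITIONS = {
    "comALS": frozenset({"control", "sod1", "vcp"}),
    "vcpALS": frozenset({"control", "sod1", "vcp"}),
    "sALS": frozenset({"control", "sals"}),
}


@dataclass(frozen=True)
class PhenotypeContrast:
    scheme: str
    indicator: np.ndarray  # per-cell 0/1


@dataclass(frozen=True)
class LmmFit:
    """ML fit of the random-intercept model for one response."""

    beta_fixed: np.ndarray  # (intercept, phenotype coefficient)
    sigma_a2: float
    sigma_e2: float
    loglik: float
    p_value: float
    n_groups: int
    ols_fallback: bool = False


@dataclass
class PCAssociation:
    scheme: str
    table: pd.DataFrame  # component, scheme, beta, sigma_a2, sigma_e2, p_value, selected
    fits: list[LmmFit]

    @property
    def selected_components(self) -> list[int]:
        """1-based indices of components passing the significance threshold."""
        return self.table.loc[self.table["selected"], "component"].tolist()


def encode_phenotype(cells: pd.DataFrame, scheme: str) -> PhenotypeContrast:
    """Per-cell 0/1 indicator for a contrast scheme.

    *cells* is an annotation frame with a ``condition`` column. Errors if the
    observed conditions are incompatible with the scheme (e.g. the human sALS
    contrast applied to mouse conditions).
    """
    if scheme not in SCHEME_POSITIVE:
        raise ValueError(f"unknown scheme {scheme!r}; known: {sorted(SCHEME_POSITIVE)}")
    observed = set(cells["condition"])
    allowed = SCHEME_CONDITIONS[scheme]
    if not observed <= allowed:
        raise ValueError(
            f"conditions {sorted(observed - allowed)} incompatible with scheme {scheme!r}"
        )
    positive = SCHEME_POSITIVE[scheme]
    if not observed & positive:
        raise ValueError(f"scheme {scheme!r} references no observed condition")
    if "control" not in observed:
        raise ValueError(f"scheme {scheme!r} needs control cells")
    ind = cells["condition"].isin(positive).to_numpy(dtype=np.int8)
    return PhenotypeContrast(scheme=scheme, indicator=ind)


def _profile_ml(y: np.ndarray, X: np.ndarray, codes: np.ndarray, n_groups: int):
    """Maximize the ML log-likelihood over lambda = sigma_a^2/sigma_e^2 >= 0.

    Uses per-group sufficient statistics; each likelihood evaluation is
    O(n_groups * p^2) via the Woodbury identity for V = I + lambda*J.
    """
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    SX = np.zeros((n_groups, p))
    np.add.at(SX, codes, X)
    sy = np.bincount(codes, weights=y, minlength=n_groups)
    ng = np.bincount(codes, minlength=n_groups).astype(float)

    def loglik(lam: float):
        c = lam / (1.0 + ng * lam)
        A = XtX - (SX * c[:, None]).T @ SX
        b = Xty - SX.T @ (c * sy)
        q = yty - float(np.sum(c * sy**2))
        beta = np.linalg.solve(A, b)
        rss = max(q - float(beta @ b), 1e-300)
        sigma_e2 = rss / n
        ll = (
            -0.5 * n * (np.log(2.0 * np.pi * sigma_e2) + 1.0)
            - 0.5 * float(np.sum(np.log1p(ng * lam)))
        )
        return ll, beta, sigma_e2

    best = (*loglik(0.0), 0.0)  # (ll, beta, sigma_e2, lam)
    if n_groups > 1:
        res = minimize_scalar(
            lambda t: -loglik(np.exp(t))[0],
            bounds=(-15.0, 15.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(np.exp(res.x))
        cand = (*loglik(lam), lam)
        if cand[0] > best[0]:
            best = cand
    return best  # ll, beta, sigma_e2, lam


def fit_random_intercept_lmm(
    y: np.ndarray, x: np.ndarray, groups: np.ndarray | pd.Series
) -> LmmFit:
    """ML fit and likelihood-ratio test of the phenotype coefficient.

    With a single group the random intercept is unidentifiable and the fit
    falls back to ordinary least squares with a warning.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be aligned 1-D vectors")
    if np.ptp(x) == 0:
        raise ValueError("singular design: phenotype indicator is constant")
    codes, uniq = pd.factorize(np.asarray(groups), sort=True)
    n_groups = len(uniq)
    ols_fallback = n_groups < 2
    if ols_fallback:
        warnings.warn(
            "only one group: falling back to ordinary least squares",
            stacklevel=2,
        )
    X = np.column_stack([np.ones_like(y), x])
    X0 = np.ones((len(y), 1))
    llf, beta, se2, lam = _profile_ml(y, X, codes, n_groups)
    ll0 = _profile_ml(y, X0, codes, n_groups)[0]
    lrt = max(0.0, 2.0 * (llf - ll0))
    p = float(chi2.sf(lrt, df=1))
    return LmmFit(
        beta_fixed=np.asarray(beta, dtype=float),
        sigma_a2=float(lam * se2),
        sigma_e2=float(se2),
        loglik=float(llf),
        p_value=p,
        n_groups=n_groups,
        ols_fallback=ols_fallback,
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)


def associate_pcs(
    d: Decomposition,
    contrast: PhenotypeContrast,
    groups: np.ndarray | pd.Series,
    n_pcs: int | None = None,
    alpha: float = 0.05,
    adjust: str = "none",
) -> PCAssociation:
    """Mixed-model association of each leading component score with a contrast.

    ``n_pcs`` defaults to the smallest k capturing 90% of the variance.
    ``adjust`` is ``none`` (per-test alpha, the default) or ``bh``
    (Benjamini-Hochberg across the n_pcs tests).
    """
    if n_pcs is None:
        n_pcs = n_components_for(d, 0.9)
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if n_pcs > d.n_components:
        raise ValueError(f"n_pcs={n_pcs} exceeds {d.n_components} components")
    if adjust not in ("none", "bh"):
        raise ValueError(f"adjust must be 'none' or 'bh', got {adjust!r}")
    fits = [
        fit_random_intercept_lmm(d.scores[:, k], contrast.indicator, groups)
        for k in range(n_pcs)
    ]
    p = np.array([f.p_value for f in fits])
    p_eff = _bh_adjust(p) if adjust == "bh" else p
    table = pd.DataFrame(
        {
            "component": np.arange(1, n_pcs + 1),
            "scheme": contrast.scheme,
            "beta": [f.beta_fixed[1] for f in fits],
            "sigma_a2": [f.sigma_a2 for f in fits],
            "sigma_e2": [f.sigma_e2 for f in fits],
            "p_value": p,
            "p_adjusted": p_eff,
            "selected": p_eff < alpha,
        }
    )
    return PCAssociation(scheme=contrast.scheme, table=table, fits=fits)
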