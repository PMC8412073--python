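"""Standardization, SVD variance spectra and spectrum entropy.

The analysis summarizes a standardized cells x measurements matrix by its
singular value decomposition: per-component explained-variance fractions
``p_i = sigma_i^2 / sum sigma^2`` and the normalized Shannon entropy

    H = -(1 / ln r) * sum_{p_i > 0} p_i ln p_i,   H in [0, 1],

where r is the number of reported components. H near 1 means the variance
(information) is spread over many orthogonal morphological profiles; H near 0
means a single profile dominates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class Decomposition:
    """SVD of a standardized feature table.

    loadings: (measurements x components), orthonormal columns, sign-fixed so
    each column's largest-magnitude entry is positive.
    scores: (cells x components) = data projected on the loadings.
    variance_fraction: p_i, non-increasing, summing to 1.
    entropy: normalized Shannon entropy of the spectrum.
    """

    loadings: np.ndarray
    scores: np.ndarray
    variance_fraction: np.ndarray
    entropy: float
    n_components: int
    measurement_names: list[str]
    centered: bool = True


def standardize(table: FeatureTable) -> FeatureTable:
    """Z-score each measurement column (mean 0, sample sd 1, n-1 denominator).

    Constant columns carry no information on a z-scale and are dropped with a
    logged list; it is an error if every column is constant.
    """
    if table.scaled:
        raise ValueError("table is already standardized")
    if table.n_cells < 2:
        raise ValueError("standardization needs at least 2 cells")
    X = table.values
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all measurement columns are constant")
    dropped = list(X.columns[~keep])
    if dropped:
        logger.warning("dropping %d constant measurement(s): %s", len(dropped), dropped)
    Xk = X.loc[:, keep]
    Z = (Xk - Xk.mean(axis=0)) / sd[keep]
    kept = set(Xk.columns)
    measurements = [m for m in table.measurements if m.name in kept]
    return FeatureTable(Z, measurements, table.cells.copy(), scaled=True)


def decompose(table: FeatureTable, center: bool = True) -> Decomposition:
    """SVD of the (optionally re-centered) standardized matrix.

    Reports r = min(n_cells, n_measurements) components. With ``center=True``
    (default) columns are mean-subtracted before the SVD so that p_i are the
    eigenvalue fractions of the sample covariance matrix; the flag exists
    because deposited datasets may have been decomposed uncentered.
    """
    if not table.scaled:
        raise ValueError("decompose expects a standardized table")
    X = table.values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in feature table")
    if center:
        X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    r = min(X.shape)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("zero total variance; nothing to decompose")
    p = var / total
    loadings = Vt.T
    # deterministic sign: largest-|entry| of each loading column positive
    amax = np.abs(loadings).argmax(axis=0)
    signs = np.sign(loadings[amax, np.arange(r)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    scores = (U * s) * signs
    return Decomposition(
        loadings=loadings,
        scores=scores,
        variance_fraction=p,
        entropy=_spectrum_entropy(p, r),
        n_components=r,
        measurement_names=table.measurement_names,
        centered=center,
    )


def _spectrum_entropy(p: np.ndarray, r: int) -> float:
    if r < 2:
        raise ValueError("spectrum entropy requires at least 2 components")
    p = np.asarray(p, dtype=float)
    pos = p[p > 0]
    h = float(-(pos * np.log(pos)).sum() / np.log(r))
    return float(np.clip(h, 0.0, 1.0))


def variance_entropy(d: Decomposition) -> float:
    """Normalized Shannon entropy of the explained-variance spectrum."""
    return _spectrum_entropy(d.variance_fraction, d.n_components)


def n_components_for(d: Decomposition, frac: float) -> int:
    """Smallest k whose cumulative explained variance reaches *frac*."""
    if not 0.0 < frac <= 1.0:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    cum = np.cumsum(d.variance_fraction)
    k = int(np.searchsorted(cum, frac - 1e-12) + 1)
    return min(k, d.n_components)


def spectrum_summary(d: Decomposition, fracs: tuple[float, ...] = (0.9,)) -> dict:
    """JSON-ready summary of the variance spectrum."""
    cum = np.cumsum(d.variance_fraction)
    out = {
        "n_components": d.n_components,
        "entropy": d.entropy,
        "variance_fraction": d.variance_fraction.tolist(),
        "cumulative": cum.tolist(),
    }
    for f in fracs:
        out[f"k{int(round(100 * f))}"] = n_components_for(d, f)
    return out
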