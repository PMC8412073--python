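"""Per-measurement relative contributions of fitted classifiers.

Each classifier is decomposed into a nonnegative per-measurement
contribution vector c_j summing to 1:

* LR: ``c_j ∝ |beta_j|`` — exact for a linear model on standardized inputs.
* GMM on PCs: the Fisher discriminant direction in PC space,
  ``w = pooled_cov^-1 (mu_sick - mu_healthy)``, mapped back to measurement
  space through the selected loading columns; ``c_j ∝ |(L_sel w)_j|``.
* MLP (one hidden layer): the standard path-weight heuristic
  ``c_j ∝ sum_h |W1_jh * W2_h|``.

Contributions are aggregated by measurement category (area-shape, texture,
intensity) and tested two ways: a random-intercept LMM across classifiers
(classifier = grouping factor) for comALS-vs-vcpALS differences, and a
seeded permutation z-score of the within-category mean against random
category assignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import fit_random_intercept_lmm
from .classify import GmmModel, LrModel, MlpModel
from .io import classify_measurement, is_nc_ratio
from .spectra import Decomposition

logger = logging.getLogger(__name__)


@dataclass
class ContributionProfile:
    classifier_id: str
    contributions: np.ndarray  # c_j >= 0, sum 1
    measurement_names: list[str]
    classifier_group: str | None = None  # "comALS" | "vcpALS"

    def __post_init__(self) -> None:
        c = np.asarray(self.contributions, dtype=float)
        if (c < 0).any():
            raise ValueError("negative contribution")
        if abs(c.sum() - 1.0) > 1e-9:
            raise ValueError("contributions must sum to 1")
        if len(c) != len(self.measurement_names):
            raise ValueError("contribution length != number of measurements")
        self.contributions = c

    def as_series(self) -> pd.Series:
        return pd.Series(self.contributions, index=self.measurement_names)


def _normalize(v: np.ndarray) -> np.ndarray:
    a = np.abs(np.asarray(v, dtype=float))
    s = a.sum()
    if s <= 0:
        raise ValueError("all-zero weights; no contributions defined")
    return a / s


def contributions_lr(
    m: LrModel, classifier_id: str = "lr", classifier_group: str | None = None
) -> ContributionProfile:
    """|beta_j| normalized to 1 (intercept excluded)."""
    if m.feature_names is None:
        raise ValueError("LR model carries no feature names")
    return ContributionProfile(
        classifier_id=classifier_id,
        contributions=_normalize(m.coef),
        measurement_names=list(m.feature_names),
        classifier_group=classifier_group,
    )


def contributions_gmm(
    m: GmmModel,
    d: Decomposition,
    classifier_id: str = "gmm",
    classifier_group: str | None = None,
) -> ContributionProfile:
    """Discriminant direction in PC space, mapped back through the loadings.

    Uses the mixture-weight-pooled covariance for symmetry and stability in
    the 1-3 dimensional PC spaces the GMM classifiers operate in.
    """
    if m.pc_indices is None:
        raise ValueError("GMM model has no pc_indices")
    if max(m.pc_indices) >= d.n_components:
        raise ValueError("pc_indices exceed decomposition components")
    sick = m.sick_component if m.sick_component is not None else 1
    pooled = m.weights[0] * m.covariances[0] + m.weights[1] * m.covariances[1]
    delta = m.means[sick] - m.means[1 - sick]
    try:
        w = np.linalg.solve(pooled, delta)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular pooled covariance: {e}") from e
    L = d.loadings[:, m.pc_indices]
    return ContributionProfile(
        classifier_id=classifier_id,
        contributions=_normalize(L @ w),
        measurement_names=list(d.measurement_names),
        classifier_group=classifier_group,
    )


def contributions_mlp(
    m: MlpModel, classifier_id: str = "mlp", classifier_group: str | None = None
) -> ContributionProfile:
    """Path-weight products summed over hidden units, normalized."""
    if len(m.estimator.coefs_) != 2:
        raise ValueError("contribution decomposition supports one hidden layer only")
    W1, W2 = m.weights
    if m.feature_names is None:
        raise ValueError("MLP model carries no feature names")
    return ContributionProfile(
        classifier_id=classifier_id,
        contributions=_normalize(np.abs(W1) @ np.abs(W2)),
        measurement_names=list(m.feature_names),
        classifier_group=classifier_group,
    )


def top_contributors(p: ContributionProfile, k: int) -> list[tuple[str, float]]:
    """The k largest contributions; ties broken lexicographically by name."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(p.contributions):
        raise ValueError("k exceeds number of measurements")
    order = sorted(
        range(len(p.contributions)),
        key=lambda j: (-p.contributions[j], p.measurement_names[j]),
    )
    return [(p.measurement_names[j], float(p.contributions[j])) for j in order[:k]]


@dataclass(frozen=True)
class CategoryTest:
    category: str
    observed: float  # mean contribution within category
    effect: float | None = None  # LMM group effect
    p_value: float | None = None
    z: float | None = None  # permutation z-score
    n_perm: int | None = None


def category_lmm(
    profiles: list[ContributionProfile], categories: np.ndarray
) -> list[CategoryTest]:
    """Per-category comALS-vs-vcpALS effect on contributions, LMM across
    classifiers (random intercept per classifier).

    *categories* gives the category of each measurement, aligned with every
    profile. Needs >= 2 classifiers per group and >= 2 measurements per
    category.
    """
    categories = np.asarray(categories)
    groups = [p.classifier_group for p in profiles]
    if any(g not in ("comALS", "vcpALS") for g in groups):
        raise ValueError("every profile needs classifier_group comALS or vcpALS")
    for g in ("comALS", "vcpALS"):
        if groups.count(g) < 2:
            raise ValueError(f"need >= 2 classifiers in group {g!r}")
    names = profiles[0].measurement_names
    for p in profiles:
        if p.measurement_names != names:
            raise ValueError("profiles are not over identical measurements")
    out = []
    for cat in pd.unique(categories):
        mask = categories == cat
        if mask.sum() < 2:
            raise ValueError(f"category {cat!r} has fewer than 2 measurements")
        # indicator: comALS = 1, so effect > 0 means comALS-enriched
        y = np.concatenate([p.contributions[mask] for p in profiles])
        x = np.concatenate(
            [np.full(mask.sum(), 1.0 if g == "comALS" else 0.0) for g in groups]
        )
        grp = np.concatenate(
            [np.full(mask.sum(), p.classifier_id) for p in profiles]
        )
        fit = fit_random_intercept_lmm(y, x, grp)
        out.append(
            CategoryTest(
                category=str(cat),
                observed=float(
                    np.mean([p.contributions[mask].mean() for p in profiles])
                ),
                effect=float(fit.beta_fixed[1]),
                p_value=fit.p_value,
            )
        )
    return out


def category_permutation_z(
    p: ContributionProfile,
    categories: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[CategoryTest]:
    """Permutation z-score of each category's mean contribution.

    The null permutes category labels across measurements; since the
    statistic is a within-category mean, this equals drawing random subsets
    of the same size. Seeded and reproducible.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    categories = np.asarray(categories)
    c = p.contributions
    if len(categories) != len(c):
        raise ValueError("categories not aligned with contributions")
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(c, (n_perm, 1)), axis=1)
    out = []
    for cat in pd.unique(categories):
        mask = categories == cat
        if mask.sum() == 0:
            raise ValueError(f"empty category {cat!r}")
        obs = float(c[mask].mean())
        null = perm[:, mask].mean(axis=1)
        sd = float(null.std(ddof=1))
        # guard: a (near-)uniform profile has a degenerate null up to
        # floating-point summation noise
        degenerate = sd <= 1e-12 * max(abs(obs), 1.0 / len(c))
        z = 0.0 if degenerate else (obs - float(null.mean())) / sd
        out.append(CategoryTest(category=str(cat), observed=obs, z=z, n_perm=n_perm))
    return out


def category_tests_frame(tests: list[CategoryTest], **extra) -> pd.DataFrame:
    nan = float("nan")
    rows = [
        {
            "category": t.category,
            "observed": t.observed,
            "effect": nan if t.effect is None else t.effect,
            "p_value": nan if t.p_value is None else t.p_value,
            "z": nan if t.z is None else t.z,
            "n_perm": nan if t.n_perm is None else t.n_perm,
            **extra,
        }
        for t in tests
    ]
    return pd.DataFrame(rows)


def nc_ratio_contribution(p: ContributionProfile, channel: str) -> float:
    """Relative contribution of the single N/C-ratio measurement of *channel*."""
    matches = [
        j
        for j, name in enumerate(p.measurement_names)
        if is_nc_ratio(name) and classify_measurement(name).channel == channel
    ]
    if not matches:
        raise ValueError(f"no N/C-ratio measurement for channel {channel!r}")
    if len(matches) > 1:
        raise ValueError(f"ambiguous N/C-ratio match for channel {channel!r}")
    return float(p.contributions[matches[0]])
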