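"""Seeded synthetic feature tables with known ground truth.

The generator emulates the statistical structure the analysis assumes in
real high-content motor-neuron data, on the standardized scale:

* animals (samples) with random intercept profiles: each sample draws a
  per-measurement offset ``a_sj ~ N(0, sigma_sample^2)`` shared by all its
  cells — an acquisition/staining-batch-like idiosyncrasy that spreads
  animal-level variation across many principal components, as in real data;
* within disease tissue, a mixture of healthy and sick cells
  (``z_c ~ Bernoulli(pi_sick)``); controls may carry a small contamination;
* a dominant condition-specific effect direction (vcp-like) nested with a
  subtle shared disease direction (com-like), on disjoint measurement
  supports: sick cells are shifted along

      x_cj = a_s(c) + z_c * (d_com * e_com_j + 1{vcp} * d_vcp * e_vcp_j)
             + eps_cj,     eps ~ N(0, 1),

  where ``e`` is +-1 on the k affected measurements (so ``d`` is the
  per-affected-measurement shift in sd units; the stored direction ``u`` is
  the unit-norm version, effect vector = d*sqrt(k)*u);
* a measurement-category block structure (area-shape / texture / intensity)
  with CellProfiler-style names: the shared com-like direction loads on
  area-shape measurements plus the SFPQ N/C ratio, the vcp-like direction on
  texture/intensity measurements plus the FUS N/C ratio, mirroring which
  stains mislocalize in which model.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import FeatureTable, classify_measurement

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Default scenario: paper-scale mouse study (3/4/3 animals, ~12 cells
    per animal, 750 measurements split 300/250/200 across categories,
    dominant vcp-like effect over a subtle shared effect)."""

    n_samples: dict = field(
        default_factory=lambda: {"control": 3, "sod1": 4, "vcp": 3}
    )
    cells_per_sample: tuple[float, float] = (12.0, 2.0)  # (mean, dispersion sd)
    n_features: dict = field(
        default_factory=lambda: {"area_shape": 300, "texture": 250, "intensity": 200}
    )
    d_com: float = 0.8  # per-measurement shift (sd units) of shared effect
    d_vcp: float = 2.0  # per-measurement shift of vcp-only effect
    k_com: int = 40
    k_vcp: int = 60
    pi_sick: dict = field(default_factory=lambda: {"sod1": 0.7, "vcp": 0.7})
    pi_sick_control: float = 0.0
    sigma_sample: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if sum(self.n_samples.values()) < 1 or min(self.n_samples.values()) < 0:
            raise ValueError("need at least one sample")
        if sum(self.n_features.values()) < 1:
            raise ValueError("need at least one feature")
        fracs = list(self.pi_sick.values()) + [self.pi_sick_control]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("sick fractions must be in [0, 1]")
        if self.d_com < 0 or self.d_vcp < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.sigma_sample < 0:
            raise ValueError("sigma_sample must be >= 0")
        total = sum(self.n_features.values())
        if self.k_com > total or self.k_vcp > total:
            raise ValueError("effect support exceeds number of features")


@dataclass
class GroundTruth:
    status: pd.Series  # per cell: True = sick
    support_com: list[str]
    support_vcp: list[str]
    u_com: np.ndarray  # unit-norm direction over all measurements
    u_vcp: np.ndarray
    intercepts: dict  # sample_id -> per-measurement offset vector

    @property
    def sick_fraction(self) -> float:
        return float(self.status.mean())


_TEXTURE_STATS = ("Contrast", "Correlation", "Entropy", "Variance", "SumAverage")
_INTENSITY_STATS = ("MeanIntensity", "MedianIntensity", "MaxIntensity", "StdIntensity")
_CHANNELS = ("DAPI", "ChAT", "FUS", "SFPQ")
_COMPARTMENTS = ("Nucleus", "Cytoplasm", "Cell")


def _measurement_names(n_features: dict) -> list[str]:
    names: list[str] = []
    n = n_features.get("area_shape", 0)
    for i in range(n):
        if i % 2 == 0:
            names.append(f"AreaShape_Zernike_{i % 10}_{i % 5}_{_COMPARTMENTS[i % 3]}_{i}")
        else:
            names.append(f"AreaShape_Area_{_COMPARTMENTS[i % 3]}_{i}")
    for i in range(n_features.get("texture", 0)):
        names.append(
            f"Texture_{_TEXTURE_STATS[i % 5]}_{_CHANNELS[i % 4]}_"
            f"{_COMPARTMENTS[i % 3]}_{i}"
        )
    n_int = n_features.get("intensity", 0)
    for i in range(n_int):
        if i == 0 and n_int >= 2:
            names.append("Intensity_NCRatio_SFPQ")
        elif i == 1 and n_int >= 2:
            names.append("Intensity_NCRatio_FUS")
        else:
            names.append(
                f"Intensity_{_INTENSITY_STATS[i % 4]}_{_CHANNELS[i % 4]}_"
                f"{_COMPARTMENTS[i % 3]}_{i}"
            )
    return names


def generate(config: SyntheticConfig) -> tuple[FeatureTable, GroundTruth]:
    """Draw one synthetic study; bit-identical for identical configs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = _measurement_names(config.n_features)
    M = len(names)
    categories = np.array(
        [classify_measurement(n).category.value for n in names]
    )

    # effect supports: com-like on area-shape (+ SFPQ N/C ratio when present),
    # vcp-like on texture/intensity (+ FUS N/C ratio), disjoint.
    def _support(pool: np.ndarray, k: int, forced: list[int]) -> np.ndarray:
        forced = [f for f in forced if f in pool]
        rest = np.setdiff1d(pool, forced)
        k_draw = min(max(k - len(forced), 0), len(rest))
        drawn = rng.choice(rest, size=k_draw, replace=False) if k_draw else []
        return np.sort(np.r_[forced, drawn].astype(int))

    idx_sfpq = names.index("Intensity_NCRatio_SFPQ") if "Intensity_NCRatio_SFPQ" in names else None
    idx_fus = names.index("Intensity_NCRatio_FUS") if "Intensity_NCRatio_FUS" in names else None
    pool_com = np.where(categories == "area_shape")[0]
    if idx_sfpq is not None:
        pool_com = np.r_[pool_com, idx_sfpq]
    pool_vcp = np.where(np.isin(categories, ["texture", "intensity"]))[0]
    pool_vcp = np.setdiff1d(pool_vcp, [i for i in (idx_sfpq,) if i is not None])
    if len(pool_com) == 0:
        pool_com = np.arange(M)
    if len(pool_vcp) == 0:
        pool_vcp = np.arange(M)
    sup_com = _support(pool_com, config.k_com, [idx_sfpq] if idx_sfpq is not None else [])
    sup_vcp = _support(
        np.setdiff1d(pool_vcp, sup_com),
        config.k_vcp,
        [idx_fus] if idx_fus is not None else [],
    )

    def _direction(support: np.ndarray, negative: list[int]) -> np.ndarray:
        u = np.zeros(M)
        signs = rng.choice([-1.0, 1.0], size=len(support))
        u[support] = signs
        for j in negative:
            if j in support:
                u[j] = -1.0  # reduced N/C ratio in disease
        return u / max(np.linalg.norm(u), 1.0)

    u_com = _direction(sup_com, [idx_sfpq] if idx_sfpq is not None else [])
    u_vcp = _direction(sup_vcp, [idx_fus] if idx_fus is not None else [])
    # per-measurement shift d  <=>  effect vector d*sqrt(k)*u
    e_com = config.d_com * np.sqrt(max(len(sup_com), 1)) * u_com
    e_vcp = config.d_vcp * np.sqrt(max(len(sup_vcp), 1)) * u_vcp

    rows, cell_ids, sample_ids, conditions, status = [], [], [], [], []
    intercepts: dict[str, float] = {}
    mean_c, disp_c = config.cells_per_sample
    i_cell = 0
    for cond in ("control", "sod1", "vcp", "sals"):
        for s in range(config.n_samples.get(cond, 0)):
            sid = f"{cond}_{s + 1}"
            a_s = rng.normal(0.0, config.sigma_sample, size=M)
            intercepts[sid] = a_s
            n_cells = max(2, int(round(rng.normal(mean_c, disp_c))))
            pi = (
                config.pi_sick_control
                if cond == "control"
                else config.pi_sick.get(cond, 0.0)
            )
            for _ in range(n_cells):
                z = bool(rng.random() < pi)
                x = a_s + rng.standard_normal(M)
                if z:
                    x = x + e_com
                    if cond == "vcp":
                        x = x + e_vcp
                rows.append(x)
                cell_ids.append(f"cell_{i_cell:04d}")
                sample_ids.append(sid)
                conditions.append(cond)
                status.append(z)
                i_cell += 1
    if not rows:
        raise ValueError("configuration yields zero cells")

    values = pd.DataFrame(np.asarray(rows), index=cell_ids, columns=names)
    cells = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": conditions,
            "stain_panel": "SFPQ|FUS",
        },
        index=cell_ids,
    )
    measurements = [classify_measurement(n) for n in names]
    table = FeatureTable(values, measurements, cells, scaled=False)
    truth = GroundTruth(
        status=pd.Series(status, index=cell_ids, name="sick"),
        support_com=[names[j] for j in sup_com],
        support_vcp=[names[j] for j in sup_vcp],
        u_com=u_com,
        u_vcp=u_vcp,
        intercepts=intercepts,
    )
    return table, truth


def recovery_report(
    profile: pd.DataFrame,
    truth: GroundTruth,
    threshold: float = 0.5,
    contributions=None,
) -> dict:
    """Compare classifier output against ground truth.

    Returns cell-status accuracy, |estimated - true| sick fraction, and — if
    a :class:`ContributionProfile` is supplied — the fraction of contribution
    mass on each true effect support.
    """
    pred = profile.set_index("cell_id")["P"].reindex(truth.status.index)
    if pred.isna().any():
        raise ValueError("profile does not cover every ground-truth cell")
    sick_pred = pred.to_numpy() > threshold
    sick_true = truth.status.to_numpy()
    out = {
        "accuracy": float((sick_pred == sick_true).mean()),
        "sick_fraction_error": float(
            abs(sick_pred.mean() - sick_true.mean())
        ),
    }
    if contributions is not None:
        c = contributions.as_series()
        out["contribution_mass_com"] = float(
            c.reindex(truth.support_com).fillna(0.0).sum()
        )
        out["contribution_mass_vcp"] = float(
            c.reindex(truth.support_vcp).fillna(0.0).sum()
        )
    return out


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["cells_per_sample"] = list(d["cells_per_sample"])
    return d
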