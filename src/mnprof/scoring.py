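"""Per-animal disease scoring, group tests and the re-labeling analysis.

Per-cell disease profiles (P, S) are aggregated per animal/donor into the
mean disease probability, mean severity and percentage of sick cells
(P above a threshold, default 0.5). Groups of animals are compared with
Welch's unequal-variance t test at the animal level, never at the cell
level — cells from the same animal are not independent replicates.

The re-labeling analysis quantifies the central claim that classifier-based
healthy/sick labels have a better signal-to-noise ratio than tissue-origin
labels: a marker measurement (e.g. an N/C intensity ratio) is tested between
groups twice, once grouped by tissue origin and once grouped by the
classifier's sick/healthy call, and the two p-values are compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable

logger = logging.getLogger(__name__)


def make_profile(
    cell_ids,
    classifier_id: str,
    P: np.ndarray,
    S: np.ndarray,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Assemble a per-cell disease-profile frame (one row per cell)."""
    P = np.asarray(P, dtype=float)
    S = np.asarray(S, dtype=float)
    if not ((P > 0) & (P < 1)).all():
        P = np.clip(P, 1e-12, 1 - 1e-12)
    return pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "classifier_id": classifier_id,
            "P": P,
            "S": S,
            "sick": P > threshold,
        }
    )


def aggregate_samples(
    profile: pd.DataFrame, cells: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-animal scores: unweighted mean P, mean S, % sick cells, n_cells.

    *cells* is the annotation frame indexed by cell id; every profiled cell
    must be annotated. Returns one row per (classifier_id, sample_id).
    """
    missing = set(profile["cell_id"]) - set(cells.index)
    if missing:
        raise ValueError(f"profiled cells without annotation: {sorted(missing)[:5]}")
    df = profile.merge(
        cells[["sample_id", "condition"]],
        left_on="cell_id",
        right_index=True,
        how="left",
    )
    df["sick"] = df["P"] > threshold
    out = (
        df.groupby(["classifier_id", "sample_id"], sort=True)
        .agg(
            condition=("condition", "first"),
            mean_P=("P", "mean"),
            mean_S=("S", "mean"),
            pct_sick=("sick", lambda s: 100.0 * s.mean()),
            n_cells=("P", "size"),
        )
        .reset_index()
    )
    if (out["n_cells"] == 0).any():
        raise ValueError("sample with zero cells")
    return out


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t: float
    df: float
    p_value: float


def welch_test(a, b, labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Two-sided Welch unequal-variance t test with Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch test needs at least 2 observations per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in Welch test input")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        # degenerate: no within-group variability
        same = np.isclose(a.mean(), b.mean())
        t = 0.0 if same else np.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if same else 0.0
        df = float(len(a) + len(b) - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return GroupComparison(
        group_a=labels[0],
        group_b=labels[1],
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=len(a),
        n_b=len(b),
        t=t,
        df=df,
        p_value=p,
    )


def compare_to_control(
    scores: pd.DataFrame, metric: str = "mean_P", control: str = "control"
) -> list[GroupComparison]:
    """Welch tests of each non-control condition vs control on a per-animal
    metric (``mean_P``, ``mean_S`` or ``pct_sick``).

    *scores* is the output of :func:`aggregate_samples` for one classifier.
    """
    if metric not in ("mean_P", "mean_S", "pct_sick"):
        raise ValueError(f"unknown metric {metric!r}")
    if "classifier_id" in scores.columns and scores["classifier_id"].nunique() > 1:
        raise ValueError("scores contain several classifiers; filter to one first")
    ctrl = scores.loc[scores["condition"] == control, metric].to_numpy()
    if len(ctrl) < 2:
        raise ValueError(f"need >= 2 {control!r} samples, found {len(ctrl)}")
    out = []
    for cond in sorted(set(scores["condition"]) - {control}):
        vals = scores.loc[scores["condition"] == cond, metric].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"need >= 2 {cond!r} samples, found {len(vals)}")
        out.append(welch_test(vals, ctrl, labels=(cond, control)))
    return out


def comparisons_frame(comps: list[GroupComparison], **extra) -> pd.DataFrame:
    rows = [
        {
            "group": c.group_a,
            "reference": c.group_b,
            "mean_group": c.mean_a,
            "mean_reference": c.mean_b,
            "t": c.t,
            "df": c.df,
            "p_value": c.p_value,
            **extra,
        }
        for c in comps
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RelabelResult:
    p_origin: float
    p_relabel: float
    n_origin: tuple[int, int]  # (disease-origin, control-origin)
    n_relabel: tuple[int, int]  # (sick, healthy)


def relabel_and_retest(
    table: FeatureTable,
    measurement: str | int,
    profile: pd.DataFrame,
    threshold: float = 0.5,
) -> RelabelResult:
    """Welch-test one measurement under tissue-origin vs classifier labels.

    ``p_origin`` groups cells by condition (disease vs control tissue);
    ``p_relabel`` groups the same cells by the classifier's sick/healthy call
    (P above/below *threshold*). When disease tissue contains healthy cells,
    re-labeling removes that contamination and p_relabel is expected to drop
    below p_origin.
    """
    col = (
        table.values.columns[measurement]
        if isinstance(measurement, (int, np.integer))
        else measurement
    )
    if col not in table.values.columns:
        raise KeyError(f"no measurement named {col!r}")
    values = table.values[col]
    disease = (table.conditions != "control").to_numpy()
    sick_by_cell = pd.Series(
        (profile["P"] > threshold).to_numpy(), index=profile["cell_id"]
    )
    sick = sick_by_cell.reindex(table.values.index)
    if sick.isna().any():
        raise ValueError("profile does not cover every cell in the table")
    sick = sick.to_numpy(dtype=bool)
    if sick.all() or (~sick).all():
        raise ValueError("classifier assigned all cells to one class")
    p_origin = welch_test(
        values[disease], values[~disease], labels=("disease", "control")
    ).p_value
    p_relabel = welch_test(
        values[sick], values[~sick], labels=("sick", "healthy")
    ).p_value
    return RelabelResult(
        p_origin=p_origin,
        p_relabel=p_relabel,
        n_origin=(int(disease.sum()), int((~disease).sum())),
        n_relabel=(int(sick.sum()), int((~sick).sum())),
    )
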