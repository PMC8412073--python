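"""Config-driven end-to-end orchestration of the disease-profiling analysis.

Stages (in order): data (simulate or ingest) -> standardize -> decompose ->
associate -> train -> score -> contribute -> cluster. Every stage writes its
tables under the output directory and the run ends with a manifest echoing
the seed and every tunable, so a run is reproducible and resumable from its
serialized artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import associate_pcs, encode_phenotype
from .classify import (
    fit_censored,
    fit_gmm,
    fit_logistic,
    fit_mlp,
    orient_sick_component,
    predict_profile,
    roc_auc,
)
from .cluster import cluster_composition, cut_k, hclust_average
from .contributions import (
    category_lmm,
    category_permutation_z,
    category_tests_frame,
    contributions_gmm,
    contributions_lr,
    contributions_mlp,
    top_contributors,
)
from .io import FeatureTable, read_feature_table, write_feature_table
from .scoring import (
    aggregate_samples,
    compare_to_control,
    comparisons_frame,
    make_profile,
)
from .simulate import SyntheticConfig, config_to_dict, generate
from .spectra import decompose, n_components_for, spectrum_summary, standardize

logger = logging.getLogger(__name__)

VALID_KINDS = {"gmm", "lr", "mlp"}

DEFAULT_CLASSIFIERS = [
    {"name": "lr", "kind": "lr", "group": "comALS"},
    {"name": "mlp", "kind": "mlp", "group": "comALS"},
    {"name": "gmm_com", "kind": "gmm", "scheme": "comALS", "group": "comALS"},
    {"name": "slr", "kind": "lr", "censor": ["sod1"], "group": "vcpALS"},
    {"name": "smlp", "kind": "mlp", "censor": ["sod1"], "group": "vcpALS"},
    {"name": "gmm_vcp", "kind": "gmm", "scheme": "vcpALS", "group": "vcpALS"},
]


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage name."""


@dataclass
class RunConfig:
    """Validated pipeline configuration; every tunable is echoed to the
    run manifest."""

    outdir: str | Path = "mnprof_run"
    seed: int = 0
    simulate: dict | None = None  # SyntheticConfig overrides; None -> ingest
    values_path: str | None = None
    annotations_path: str | None = None
    dialect: str = "cellprofiler"
    schemes: list[str] = field(default_factory=lambda: ["comALS", "vcpALS"])
    classifiers: list[dict] = field(
        default_factory=lambda: [dict(c) for c in DEFAULT_CLASSIFIERS]
    )
    alpha: float = 0.05
    sick_threshold: float = 0.5
    variance_fraction: float = 0.9
    lr_l2: float = 1.0
    mlp_hidden: int = 25
    mlp_l2: float = 1e-4
    n_perm: int = 10_000

    def validate(self) -> None:
        if self.simulate is None and not (self.values_path and self.annotations_path):
            raise ValueError("config needs either a simulate block or input paths")
        names = [c.get("name") for c in self.classifiers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate classifier names")
        for c in self.classifiers:
            kind = c.get("kind")
            if kind not in VALID_KINDS:
                raise ValueError(
                    f"unknown classifier kind {kind!r} (valid: {sorted(VALID_KINDS)})"
                )
            if c.get("group") not in ("comALS", "vcpALS"):
                raise ValueError(f"classifier {c.get('name')!r} needs a group")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.variance_fraction <= 1:
            raise ValueError("variance_fraction must be in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _select_pcs(associations: dict, scheme: str, n_max: int = 2) -> list[int]:
    """0-based score columns for a GMM classifier of the given scheme.

    vcpALS takes its own significant components; comALS takes its significant
    components minus those claimed by vcpALS (the shared-phenotype components
    are the ones *not* explained by the dominant vcp-specific signal). Falls
    back to the scheme's smallest-p component when nothing is significant.
    """
    tab = associations[scheme].table
    sel = tab.loc[tab["selected"]].sort_values("p_value")
    picked = sel["component"].tolist()
    if scheme == "comALS" and "vcpALS" in associations:
        vtab = associations["vcpALS"].table.set_index("component")
        vsel = set(vtab.index[vtab["selected"]])
        filtered = [c for c in picked if c not in vsel]
        if filtered:
            picked = filtered
        # most com-specific first: weakest vcpALS association wins
        picked.sort(key=lambda c: -float(vtab.loc[c, "p_value"]))
    if not picked:
        picked = [int(tab.sort_values("p_value")["component"].iloc[0])]
    return [int(c) - 1 for c in picked[:n_max]]


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute every stage, write all artifacts, return the results bundle."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stages_done: list[str] = []

    def stage(name):
        def deco(fn):
            try:
                fn()
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage {name!r}: {e}") from e
            stages_done.append(name)

        return deco

    @stage("data")
    def _data():
        if config.simulate is not None:
            sim = dict(config.simulate)
            sim.setdefault("seed", config.seed)
            if "cells_per_sample" in sim:
                sim["cells_per_sample"] = tuple(sim["cells_per_sample"])
            scfg = SyntheticConfig(**sim)
            table, truth = generate(scfg)
            truth.status.to_frame().to_csv(outdir / "truth.csv", index_label="cell_id")
            with open(outdir / "simulate_config.json", "w") as fh:
                json.dump(config_to_dict(scfg), fh, indent=1)
            results["truth"] = truth
        else:
            table = read_feature_table(
                config.values_path, config.annotations_path, config.dialect
            )
        write_feature_table(
            table,
            outdir / "measurements.csv",
            outdir / "annotations.csv",
            outdir / "schema.json",
        )
        results["table"] = table

    @stage("standardize")
    def _standardize():
        results["scaled"] = standardize(results["table"])

    @stage("decompose")
    def _decompose():
        d = decompose(results["scaled"])
        results["decomposition"] = d
        with open(outdir / "spectrum.json", "w") as fh:
            json.dump(spectrum_summary(d, (config.variance_fraction,)), fh)
        pd.DataFrame(
            d.scores,
            index=results["scaled"].values.index,
            columns=[f"PC{i + 1}" for i in range(d.n_components)],
        ).to_csv(outdir / "scores.csv", index_label="cell_id")
        pd.DataFrame(
            d.loadings,
            index=d.measurement_names,
            columns=[f"PC{i + 1}" for i in range(d.n_components)],
        ).to_csv(outdir / "loadings.csv", index_label="measurement")

    @stage("associate")
    def _associate():
        d = results["decomposition"]
        scaled = results["scaled"]
        n_pcs = n_components_for(d, config.variance_fraction)
        assoc = {}
        for scheme in config.schemes:
            contrast = encode_phenotype(scaled.cells, scheme)
            assoc[scheme] = associate_pcs(
                d, contrast, scaled.sample_ids.to_numpy(), n_pcs=n_pcs,
                alpha=config.alpha,
            )
        results["associations"] = assoc
        pd.concat([a.table for a in assoc.values()]).to_csv(
            outdir / "associations.csv", index=False
        )

    @stage("train")
    def _train():
        scaled = results["scaled"]
        d = results["decomposition"]
        x = scaled.values.to_numpy(dtype=float)
        y = (scaled.conditions != "control").to_numpy(dtype=float)
        models, profiles, aucs, meta = {}, [], {}, {}
        for i_clf, spec in enumerate(config.classifiers):
            name, kind = spec["name"], spec["kind"]
            # independent deterministic stream per classifier: models must
            # not share initialization noise
            clf_seed = int(
                np.random.SeedSequence([config.seed, i_clf]).generate_state(1)[0]
                % (2**31)
            )
            if kind == "gmm":
                pcs = spec.get("pcs")
                if pcs is not None:
                    pcs = [int(p) - 1 for p in pcs]  # user-facing PCs are 1-based
                else:
                    pcs = _select_pcs(results["associations"], spec["scheme"])
                m = fit_gmm(d.scores[:, pcs], seed=clf_seed, pc_indices=pcs)
                m = orient_sick_component(m, scaled.conditions)
                P, S = predict_profile(m, d.scores)
                meta[name] = {"kind": kind, "pcs": [p + 1 for p in pcs]}
            elif spec.get("censor"):
                keep = set(scaled.conditions) - set(spec["censor"])
                m = fit_censored(
                    kind,
                    scaled,
                    keep,
                    **(
                        {"lam": config.lr_l2}
                        if kind == "lr"
                        else {
                            "hidden": config.mlp_hidden,
                            "l2": config.mlp_l2,
                            "seed": clf_seed,
                        }
                    ),
                )
                P, S = predict_profile(m, x)
                meta[name] = {"kind": kind, "censor": spec["censor"]}
            elif kind == "lr":
                m = fit_logistic(
                    x, y, lam=config.lr_l2,
                    feature_names=scaled.measurement_names,
                )
                P, S = predict_profile(m, x)
                meta[name] = {"kind": kind, "l2": config.lr_l2}
            else:
                m = fit_mlp(
                    x, y, hidden=config.mlp_hidden, l2=config.mlp_l2,
                    seed=clf_seed, feature_names=scaled.measurement_names,
                )
                P, S = predict_profile(m, x)
                meta[name] = {
                    "kind": kind,
                    "hidden": config.mlp_hidden,
                    "l2": config.mlp_l2,
                }
            models[name] = m
            profiles.append(
                make_profile(
                    scaled.values.index, name, P, S, config.sick_threshold
                )
            )
            aucs[name] = roc_auc(S, y).auc
        results["models"] = models
        results["model_meta"] = meta
        results["profiles"] = pd.concat(profiles, ignore_index=True)
        results["aucs"] = aucs
        results["profiles"].to_csv(outdir / "predictions.csv", index=False)
        with open(outdir / "models.json", "w") as fh:
            json.dump({"auc": aucs, "meta": meta, "seed": config.seed}, fh, indent=1)

    @stage("score")
    def _score():
        scaled = results["scaled"]
        scores = aggregate_samples(
            results["profiles"], scaled.cells, config.sick_threshold
        )
        results["sample_scores"] = scores
        scores.to_csv(outdir / "sample_scores.csv", index=False)
        frames = []
        for name in scores["classifier_id"].unique():
            sub = scores[scores["classifier_id"] == name]
            for metric in ("mean_P", "mean_S", "pct_sick"):
                comps = compare_to_control(sub, metric=metric)
                frames.append(
                    comparisons_frame(comps, classifier_id=name, metric=metric)
                )
        results["comparisons"] = pd.concat(frames, ignore_index=True)
        results["comparisons"].to_csv(outdir / "comparisons.csv", index=False)

    @stage("contribute")
    def _contribute():
        scaled = results["scaled"]
        d = results["decomposition"]
        cats = scaled.categories()
        profs = []
        for spec in config.classifiers:
            name, kind = spec["name"], spec["kind"]
            m = results["models"][name]
            group = spec["group"]
            if kind == "gmm":
                profs.append(contributions_gmm(m, d, name, group))
            elif kind == "lr":
                profs.append(contributions_lr(m, name, group))
            else:
                profs.append(contributions_mlp(m, name, group))
        results["contributions"] = profs
        mat = pd.DataFrame(
            {p.classifier_id: p.contributions for p in profs},
            index=profs[0].measurement_names,
        ).T
        mat.to_csv(outdir / "contributions.csv", index_label="classifier_id")
        lmm_tests = category_lmm(profs, cats)
        perm_frames = [
            category_tests_frame(
                category_permutation_z(
                    p, cats, n_perm=config.n_perm, seed=config.seed
                ),
                classifier_id=p.classifier_id,
                test="permutation",
            )
            for p in profs
        ]
        tests = pd.concat(
            [category_tests_frame(lmm_tests, test="lmm")] + perm_frames,
            ignore_index=True,
        )
        results["category_tests"] = tests
        tests.to_csv(outdir / "category_tests.csv", index=False)
        topk = {p.classifier_id: top_contributors(p, 5) for p in profs}
        results["top_contributors"] = topk
        with open(outdir / "top_contributors.json", "w") as fh:
            json.dump(topk, fh, indent=1)

    @stage("cluster")
    def _cluster():
        scaled = results["scaled"]
        dend = hclust_average(
            scaled.values.to_numpy(dtype=float), list(scaled.values.index)
        )
        labels = cut_k(dend, 2)
        counts, fractions = cluster_composition(labels, scaled.cells)
        results["cell_clusters"] = {
            "dendrogram": dend,
            "labels": labels,
            "counts": counts,
            "fractions": fractions,
        }
        pd.DataFrame(
            {"cell_id": scaled.values.index, "cluster": labels}
        ).to_csv(outdir / "cell_clusters.csv", index=False)
        counts.to_csv(outdir / "cell_cluster_composition.csv")
        profs = results["contributions"]
        cmat = np.vstack([p.contributions for p in profs])
        cdend = hclust_average(cmat, [p.classifier_id for p in profs])
        clabels = cut_k(cdend, 2)
        results["classifier_clusters"] = {
            "dendrogram": cdend,
            "labels": dict(zip([p.classifier_id for p in profs], clabels)),
        }
        pd.DataFrame(
            {
                "classifier_id": [p.classifier_id for p in profs],
                "group": [p.classifier_group for p in profs],
                "cluster": clabels,
            }
        ).to_csv(outdir / "classifier_clusters.csv", index=False)

    manifest = {
        "package": "mnprof",
        "version": __version__,
        "seed": config.seed,
        "stages": stages_done,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    results["manifest"] = manifest
    return results
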