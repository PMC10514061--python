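"""Configuration and orchestration of the three study-level experiments.

* **Preservation** — are the dynamical features (event peaks, FCD,
  metastability, modularity, complexity) preserved when the signals are
  embedded into the latent space?
* **Acute classification** — can FC / irreversibility features, in
  source or latent space, separate controls from patients and low- from
  high-lesion patients at the acute stage?
* **Recovery prediction** — do the longitudinal outcome metrics move in
  the recovery direction, and can acute features predict median-split
  recovery labels?

A single :class:`PipelineConfig` carries every stage's parameters and a
global seed that fans out deterministically; each report embeds the full
config for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify, edges, features, irreversibility, latent, outcomes
from .signals import concatenate_for_training, zscore_rows
from .synthetic import Cohort, CohortParams, generate_cohort

__all__ = [
    "PipelineConfig",
    "run_preservation_experiment",
    "run_classification_experiment",
    "run_recovery_experiment",
]

log = logging.getLogger("latentflow")


@dataclass
class PipelineConfig:
    cohort: CohortParams = field(default_factory=CohortParams)
    seed: int = 0
    # embedding
    d_range: tuple = (2, 3, 4, 5, 6, 7, 8)
    d_selected: int = 6
    batch: int = 256
    max_epochs: int = 100
    patience: int = 10
    learning_rate: float = 1e-3
    correlation_threshold: float = 0.9
    # event detection
    peak_p: float = 0.001
    peak_z_max: float = 4.5
    null_iter: int = 200
    # dynamical features
    fcd_window: int = 30
    fcd_step: int = 3
    gamma_grid: tuple = tuple(np.round(np.arange(0.0, 0.3001, 0.025), 3))
    louvain_restarts: int = 5
    complexity_bins: int = 20
    dt: int = 1
    # classification
    n_trees: int = 1000
    n_repeats: int = 10
    train_frac: float = 0.8
    # output
    outdir: str | None = None

    def train_config(self) -> latent.TrainConfig:
        return latent.TrainConfig(batch=self.batch, max_epochs=self.max_epochs,
                                  patience=self.patience,
                                  learning_rate=self.learning_rate)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["d_range"] = list(self.d_range)
        d["gamma_grid"] = list(self.gamma_grid)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in data:
            data["cohort"] = CohortParams.from_dict(data["cohort"])
        for key in ("d_range", "gamma_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @classmethod
    def desk(cls, **over) -> "PipelineConfig":
        return cls(**over)

    @classmethod
    def full_scale(cls, **over) -> "PipelineConfig":
        over.setdefault("cohort", CohortParams(n_roi=235, n_frames=896,
                                               n_controls=27, n_patients=96))
        return cls(**over)


def _cohort_and_model(config: PipelineConfig, d: int | None = None):
    cohort = generate_cohort(config.cohort, seed=config.seed)
    frames, index_map = concatenate_for_training(cohort, "2wk")
    model = latent.train_autoencoder(frames, d or config.d_selected,
                                     config.train_config(), seed=config.seed)
    return cohort, frames, index_map, model


def _modularity_with_fallback(fc: np.ndarray, config: PipelineConfig):
    """Bipartition sweep with the constrained-search fallback enabled."""
    return features.modularity_signed(
        fc, np.asarray(config.gamma_grid),
        n_restarts=config.louvain_restarts, seed=config.seed,
        on_missing="constrained")


def _subject_features(cohort: Cohort, model, config: PipelineConfig):
    """Per-subject feature rows in both spaces (acute series)."""
    rows = []
    for rec in cohort.records:
        tp = "control" if rec.group == "control" else "2wk"
        src = zscore_rows(cohort.get_series(rec.subject_id, tp))
        lat = zscore_rows(latent.encode(model, src))
        for space, series in (("source", src), ("latent", lat)):
            e = edges.edge_time_series(series)
            fc = edges.full_fc(series)
            part = _modularity_with_fallback(fc, config)
            fcd = features.fcd_matrix(series, config.fcd_window, config.fcd_step)
            rows.append({
                "subject_id": rec.subject_id,
                "group": rec.group,
                "space": space,
                "fcd_mean": float(features.fcd_distribution(fcd).mean()),
                "metastability": features.edge_metastability(e),
                "modularity_q": part.q,
                "complexity": features.functional_complexity(
                    fc, config.complexity_bins),
                "mean_irreversibility": irreversibility.mean_irreversibility(
                    irreversibility.irreversibility_matrix(series, config.dt)),
            })
    import pandas as pd

    return pd.DataFrame(rows)


def run_preservation_experiment(config: PipelineConfig | None = None) -> dict:
    """Feature-preservation experiment: agreement curve + 4 feature contrasts."""
    config = config or PipelineConfig()
    log.info("preservation: generating cohort (seed=%d)", config.seed)
    cohort = generate_cohort(config.cohort, seed=config.seed)
    frames, _ = concatenate_for_training(cohort, "2wk")

    models = {}
    for d in config.d_range:
        log.info("preservation: training autoencoder d=%d", d)
        models[d] = latent.train_autoencoder(frames, d, config.train_config(),
                                             seed=config.seed)
    curve = edges.agreement_curve(cohort, models, n_iter=config.null_iter,
                                  p=config.peak_p, z_max=config.peak_z_max,
                                  seed=config.seed)
    sel = config.d_selected if config.d_selected in models else max(models)
    table = _subject_features(cohort, models[sel], config)

    comparisons = {}
    for space in ("source", "latent"):
        sub = table[table.space == space]
        ctrl = sub[sub.group == "control"]
        pat = sub[sub.group == "patient"]
        for feat in ("fcd_mean", "metastability", "modularity_q", "complexity"):
            t, df, p = classify.group_compare(ctrl[feat], pat[feat])
            comparisons[f"{feat}_{space}"] = {
                "control_mean": float(ctrl[feat].mean()),
                "patient_mean": float(pat[feat].mean()),
                "t": t, "df": df, "p": p,
            }
    report = {
        "config": config.to_dict(),
        "agreement_curve": {
            "dims": curve["dims"],
            "mean_agreement": curve["mean_agreement"],
            "paired_tests": curve["paired_tests"],
        },
        "feature_comparisons": comparisons,
        "feature_table": table.to_dict(orient="records"),
    }
    _maybe_write(config, "preservation", report, tables={"features": table})
    return report


def run_classification_experiment(config: PipelineConfig | None = None) -> dict:
    """Acute-stage classification: 4 feature configs x 2 label schemes."""
    config = config or PipelineConfig()
    cohort, frames, _, model = _cohort_and_model(config)

    group_labels = np.array([1 if r.group == "patient" else 0
                             for r in cohort.records])
    patients = cohort.patients()
    lesion_labels = outcomes.median_split([r.lesion_volume for r in patients])

    auc_rows = []
    for space in ("source", "latent"):
        for metric in ("fc", "irreversibility"):
            feats = classify.build_features(
                cohort, space, metric, "upper_triangle", model, dt=config.dt)
            feats.labels = group_labels
            rep = classify.rf_classify(feats, config.n_trees, config.n_repeats,
                                       config.train_frac, config.seed,
                                       label_spec="group")
            auc_rows.append(rep)
            pf = classify.build_features(
                cohort, space, metric, "upper_triangle", model,
                subjects=patients, dt=config.dt)
            pf.labels = lesion_labels
            rep = classify.rf_classify(pf, config.n_trees, config.n_repeats,
                                       config.train_frac, config.seed,
                                       label_spec="lesion_volume")
            auc_rows.append(rep)

    feats_latent = classify.build_features(cohort, "latent", "fc",
                                           "upper_triangle", model)
    coords = classify.tsne_project(feats_latent, seed=config.seed)
    behavior = classify.behavior_correlations(cohort, model, "recovery",
                                              dt=config.dt)

    report = {
        "config": config.to_dict(),
        "auc_table": [{
            "space": r.space, "metric": r.metric, "labels": r.label_spec,
            "auc_mean": r.auc_mean, "auc_sd": r.auc_sd,
        } for r in auc_rows],
        "tsne": coords.tolist(),
        "behavior_correlations": behavior.to_dict(orient="records"),
    }
    _maybe_write(config, "classification", report, tables={"behavior": behavior})
    return report


def run_recovery_experiment(config: PipelineConfig | None = None) -> dict:
    """Recovery prediction: trajectories + 4 feature configs x 3 criteria."""
    config = config or PipelineConfig()
    for tp in ("2wk", "1yr"):
        if tp not in config.cohort.timepoints:
            raise ValueError(f"recovery experiment needs timepoint {tp}")
    cohort, frames, _, model = _cohort_and_model(config)
    table = outcomes.outcome_table(cohort)

    trajectories = {
        "fc_distance": {tp: float(table[f"fc_distance_{tp}"].mean())
                        for tp in config.cohort.timepoints},
        "sc_fc": {tp: float(table[f"sc_fc_{tp}"].mean())
                  for tp in config.cohort.timepoints},
    }

    patients = cohort.patients()
    criteria = {
        "behavior": table["label_behavior"].to_numpy(),
        "fc_distance": table["label_fc_distance"].to_numpy(),
        "sc_fc": table["label_sc_fc"].to_numpy(),
    }
    auc_rows = []
    for space in ("source", "latent"):
        for metric in ("fc", "irreversibility"):
            feats = classify.build_features(cohort, space, metric,
                                            "upper_triangle", model,
                                            subjects=patients, dt=config.dt)
            for name, labels in criteria.items():
                ft = classify.FeatureTable(feats.x, feats.subject_ids,
                                           np.asarray(labels), space, metric,
                                           "upper_triangle")
                rep = classify.rf_classify(ft, config.n_trees,
                                           config.n_repeats,
                                           config.train_frac, config.seed,
                                           label_spec=name)
                auc_rows.append(rep)

    agreement = {}
    names = list(criteria)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            agreement[f"{a}|{b}"] = outcomes.cohen_kappa(criteria[a], criteria[b])

    report = {
        "config": config.to_dict(),
        "trajectories": trajectories,
        "label_agreement_kappa": agreement,
        "auc_table": [{
            "space": r.space, "metric": r.metric, "criterion": r.label_spec,
            "auc_mean": r.auc_mean, "auc_sd": r.auc_sd,
        } for r in auc_rows],
        "outcome_table": table.reset_index().to_dict(orient="records"),
    }
    _maybe_write(config, "recovery", report, tables={"outcomes": table})
    return report


def _maybe_write(config: PipelineConfig, name: str, report: dict,
                 tables: dict | None = None) -> None:
    if not config.outdir:
        return
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / f"{name}.json").write_text(json.dumps(report, indent=2,
                                                    default=_json_default))
    for tname, frame in (tables or {}).items():
        frame.to_csv(outdir / f"{name}_{tname}.tsv", sep="\t")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
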