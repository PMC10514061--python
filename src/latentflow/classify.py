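"""Feature construction, random-forest classification and projections.

Subjects are represented by either their FC matrix or their
irreversibility matrix, in source or latent space, summarized as the
vectorized upper triangle (the classifier input), its mean, or its SD.
Classification uses random forests (1000 trees) with repeated stratified
80/20 subject-level splits and reports the held-out ROC AUC mean +- SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .edges import full_fc
from .irreversibility import irreversibility_matrix, mean_irreversibility
from .latent import Autoencoder, encode
from .signals import SubjectSeries, zscore_rows
from .synthetic import BEHAVIOR_DOMAINS, Cohort

__all__ = [
    "FeatureTable",
    "ClassificationReport",
    "subject_matrix",
    "build_features",
    "rf_classify",
    "behavior_correlations",
    "tsne_project",
    "group_compare",
]

SPACES = ("source", "latent")
METRICS = ("fc", "irreversibility")
SUMMARIES = ("upper_triangle", "mean", "sd")


@dataclass
class FeatureTable:
    x: np.ndarray                   # (n_subjects, n_features)
    subject_ids: list
    labels: np.ndarray | None
    space: str
    metric: str
    summary: str
    label_spec: str = ""

    @property
    def n_subjects(self) -> int:
        return self.x.shape[0]


@dataclass
class ClassificationReport:
    auc_mean: float
    auc_sd: float
    aucs: np.ndarray
    n_trees: int
    n_repeats: int
    train_frac: float
    seed: int
    space: str = ""
    metric: str = ""
    label_spec: str = ""

    def summary(self) -> str:
        tag = f"{self.space}/{self.metric}" if self.space else "features"
        return (f"{tag} vs {self.label_spec or 'labels'}: "
                f"AUC = {self.auc_mean:.3f} +- {self.auc_sd:.3f} "
                f"({self.n_repeats} x {round((1 - self.train_frac) * 100)}% "
                f"held-out splits, {self.n_trees} trees)")


def subject_matrix(series: SubjectSeries, metric: str, dt: int = 1) -> np.ndarray:
    """FC or irreversibility matrix of one (z-scored) series."""
    z = zscore_rows(series)
    if metric == "fc":
        return full_fc(z)
    if metric == "irreversibility":
        return irreversibility_matrix(z, dt=dt).data
    raise ValueError(f"unknown metric {metric!r}")


def _summarize(matrix: np.ndarray, summary: str) -> np.ndarray:
    iu = np.triu_indices(matrix.shape[0], k=1)
    tri = matrix[iu]
    if summary == "upper_triangle":
        return tri
    if summary == "mean":
        return np.array([tri.mean()])
    if summary == "sd":
        return np.array([tri.std()])
    raise ValueError(f"unknown summary {summary!r}")


def build_features(cohort: Cohort, space: str = "source", metric: str = "fc",
                   summary: str = "upper_triangle",
                   latent_model: Autoencoder | None = None,
                   timepoint: str = "2wk", subjects=None, labels=None,
                   dt: int = 1) -> FeatureTable:
    """Per-subject feature vectors from the chosen matrix and summary.

    Controls contribute their ``control`` series, patients the series at
    ``timepoint``; latent features encode the z-scored series through the
    trained model first.
    """
    if space not in SPACES or metric not in METRICS or summary not in SUMMARIES:
        raise ValueError("invalid feature spec")
    if space == "latent" and latent_model is None:
        raise ValueError("latent features require a trained latent model")
    records = subjects if subjects is not None else cohort.records
    missing = [
        r.subject_id for r in records
        if (r.subject_id, "control" if r.group == "control" else timepoint)
        not in cohort.series
    ]
    if missing:
        raise ValueError(f"missing series for subjects: {missing}")
    rows, ids = [], []
    for rec in records:
        tp = "control" if rec.group == "control" else timepoint
        series = cohort.get_series(rec.subject_id, tp)
        if space == "latent":
            series = encode(latent_model, zscore_rows(series))
        rows.append(_summarize(subject_matrix(series, metric, dt), summary))
        ids.append(rec.subject_id)
    x = np.vstack(rows)
    labels = None if labels is None else np.asarray(labels)
    return FeatureTable(x, ids, labels, space, metric, summary)


def rf_classify(features: FeatureTable, n_trees: int = 1000,
                n_repeats: int = 10, train_frac: float = 0.8,
                seed: int = 0, label_spec: str = "") -> ClassificationReport:
    """Random-forest AUC over repeated stratified subject-level splits."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedShuffleSplit

    if features.labels is None:
        raise ValueError("feature table carries no labels")
    y = np.asarray(features.labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need exactly 2 classes with at least 2 members each")

    splitter = StratifiedShuffleSplit(n_splits=n_repeats,
                                      train_size=train_frac,
                                      random_state=seed)
    aucs = []
    for rep, (tr, te) in enumerate(splitter.split(features.x, y)):
        forest = RandomForestClassifier(n_estimators=n_trees,
                                        random_state=seed + rep, n_jobs=1)
        forest.fit(features.x[tr], y[tr])
        scores = forest.predict_proba(features.x[te])[:, 1]
        aucs.append(roc_auc_score(y[te], scores))
    aucs = np.array(aucs)
    return ClassificationReport(float(aucs.mean()), float(aucs.std()),
                                aucs, n_trees, n_repeats, train_frac, seed,
                                features.space, features.metric,
                                label_spec or features.label_spec)


def behavior_correlations(cohort: Cohort, latent_model: Autoencoder,
                          target: str = "recovery", dt: int = 1) -> pd.DataFrame:
    """Pearson correlations of scalar metrics with behavioral domains.

    Four scalar metrics per patient (mean FC and mean irreversibility,
    each in source and latent space, from the acute series) are related
    to each of the nine domains' recovery scores (``target="recovery"``)
    or acute scores (``target="acute"``).  Returns a tidy frame with one
    row per (metric, domain) plus an ``is_argmax`` flag marking, for each
    domain, the metric with the largest |r|.
    """
    from .outcomes import behavioral_recovery

    if target not in ("recovery", "acute"):
        raise ValueError("target must be 'recovery' or 'acute'")
    patients = cohort.patients()
    if len(patients) < 4:
        raise ValueError("need at least 4 patients")

    metric_values = {f"{s}_{m}": [] for s in SPACES for m in METRICS}
    domain_values = {d: [] for d in BEHAVIOR_DOMAINS}
    for rec in patients:
        series = zscore_rows(cohort.get_series(rec.subject_id, "2wk"))
        lat = encode(latent_model, series)
        for space, s in (("source", series), ("latent", lat)):
            fc = full_fc(s)
            ir = irreversibility_matrix(zscore_rows(s) if space == "latent" else s,
                                        dt=dt)
            iu = np.triu_indices(fc.shape[0], k=1)
            metric_values[f"{space}_fc"].append(fc[iu].mean())
            metric_values[f"{space}_irreversibility"].append(
                mean_irreversibility(ir))
        for d in BEHAVIOR_DOMAINS:
            if target == "recovery":
                domain_values[d].append(behavioral_recovery(
                    rec.behavior["2wk"][d], rec.behavior["1yr"][d]))
            else:
                domain_values[d].append(rec.behavior["2wk"][d])

    rows = []
    for metric, mv in metric_values.items():
        mv = np.asarray(mv)
        for d, dv in domain_values.items():
            dv = np.asarray(dv)
            ok = np.isfinite(dv) & np.isfinite(mv)
            if ok.sum() < 4 or np.std(dv[ok]) == 0 or np.std(mv[ok]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(mv[ok], dv[ok])
            rows.append({"metric": metric, "domain": d,
                         "r": float(r), "p": float(p)})
    table = pd.DataFrame(rows)
    table["is_argmax"] = False
    for d in BEHAVIOR_DOMAINS:
        sub = table[table.domain == d]
        if sub.r.abs().notna().any():
            idx = sub.r.abs().idxmax()
            table.loc[idx, "is_argmax"] = True
    return table


def tsne_project(features: FeatureTable, seed: int = 0,
                 perplexity: float | None = None) -> np.ndarray:
    """2-D t-SNE coordinates of the subjects, deterministic under seed."""
    from sklearn.manifold import TSNE

    n = features.n_subjects
    if n < 5:
        raise ValueError("need at least 5 subjects for a projection")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                init="pca")
    return tsne.fit_transform(features.x)


def group_compare(values_a, values_b):
    """Welch two-sample t-test: returns (t, df, p)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
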