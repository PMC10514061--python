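"""Recovery-related outcome metrics and split-label construction.

Three complementary views of a patient's functional recovery:

* **FC distance** — Frobenius norm of the difference between the
  subject's FC at a timepoint and the average FC of the healthy
  controls; shrinks as the FC normalizes.
* **SC-FC coupling** — Pearson correlation between the subject's FC and
  the structural-connectome template, restricted to structurally
  connected pairs; rises as function re-aligns with structure.
* **Behavioral recovery** — relative change of each of nine z-scored
  behavioral domain scores between 2 weeks and 1 year, and the count of
  domains whose deficit magnitude decreased.

Each view can be median-split into high/low-recovery labels, the three
binary criteria used by the recovery classifiers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .edges import full_fc
from .signals import zscore_rows
from .synthetic import BEHAVIOR_DOMAINS, Cohort, SubjectRecord

__all__ = [
    "fc_distance",
    "mean_deficit_change",
    "reference_fc",
    "sc_fc_coupling",
    "behavioral_recovery",
    "domains_recovered",
    "median_split",
    "outcome_table",
    "cohen_kappa",
]


def fc_distance(fc_subject: np.ndarray, fc_reference: np.ndarray) -> float:
    """Frobenius norm of the difference between two FC matrices."""
    a = np.asarray(fc_subject, float)
    b = np.asarray(fc_reference, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b, "fro"))


def reference_fc(cohort: Cohort, group: str = "control") -> np.ndarray:
    """Elementwise mean FC over the subjects of one group."""
    members = [r for r in cohort.records if r.group == group]
    if not members:
        raise ValueError(f"no subjects in group {group!r}")
    tp = "control" if group == "control" else "2wk"
    mats = [full_fc(cohort.get_series(r.subject_id, tp)) for r in members]
    return np.mean(mats, axis=0)


def sc_fc_coupling(fc: np.ndarray, sc: np.ndarray) -> float:
    """Pearson r between FC and SC over structurally connected pairs."""
    fc = np.asarray(fc, float)
    sc = np.asarray(sc, float)
    if fc.shape != sc.shape:
        raise ValueError(f"shape mismatch: {fc.shape} vs {sc.shape}")
    iu = np.triu_indices(fc.shape[0], k=1)
    mask = sc[iu] > 0
    sc_vals = sc[iu][mask]
    fc_vals = fc[iu][mask]
    if sc_vals.size < 2 or np.unique(sc_vals).size < 2:
        raise ValueError("degenerate SC mask: fewer than 2 distinct positive values")
    return float(np.corrcoef(fc_vals, sc_vals)[0, 1])


def behavioral_recovery(score_2wk: float, score_1yr: float) -> float:
    """Relative change (1yr - 2wk) / 2wk; NaN when the baseline is zero.

    Scores here are z-scored deficits (controls center on 0, impairment
    is negative), so a negative baseline moving toward 0 yields a
    *negative* relative change; interpret magnitudes per domain sign.
    """
    if score_2wk == 0.0:
        return float("nan")
    return (score_1yr - score_2wk) / score_2wk


def domains_recovered(record: SubjectRecord, margin: float = 0.0,
                      resolved_threshold: float = 0.75) -> int:
    """Count domains recovered after one year.

    A domain counts as recovered when the z-scored deficit both shrank
    (|score_1yr| < |score_2wk| - margin) and returned to the normal range
    (|score_1yr| <= resolved_threshold, default 1.5 control SDs).  Mere
    improvement without resolution — a severe deficit becoming a moderate
    one — does not count; pass ``resolved_threshold=numpy.inf`` for the
    any-improvement variant.
    """
    beh = record.behavior
    if "2wk" not in beh or "1yr" not in beh:
        raise ValueError(f"subject {record.subject_id} lacks 2wk or 1yr behavior")
    count = 0
    for d in BEHAVIOR_DOMAINS:
        a2, a1 = abs(beh["2wk"][d]), abs(beh["1yr"][d])
        if a1 < a2 - margin and a1 <= resolved_threshold:
            count += 1
    return count


def mean_deficit_change(record: SubjectRecord) -> float:
    """Mean change in deficit magnitude over the nine domains.

    (|score_1yr| - |score_2wk|) averaged over domains: negative values
    mean deficits shrank.  A robust per-subject recovery aggregate — the
    per-domain relative change is unstable for near-zero baselines.
    """
    beh = record.behavior
    return float(np.mean([abs(beh["1yr"][d]) - abs(beh["2wk"][d])
                          for d in BEHAVIOR_DOMAINS]))


def median_split(values) -> np.ndarray:
    """Binary high/low labels at the sample median (1 = high).

    Values above the median are high, below are low; values exactly at
    the median are assigned in stable input order to whichever side is
    currently smaller (low first on ties), so counts differ by at most 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for a median split")
    if np.unique(values).size == 1:
        raise ValueError("all values identical: median split undefined")
    med = float(np.median(values))
    labels = np.full(values.size, -1, dtype=int)
    labels[values > med] = 1
    labels[values < med] = 0
    n_low = int(np.sum(labels == 0))
    n_high = int(np.sum(labels == 1))
    for idx in np.where(labels == -1)[0]:
        if n_low <= n_high:
            labels[idx] = 0
            n_low += 1
        else:
            labels[idx] = 1
            n_high += 1
    assert abs(int(np.sum(labels == 0)) - int(np.sum(labels == 1))) <= 1
    return labels


def outcome_table(cohort: Cohort, margin: float = 0.0) -> pd.DataFrame:
    """Per-patient outcome metrics and the three recovery split labels.

    Columns: fc_distance/sc_fc per timepoint, per-domain behavioral
    recovery, domains_recovered, and binary labels label_behavior,
    label_fc_distance (low distance at 1yr = high recovery) and
    label_sc_fc (high coupling at 1yr = high recovery).
    """
    ref = reference_fc(cohort, "control")
    rows = []
    for rec in cohort.patients():
        row: dict = {"subject_id": rec.subject_id}
        for tp in cohort.params.timepoints:
            fc = full_fc(cohort.get_series(rec.subject_id, tp))
            row[f"fc_distance_{tp}"] = fc_distance(fc, ref)
            row[f"sc_fc_{tp}"] = sc_fc_coupling(fc, cohort.sc_template)
        for d in BEHAVIOR_DOMAINS:
            row[f"recovery_{d}"] = behavioral_recovery(
                rec.behavior["2wk"][d], rec.behavior["1yr"][d])
        row["domains_recovered"] = domains_recovered(rec, margin)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("subject_id")
    table["label_behavior"] = median_split(table["domains_recovered"])
    # low residual FC distance at the remote stage = good recovery
    table["label_fc_distance"] = 1 - median_split(table["fc_distance_1yr"])
    table["label_sc_fc"] = median_split(table["sc_fc_1yr"])
    return table


def cohen_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two binary labelings."""
    from sklearn.metrics import cohen_kappa_score

    return float(cohen_kappa_score(labels_a, labels_b))
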