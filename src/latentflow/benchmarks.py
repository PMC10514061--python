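"""Planted-contrast benchmark: the headline property of the pipeline.

Patients in the synthetic cohorts receive severity-scaled homotopic
down-weighting (lowering modularity) and a severity-scaled antisymmetric
coupling perturbation (raising temporal irreversibility).  The benchmark
regenerates several cohorts, measures both group contrasts in source
space, and races the latent-irreversibility classifier against the
source-FC classifier on the control-vs-patient task — the ordering the
method was designed to produce.
"""

from __future__ import annotations

import numpy as np

from . import classify, edges, features, irreversibility, latent, outcomes
from .pipeline import PipelineConfig, _modularity_with_fallback
from .signals import concatenate_for_training, zscore_rows
from .synthetic import generate_cohort

__all__ = ["planted_contrast_benchmark", "recovery_direction_benchmark"]


def planted_contrast_benchmark(n_cohorts: int = 10, seed: int = 0,
                               config: PipelineConfig | None = None) -> dict:
    """Group contrasts and classifier ranking over independent cohorts.

    Returns per-cohort modularity/irreversibility means and AUCs, pooled
    Welch tests across cohorts, and the fraction of cohorts in which the
    latent-irreversibility AUC is at least the source-FC AUC.
    """
    config = config or PipelineConfig()
    rng = np.random.SeedSequence(seed)
    cohort_seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1))
                    for s in rng.spawn(n_cohorts)]

    mod_ctrl, mod_pat = [], []
    irr_ctrl, irr_pat = [], []
    per_cohort = []
    for cs in cohort_seeds:
        cohort = generate_cohort(config.cohort, seed=cs)
        frames, _ = concatenate_for_training(cohort, "2wk")
        model = latent.train_autoencoder(frames, config.d_selected,
                                         config.train_config(), seed=cs)

        c_mod, p_mod, c_irr, p_irr = [], [], [], []
        for rec in cohort.records:
            tp = "control" if rec.group == "control" else "2wk"
            series = zscore_rows(cohort.get_series(rec.subject_id, tp))
            fc = edges.full_fc(series)
            q = _modularity_with_fallback(fc, config).q
            mi = irreversibility.mean_irreversibility(
                irreversibility.irreversibility_matrix(series, config.dt))
            (c_mod if rec.group == "control" else p_mod).append(q)
            (c_irr if rec.group == "control" else p_irr).append(mi)
        mod_ctrl += c_mod
        mod_pat += p_mod
        irr_ctrl += c_irr
        irr_pat += p_irr

        labels = np.array([1 if r.group == "patient" else 0
                           for r in cohort.records])
        feats = classify.build_features(cohort, "latent", "irreversibility",
                                        "upper_triangle", model, dt=config.dt)
        feats.labels = labels
        auc_lat_irr = classify.rf_classify(
            feats, config.n_trees, config.n_repeats, config.train_frac,
            seed=cs).auc_mean
        feats = classify.build_features(cohort, "source", "fc",
                                        "upper_triangle", model)
        feats.labels = labels
        auc_src_fc = classify.rf_classify(
            feats, config.n_trees, config.n_repeats, config.train_frac,
            seed=cs).auc_mean
        per_cohort.append({
            "seed": cs,
            "modularity_control": float(np.mean(c_mod)),
            "modularity_patient": float(np.mean(p_mod)),
            "irreversibility_control": float(np.mean(c_irr)),
            "irreversibility_patient": float(np.mean(p_irr)),
            "auc_latent_irreversibility": auc_lat_irr,
            "auc_source_fc": auc_src_fc,
        })

    t_mod, _, p_mod_test = classify.group_compare(mod_ctrl, mod_pat)
    t_irr, _, p_irr_test = classify.group_compare(irr_ctrl, irr_pat)
    wins = sum(c["auc_latent_irreversibility"] >= c["auc_source_fc"]
               for c in per_cohort)
    return {
        "per_cohort": per_cohort,
        "modularity_control_mean": float(np.mean(mod_ctrl)),
        "modularity_patient_mean": float(np.mean(mod_pat)),
        "modularity_t": t_mod, "modularity_p": p_mod_test,
        "irreversibility_control_mean": float(np.mean(irr_ctrl)),
        "irreversibility_patient_mean": float(np.mean(irr_pat)),
        "irreversibility_t": t_irr, "irreversibility_p": p_irr_test,
        "latent_irr_wins": int(wins),
        "n_cohorts": n_cohorts,
        "auc_latent_irr_mean": float(np.mean(
            [c["auc_latent_irreversibility"] for c in per_cohort])),
        "auc_source_fc_mean": float(np.mean(
            [c["auc_source_fc"] for c in per_cohort])),
    }


def recovery_direction_benchmark(n_cohorts: int = 5, seed: int = 0,
                                 config: PipelineConfig | None = None) -> dict:
    """Longitudinal directions and split-label agreement, pooled over cohorts.

    Label agreement between the three median-split criteria is tested by
    pooling patients across cohorts: Cohen's kappa plus a one-sided
    binomial test of the match count against the 50% chance level.
    """
    from scipy import stats

    config = config or PipelineConfig()
    rng = np.random.SeedSequence(seed)
    cohort_seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1))
                    for s in rng.spawn(n_cohorts)]

    fc2, fc1, sc2, sc1 = [], [], [], []
    pooled = {"behavior": [], "fc_distance": [], "sc_fc": []}
    imbalance = []
    for cs in cohort_seeds:
        cohort = generate_cohort(config.cohort, seed=cs)
        table = outcomes.outcome_table(cohort)
        fc2.append(table["fc_distance_2wk"].mean())
        fc1.append(table["fc_distance_1yr"].mean())
        sc2.append(table["sc_fc_2wk"].mean())
        sc1.append(table["sc_fc_1yr"].mean())
        crits = {
            "behavior": table["label_behavior"].to_numpy(),
            "fc_distance": table["label_fc_distance"].to_numpy(),
            "sc_fc": table["label_sc_fc"].to_numpy(),
        }
        imbalance.append({n: abs(int(v.sum()) - int((1 - v).sum()))
                          for n, v in crits.items()})
        for n, v in crits.items():
            pooled[n].append(v)
    pooled = {n: np.concatenate(v) for n, v in pooled.items()}

    agreement = {}
    names = list(pooled)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            la, lb = pooled[a], pooled[b]
            matches = int(np.sum(la == lb))
            p = stats.binomtest(matches, la.size, 0.5,
                                alternative="greater").pvalue
            agreement[f"{a}|{b}"] = {
                "kappa": outcomes.cohen_kappa(la, lb),
                "matches": matches, "n": int(la.size), "p": float(p),
            }
    return {
        "fc_distance_2wk": float(np.mean(fc2)),
        "fc_distance_1yr": float(np.mean(fc1)),
        "sc_fc_2wk": float(np.mean(sc2)),
        "sc_fc_1yr": float(np.mean(sc1)),
        "max_label_imbalance": max(max(d.values()) for d in imbalance),
        "agreement": agreement,
        "n_cohorts": n_cohorts,
    }
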