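"""Synthetic stroke-like cohort generator.

Every downstream stage of the package (edge events, latent embedding,
dynamical features, irreversibility, classification, recovery prediction)
is exercised on cohorts produced here, because the clinical cohort the
method was designed for is not publicly downloadable.

The generative model is a stationary first-order vector autoregression
(VAR(1)) per subject,

    x(t+1) = W x(t) + eps,   eps ~ N(0, noise_sd^2 I),

whose coefficient matrix ``W`` carries the three abnormality axes the
analyses are meant to detect:

* **modular block structure** — within-module weights exceed
  between-module weights, and homotopic (mirror) region pairs are coupled
  across hemispheres;
* **interhemispheric lesioning** — patient couplings have homotopic
  weights scaled down in proportion to a latent severity in [0, 1], plus a
  small set of "lesioned" regions whose rows/columns are damped;
* **temporal asymmetry** — an antisymmetric perturbation of the coupling
  grows with severity, driving the signal away from detailed balance so
  that time-reversal irreversibility increases with disease severity.

Severity decays exponentially over the follow-up timepoints, producing
longitudinal recovery in the clinical covariates (lesion volume, NIHSS,
nine behavioral domain scores) and in the simulated signals alike.

Discrete VAR(1) frames were chosen over a continuous-time
Ornstein-Uhlenbeck process: BOLD-like data are TR-sampled, and the lag-1
structure that the irreversibility statistic measures is analytically
controllable through the antisymmetric part of ``W``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signals import SubjectSeries, read_series, write_series

__all__ = [
    "CouplingMatrix",
    "SubjectRecord",
    "Cohort",
    "CohortParams",
    "build_coupling",
    "lesion_coupling",
    "simulate_series",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "variance_stable",
]

TIMEPOINT_YEARS = {"2wk": 2.0 / 52.0, "3mo": 0.25, "1yr": 1.0}
BEHAVIOR_DOMAINS = (
    "language", "motor_l", "motor_r", "att_vf", "att_avg",
    "att_val_dis", "memory_v", "memory_s", "motor_ic",
)


@dataclass
class CouplingMatrix:
    """Directed VAR(1) coefficient matrix with module/hemisphere labels."""

    weights: np.ndarray
    module_assignment: np.ndarray
    hemisphere_assignment: np.ndarray  # 0 = left, 1 = right
    target_radius: float

    @property
    def n_roi(self) -> int:
        return self.weights.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.weights))))

    def homotopic_pairs(self) -> np.ndarray:
        """Mirror pairs (i, i + n_roi/2), shape (n_roi/2, 2)."""
        half = self.n_roi // 2
        return np.column_stack([np.arange(half), np.arange(half) + half])


@dataclass
class SubjectRecord:
    subject_id: str
    group: str                      # "control" | "patient"
    severity: float                 # latent severity in [0, 1]; 0 for controls
    recovery_rate: float            # exponential decay rate of severity, 1/year
    lesion_volume: int              # number of damped ROIs
    nihss: int
    behavior: dict                  # timepoint -> {domain: score}

    def severity_at(self, timepoint: str) -> float:
        if self.group == "control":
            return 0.0
        tau = TIMEPOINT_YEARS[timepoint]
        return self.severity * float(np.exp(-self.recovery_rate * tau))


@dataclass
class Cohort:
    records: list
    series: dict                    # (subject_id, timepoint) -> SubjectSeries
    sc_template: np.ndarray
    rng_seed: int
    params: "CohortParams"

    @property
    def n_roi(self) -> int:
        return self.sc_template.shape[0]

    def controls(self):
        return [r for r in self.records if r.group == "control"]

    def patients(self):
        return [r for r in self.records if r.group == "patient"]

    def get_series(self, subject_id: str, timepoint: str) -> SubjectSeries:
        return self.series[(subject_id, timepoint)]


@dataclass
class CohortParams:
    """Desk-scale defaults; the full-scale study design (235 ROIs, 896
    frames, TR = 2 s) is reachable by overriding ``n_roi``/``n_frames``."""

    n_controls: int = 30
    n_patients: int = 60
    n_roi: int = 50
    n_frames: int = 400
    tr: float = 2.0
    timepoints: tuple = ("2wk", "3mo", "1yr")
    # coupling topology
    n_modules: int = 2
    within_w: float = 0.30
    between_w: float = -0.05
    homotopic_w: float = 0.30
    asymmetry: float = 0.02
    target_radius: float = 0.98
    # inter-subject heterogeneity: iid coupling jitter (symmetric +
    # antisymmetric parts), as a fraction of the off-diagonal RMS weight
    subject_jitter: float = 1.0
    # lesion model: lesion_frac scales the lesion-volume covariate,
    # lesion_damp_frac the (smaller) count of ROIs actually damped
    k_homotopic: float = 0.2
    k_asym: float = 0.15
    lesion_frac: float = 0.15
    lesion_damp_frac: float = 0.03
    # simulation
    noise_sd: float = 1.0
    burn_in: int = 100
    # clinical covariates
    nihss_scale: float = 20.0
    behavior_noise_sd: float = 0.5

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["timepoints"] = list(self.timepoints)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortParams":
        d = dict(d)
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown cohort parameters: {sorted(unknown)}")
        return cls(**d)


def _spectral_radius(w: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(w))))


def build_coupling(n_roi: int, n_modules: int = 2, within_w: float = 0.25,
                   between_w: float = 0.02, homotopic_w: float = 0.20,
                   asymmetry: float = 0.0, target_radius: float = 0.9,
                   seed: int = 0) -> CouplingMatrix:
    """Build a block-structured VAR(1) coupling with planted modules.

    ROIs 0..n/2-1 form the left hemisphere, n/2..n-1 the right; ROI ``i``
    and ``i + n/2`` are homotopic mirrors and share a module, so modules
    span both hemispheres.  Off-diagonal weights are ``within_w`` inside a
    module and ``between_w`` across modules; homotopic pairs are overridden
    to ``homotopic_w``.  An antisymmetric Gaussian perturbation of scale
    ``asymmetry`` is added to the off-diagonal, and the whole matrix is
    rescaled so its spectral radius equals ``target_radius``.
    """
    if n_roi % 2:
        raise ValueError("n_roi must be even (hemispheric mirror pairing)")
    if not 0.0 < target_radius < 1.0:
        raise ValueError("target_radius must lie in (0, 1)")
    if n_modules < 2:
        raise ValueError("need at least 2 modules")
    if asymmetry < 0:
        raise ValueError("asymmetry must be nonnegative")

    half = n_roi // 2
    rng = np.random.default_rng(seed)

    mod_half = (np.arange(half) * n_modules) // half
    modules = np.concatenate([mod_half, mod_half])
    hemis = np.concatenate([np.zeros(half, int), np.ones(half, int)])

    same_module = modules[:, None] == modules[None, :]
    w = np.where(same_module, within_w, between_w).astype(float)
    pairs = np.arange(half)
    w[pairs, pairs + half] = homotopic_w
    w[pairs + half, pairs] = homotopic_w

    if asymmetry > 0:
        g = rng.normal(0.0, asymmetry, size=(n_roi, n_roi))
        anti = np.triu(g, 1)
        anti = anti - anti.T
        w = w + anti

    w *= target_radius / _spectral_radius(w)
    rho = _spectral_radius(w)
    assert abs(rho - target_radius) < 1e-9
    return CouplingMatrix(w, modules, hemis, target_radius)


def lesion_coupling(coupling: CouplingMatrix, severity: float,
                    k_homotopic: float = 0.9, k_asym: float = 0.25,
                    n_lesioned: int = 0, seed: int = 0) -> CouplingMatrix:
    """Apply severity-scaled damage to a coupling matrix.

    Homotopic weights are multiplied by ``1 - k_homotopic * severity``, an
    antisymmetric perturbation of scale ``k_asym * severity`` is added, and
    ``n_lesioned`` randomly chosen ROIs have their rows and columns damped
    by a factor 0.1 (shape-preserving lesion).  The spectral radius is
    re-capped at the original target if the perturbation pushed it above.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    if n_lesioned >= coupling.n_roi:
        raise ValueError("n_lesioned must be smaller than n_roi")
    if severity == 0.0 and n_lesioned == 0:
        return CouplingMatrix(coupling.weights.copy(),
                              coupling.module_assignment.copy(),
                              coupling.hemisphere_assignment.copy(),
                              coupling.target_radius)

    rng = np.random.default_rng(seed)
    w = coupling.weights.copy()
    pairs = coupling.homotopic_pairs()
    factor = 1.0 - k_homotopic * severity
    w[pairs[:, 0], pairs[:, 1]] *= factor
    w[pairs[:, 1], pairs[:, 0]] *= factor

    scale = k_asym * severity
    if scale > 0:
        g = rng.normal(0.0, scale, size=w.shape)
        anti = np.triu(g, 1)
        w = w + (anti - anti.T)

    if n_lesioned > 0:
        lesioned = rng.choice(coupling.n_roi, size=n_lesioned, replace=False)
        w[lesioned, :] *= 0.1
        w[:, lesioned] *= 0.1

    rho = _spectral_radius(w)
    if rho > coupling.target_radius:
        w *= coupling.target_radius / rho
    return CouplingMatrix(w, coupling.module_assignment.copy(),
                          coupling.hemisphere_assignment.copy(),
                          coupling.target_radius)


def simulate_series(coupling: CouplingMatrix, n_frames: int,
                    noise_sd: float = 1.0, burn_in: int = 100,
                    seed: int = 0, tr: float = 2.0,
                    subject_id: str = "", timepoint: str = "control") -> SubjectSeries:
    """Simulate a stationary VAR(1) series from a coupling matrix.

    The first ``burn_in`` frames are discarded so the returned series is a
    draw from (near) the stationary distribution.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    if burn_in < 0:
        raise ValueError("burn_in must be nonnegative")
    rho = coupling.spectral_radius()
    if rho >= 1.0:
        raise ValueError(f"unstable coupling: spectral radius {rho:.4f} >= 1")

    rng = np.random.default_rng(seed)
    n = coupling.n_roi
    w = coupling.weights
    total = n_frames + burn_in
    eps = rng.normal(0.0, noise_sd, size=(total, n))
    x = np.empty((total, n))
    x[0] = eps[0]
    for t in range(1, total):
        x[t] = w @ x[t - 1] + eps[t]
    return SubjectSeries(x[burn_in:].T, subject_id=subject_id,
                         timepoint=timepoint, tr=tr, space="source")


def var1_stationary_cov(w: np.ndarray, noise_sd: float = 1.0) -> np.ndarray:
    """Closed-form stationary covariance of x(t+1) = W x(t) + eps.

    Solves the discrete Lyapunov equation S = W S W' + noise_sd^2 I by
    vectorization; used as an analytic oracle in tests.
    """
    n = w.shape[0]
    q = noise_sd ** 2 * np.eye(n)
    a = np.eye(n * n) - np.kron(w, w)
    s = np.linalg.solve(a, q.ravel())
    return s.reshape(n, n)


def variance_stable(series: SubjectSeries, lo: float = 0.5, hi: float = 2.0) -> bool:
    """First-half vs second-half variance ratio check for stationarity."""
    t = series.n_frames
    v1 = series.data[:, : t // 2].var()
    v2 = series.data[:, t // 2:].var()
    ratio = v1 / v2
    return bool(lo <= ratio <= hi)


def _jitter_coupling(coupling: CouplingMatrix, frac: float, seed: int) -> CouplingMatrix:
    """Per-subject perturbation of the group coupling.

    Adds iid Gaussian noise with SD = ``frac`` x the off-diagonal RMS
    weight to every off-diagonal entry, emulating inter-subject
    variability in connection strengths.  The noise carries both a
    symmetric component (FC variability) and an antisymmetric component
    (individual variation in directed coupling, hence a nonzero spread
    of baseline irreversibility across healthy subjects).  The spectral
    radius is re-capped at the group target.
    """
    if frac == 0.0:
        return coupling
    rng = np.random.default_rng(seed)
    w = coupling.weights.copy()
    off = ~np.eye(coupling.n_roi, dtype=bool)
    scale = frac * float(np.sqrt(np.mean(w[off] ** 2)))
    g = rng.normal(0.0, scale, size=w.shape)
    np.fill_diagonal(g, 0.0)
    w = w + g
    rho = _spectral_radius(w)
    if rho > coupling.target_radius:
        w *= coupling.target_radius / rho
    return CouplingMatrix(w, coupling.module_assignment.copy(),
                          coupling.hemisphere_assignment.copy(),
                          coupling.target_radius)


def generate_cohort(params: CohortParams | None = None, seed: int = 0) -> Cohort:
    """Generate a full control + patient cohort with longitudinal series.

    Draw order (fixed, for reproducibility): healthy coupling; per-cohort
    behavioral sensitivities ``beta_d ~ U(1, 3)``; then per subject in
    id order: a symmetric coupling jitter (inter-subject variability),
    severity ``~ Beta(2, 2)`` and recovery rate ``~ Gamma(shape 2,
    scale 0.5)`` for patients, clinical covariates, behavior scores, and
    one child seed per (subject, timepoint) series.
    """
    params = params or CohortParams()
    if params.n_controls < 2 or params.n_patients < 2:
        raise ValueError("need at least 2 controls and 2 patients")

    root = np.random.SeedSequence(seed)
    master = np.random.default_rng(root)
    coupling_seed, *_ = root.spawn(1)

    healthy = build_coupling(
        params.n_roi, params.n_modules, params.within_w, params.between_w,
        params.homotopic_w, params.asymmetry, params.target_radius,
        seed=coupling_seed,
    )
    sc_template = np.abs(0.5 * (healthy.weights + healthy.weights.T))
    np.fill_diagonal(sc_template, 0.0)

    betas = master.uniform(1.0, 3.0, size=len(BEHAVIOR_DOMAINS))

    records: list[SubjectRecord] = []
    series: dict = {}

    def _child_seed() -> int:
        return int(master.integers(0, 2 ** 31 - 1))

    for i in range(params.n_controls):
        sid = f"ctrl{i:03d}"
        behavior = {
            tp: {d: float(master.normal(0.0, params.behavior_noise_sd))
                 for d in BEHAVIOR_DOMAINS}
            for tp in params.timepoints
        }
        rec = SubjectRecord(sid, "control", 0.0, 0.0, 0, 0, behavior)
        records.append(rec)
        own = _jitter_coupling(healthy, params.subject_jitter, _child_seed())
        s = simulate_series(own, params.n_frames, params.noise_sd,
                            params.burn_in, seed=_child_seed(), tr=params.tr,
                            subject_id=sid, timepoint="control")
        series[(sid, "control")] = s

    for i in range(params.n_patients):
        sid = f"pat{i:03d}"
        sev = float(master.beta(2.0, 2.0))
        sev = min(max(sev, 1e-3), 1.0)          # patients have severity > 0
        rate = float(master.gamma(2.0, 0.5))
        lesion_volume = int(round(sev * params.n_roi * params.lesion_frac))
        n_damped = int(round(sev * params.n_roi * params.lesion_damp_frac))
        nihss = max(0, int(round(params.nihss_scale * sev + master.normal(0.0, 1.0))))
        behavior = {}
        rec = SubjectRecord(sid, "patient", sev, rate, lesion_volume, nihss, behavior)
        for tp in params.timepoints:
            s_tau = rec.severity_at(tp)
            behavior[tp] = {
                d: float(-betas[k] * s_tau
                         + master.normal(0.0, params.behavior_noise_sd))
                for k, d in enumerate(BEHAVIOR_DOMAINS)
            }
        own = _jitter_coupling(healthy, params.subject_jitter, _child_seed())
        lesion_seed = _child_seed()
        for tp in params.timepoints:
            s_tau = rec.severity_at(tp)
            damaged = lesion_coupling(own, s_tau, params.k_homotopic,
                                      params.k_asym, n_damped,
                                      seed=lesion_seed)
            series[(sid, tp)] = simulate_series(
                damaged, params.n_frames, params.noise_sd, params.burn_in,
                seed=_child_seed(), tr=params.tr, subject_id=sid, timepoint=tp)
        records.append(rec)

    return Cohort(records, series, sc_template, seed, params)


# ---------------------------------------------------------------------------
# Disk round-trip (TSV matrices + metadata table + params sidecar)

def write_cohort(cohort: Cohort, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (sid, tp), s in cohort.series.items():
        write_series(s, outdir / f"{sid}_{tp}.tsv")
    np.savetxt(outdir / "sc_template.tsv", cohort.sc_template,
               delimiter="\t", fmt="%.17g")

    import pandas as pd
    rows = []
    for rec in cohort.records:
        row = {
            "subject_id": rec.subject_id, "group": rec.group,
            "severity": rec.severity, "recovery_rate": rec.recovery_rate,
            "lesion_volume": rec.lesion_volume, "nihss": rec.nihss,
        }
        for tp, scores in rec.behavior.items():
            for d, v in scores.items():
                row[f"beh_{d}_{tp}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    (outdir / "params.json").write_text(json.dumps(
        {"seed": cohort.rng_seed, "params": cohort.params.to_dict()}, indent=2))


def read_cohort(indir) -> Cohort:
    import pandas as pd
    indir = Path(indir)
    meta = json.loads((indir / "params.json").read_text())
    params = CohortParams.from_dict(meta["params"])
    table = pd.read_csv(indir / "cohort.tsv", sep="\t")
    records = []
    series = {}
    for _, row in table.iterrows():
        tps = ("control",) if row["group"] == "control" else params.timepoints
        behavior = {}
        for tp in params.timepoints:
            behavior[tp] = {d: float(row[f"beh_{d}_{tp}"])
                            for d in BEHAVIOR_DOMAINS
                            if f"beh_{d}_{tp}" in row}
        rec = SubjectRecord(row["subject_id"], row["group"],
                            float(row["severity"]), float(row["recovery_rate"]),
                            int(row["lesion_volume"]), int(row["nihss"]), behavior)
        records.append(rec)
        for tp in tps:
            series[(rec.subject_id, tp)] = read_series(
                indir / f"{rec.subject_id}_{tp}.tsv")
    sc = np.loadtxt(indir / "sc_template.tsv", delimiter="\t")
    return Cohort(records, series, sc, meta["seed"], params)
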