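"""Synthetic clinical dataset generator.

Emulates the structure of a longitudinal type-1/type-2 diabetes cohort:
50 patients, 391 encounters (113 T1DM / 278 T2DM), 2-18 encounters per
patient, published marginal statistics per attribute, and per-attribute
missing-value rates.  The generator reproduces marginal moments and
structural counts only; it makes no claim about the joint distribution of
any real cohort.

Each continuous attribute is sampled from a truncated normal whose
underlying parameters are moment-matched so that the *truncated* mean and
standard deviation equal the configured targets (a naive truncated normal
parameterised directly by the target moments can be badly biased when the
bounds are asymmetric, e.g. triglycerides).  Longitudinal structure within
a patient is induced through a Gaussian copula: a patient-level random
effect plus an AR(1) encounter process on the latent normal scale, so the
marginals stay exact while consecutive encounters are correlated.

Class signal is injected as mean-centred shifts (T1DM younger, leaner,
higher HbA1c — a clinically plausible synthetic construction, not an
estimate from any real dataset); within-class variance is shrunk so the
overall marginal mean and sd still match the configured targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .data_model import MISSING, AttributeSpec, DecisionTable, EncounterRecord


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class AttributeDistribution:
    """Marginal target for one continuous attribute."""

    name: str
    mean: float
    sd: float
    min: float
    max: float
    shape: str = "truncated-normal"   # or "truncated-lognormal"

    def __post_init__(self):
        if not (self.min < self.max):
            raise ConfigurationError(f"{self.name}: min must be < max")
        if self.sd <= 0:
            raise ConfigurationError(f"{self.name}: sd must be positive")
        if not (self.min <= self.mean <= self.max):
            raise ConfigurationError(f"{self.name}: mean outside [min, max]")


#: Published cohort marginals (mean, min, max, sd) per attribute.
DEFAULT_DISTRIBUTIONS = (
    AttributeDistribution("BMI", 23.0, 3.2, 16.2, 32.0),
    AttributeDistribution("Age", 48.8, 15.4, 20.0, 85.0),
    AttributeDistribution("SBP", 120.8, 14.9, 89.0, 190.0),
    AttributeDistribution("DBP", 74.5, 10.2, 45.0, 115.0),
    AttributeDistribution("FBS", 137.6, 43.9, 49.0, 394.0),
    AttributeDistribution("Hba1c", 8.0, 2.0, 4.2, 14.6),
    AttributeDistribution("TC", 169.5, 37.7, 0.0, 371.0),
    AttributeDistribution("TG", 101.0, 80.9, 18.0, 634.0),
    AttributeDistribution("HDL", 64.5, 23.7, 31.0, 196.0),
    AttributeDistribution("LDL", 82.2, 29.4, 15.0, 180.0),
    AttributeDistribution("AST", 22.0, 7.8, 11.0, 65.0),
    AttributeDistribution("ALT", 26.6, 18.0, 8.0, 120.0),
)

#: T1DM-minus-T2DM mean differences injected as learnable class signal.
DEFAULT_CLASS_EFFECTS = {"Age": -20.0, "BMI": -3.5, "Hba1c": 1.2}

#: Published per-attribute missing-cell rates; FHx/SHx above the 20% drop
#: threshold so the attribute-dropping rule is exercised.
DEFAULT_MISSINGNESS = {
    "SBP": 0.06, "DBP": 0.06, "FBS": 0.04, "Hba1c": 0.01,
    "TC": 0.09, "TG": 0.09, "HDL": 0.09, "LDL": 0.15,
    "AST": 0.19, "ALT": 0.19,
    "FHx": 0.25, "SHx": 0.25,
}


@dataclass
class SyntheticConfig:
    n_patients: int = 50
    total_encounters: int = 391
    encounters_min: int = 2
    encounters_max: int = 18
    class_split: dict = field(default_factory=lambda: {"T1DM": 113, "T2DM": 278})
    class_patients: dict = field(default_factory=lambda: {"T1DM": 20, "T2DM": 30})
    gender_split: dict = field(default_factory=lambda: {"M": 256, "F": 135})
    distributions: tuple = DEFAULT_DISTRIBUTIONS
    class_effects: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_EFFECTS))
    missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    ar_coefficient: float = 0.7
    patient_effect_share: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if sum(self.class_split.values()) != self.total_encounters:
            raise ConfigurationError("class_split must sum to total_encounters")
        if sum(self.class_patients.values()) != self.n_patients:
            raise ConfigurationError("class_patients must sum to n_patients")
        for cls, n_enc in self.class_split.items():
            n_pat = self.class_patients[cls]
            if not (n_pat * self.encounters_min <= n_enc <= n_pat * self.encounters_max):
                raise ConfigurationError(
                    f"class {cls}: {n_enc} encounters infeasible for {n_pat} patients "
                    f"with per-patient bounds [{self.encounters_min}, {self.encounters_max}]"
                )
        for a, f in self.missingness.items():
            if not (0 <= f <= 1):
                raise ConfigurationError(f"missingness[{a}] outside [0, 1]")


@lru_cache(maxsize=512)
def _calibrate_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Underlying (mu, sigma) whose [lo, hi]-truncated normal has the given
    truncated mean and sd."""

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        with np.errstate(invalid="ignore"):
            m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        if not (np.isfinite(m) and np.isfinite(v) and v > 0):
            return [1e6, 1e6]
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    # multi-start: strongly skewed targets live in the near-exponential
    # corner of the parameter space (mu far below the lower bound)
    starts = ([mean, np.log(sd)], [mean - sd, np.log(2 * sd)],
              [lo - 2 * sd, np.log(4 * sd)])
    best = None
    for x0 in starts:
        sol = optimize.least_squares(moments, x0=x0, method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    mu, sigma = float(best.x[0]), float(np.exp(best.x[1]))
    if best.cost > 1e-4 * (1 + sd ** 2):
        warnings.warn(f"truncated-normal calibration imperfect for target ({mean}, {sd})")
    return mu, sigma


def _sample_marginal(z: np.ndarray, mean: float, sd: float, lo: float, hi: float,
                     shape: str) -> np.ndarray:
    """Map latent standard normals to the calibrated truncated marginal."""
    if shape == "truncated-lognormal":
        # match moments on the log scale of the shifted variable
        shift = max(1e-9, lo)
        m = np.log(max(mean, shift + 1e-6))
        s = np.sqrt(np.log(1 + (sd / max(mean, 1e-6)) ** 2))
        x = np.exp(m + s * z)
        return np.clip(x, lo, hi)
    mu, sigma = _calibrate_truncnorm(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    u = stats.norm.cdf(z)
    # keep u strictly inside (0, 1) for ppf stability
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


def _allocate_counts(rng, n_patients, total, lo, hi):
    """Per-patient encounter counts, uniform in [lo, hi], adjusted to hit the
    exact total while respecting the bounds."""
    counts = rng.integers(lo, hi + 1, size=n_patients)
    diff = total - int(counts.sum())
    step = 1 if diff > 0 else -1
    guard = 0
    while diff != 0:
        i = int(rng.integers(n_patients))
        if lo <= counts[i] + step <= hi:
            counts[i] += step
            diff -= step
        guard += 1
        if guard > 100000:
            raise ConfigurationError("could not allocate encounter counts")
    return [int(c) for c in counts]


def _gender_assignment(counts, target_m):
    """Subset of patients whose encounter counts sum exactly to target_m
    (assigned male), via subset-sum DP; falls back to the closest sum."""
    reachable = {0: []}
    for i, c in enumerate(counts):
        updates = {}
        for s, subset in reachable.items():
            ns = s + c
            if ns <= target_m and ns not in reachable and ns not in updates:
                updates[ns] = subset + [i]
        reachable.update(updates)
    best = max(reachable, key=lambda s: s)  # closest to target from below
    return set(reachable[best])


def generate_dmis(config: SyntheticConfig | None = None,
                  seed: int | None = None) -> DecisionTable:
    """Generate a synthetic diabetes information system.

    Deterministic for a fixed seed.  Structural counts (patients, total
    encounters, class split) match the config exactly; continuous values lie
    within the configured [min, max]; each patient carries one class label
    and one gender across encounters; missing cells are injected per
    attribute at the configured rates (rounded to whole cells).
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # -- structure: patients, classes, encounter counts -----------------
    pids, classes, counts = [], [], []
    for cls in sorted(config.class_split):
        n_pat = config.class_patients[cls]
        cls_counts = _allocate_counts(
            rng, n_pat, config.class_split[cls],
            config.encounters_min, config.encounters_max)
        for c in cls_counts:
            pids.append(f"P{len(pids) + 1:03d}")
            classes.append(cls)
            counts.append(c)

    male_idx = _gender_assignment(counts, config.gender_split.get("M", 0))
    genders = ["M" if i in male_idx else "F" for i in range(len(pids))]

    n_total = sum(counts)
    class_sizes = dict(config.class_split)
    n_all = sum(class_sizes.values())

    # -- continuous values via Gaussian copula ---------------------------
    # latent z per (attribute, row): patient random effect + AR(1) encounter
    # process.  The latent normals are re-standardised within each
    # (attribute, class) group before the quantile transform, so the realised
    # marginal moments track the configured targets instead of drifting with
    # the patient-level clustering (50 patients give a small effective n).
    lam = config.patient_effect_share
    phi = config.ar_coefficient
    dist_by_name = {d.name: d for d in config.distributions}
    latent = {name: np.empty(n_total) for name in dist_by_name}
    row = 0
    rows_by_patient = []
    for i, (pid, cls, k) in enumerate(zip(pids, classes, counts)):
        rows_by_patient.append(range(row, row + k))
        for name in dist_by_name:
            u_pat = rng.standard_normal()
            eps = np.empty(k)
            eps[0] = rng.standard_normal()
            for t in range(1, k):
                eps[t] = phi * eps[t - 1] + np.sqrt(1 - phi ** 2) * rng.standard_normal()
            latent[name][row:row + k] = np.sqrt(lam) * u_pat + np.sqrt(1 - lam) * eps
        row += k

    cls_rows = {cls: np.array([r for i, c in enumerate(classes) if c == cls
                               for r in rows_by_patient[i]])
                for cls in class_sizes}
    values = {name: np.empty(n_total) for name in dist_by_name}
    for name, d in dist_by_name.items():
        for cls, rows in cls_rows.items():
            z = latent[name][rows]
            if len(z) > 1 and z.std() > 0:
                z = (z - z.mean()) / z.std()
            diff = config.class_effects.get(name, 0.0)
            if diff:
                p1 = class_sizes.get("T1DM", 0) / n_all
                p2 = 1.0 - p1
                shift = diff * (p2 if cls == "T1DM" else -p1)
                between_var = p1 * p2 * diff ** 2
                sd_within = np.sqrt(max(d.sd ** 2 - between_var, (0.3 * d.sd) ** 2))
                target_mean = min(max(d.mean + shift, d.min), d.max)
            else:
                target_mean, sd_within = d.mean, d.sd
            values[name][rows] = _sample_marginal(
                z, target_mean, sd_within, d.min, d.max, d.shape)

    # -- assemble records -------------------------------------------------
    records = []
    for i, (pid, cls, gender) in enumerate(zip(pids, classes, genders)):
        fhx = "Y" if rng.random() < 0.4 else "N"
        shx = "Y" if rng.random() < 0.3 else "N"
        for t, r in enumerate(rows_by_patient[i], start=1):
            vals = {"Gender": gender, "FHx": fhx, "SHx": shx, "TDM": cls}
            for name in dist_by_name:
                x = float(values[name][r])
                vals[name] = round(x, 1)
            records.append(EncounterRecord(pid=pid, encounter_id=t, values=vals))

    # -- inject missingness ----------------------------------------------
    for name, rate in config.missingness.items():
        if rate <= 0:
            continue
        k = int(round(rate * n_total))
        for r in rng.choice(n_total, size=min(k, n_total), replace=False):
            if name in records[r].values:
                records[r].values[name] = MISSING

    attributes = [
        AttributeSpec("PID", "nominal", "identifier"),
        AttributeSpec("EncounterID", "nominal", "identifier"),
        AttributeSpec("Gender", "nominal"),
        AttributeSpec("FHx", "nominal"),
        AttributeSpec("SHx", "nominal"),
        AttributeSpec("Age", "continuous", units="years"),
        AttributeSpec("BMI", "continuous", units="kg/m2"),
        AttributeSpec("SBP", "continuous", units="mm Hg"),
        AttributeSpec("DBP", "continuous", units="mm Hg"),
        AttributeSpec("FBS", "continuous", units="mg/dL"),
        AttributeSpec("Hba1c", "continuous", units="%"),
        AttributeSpec("TC", "continuous", units="mg/dL"),
        AttributeSpec("TG", "continuous", units="mg/dL"),
        AttributeSpec("HDL", "continuous", units="mg/dL"),
        AttributeSpec("LDL", "continuous", units="mg/dL"),
        AttributeSpec("AST", "continuous", units="U/L"),
        AttributeSpec("ALT", "continuous", units="U/L"),
        AttributeSpec("TDM", "nominal", "decision"),
    ]
    return DecisionTable(attributes=attributes, records=records)


def marginal_summary(table: DecisionTable):
    """Sample statistics (mean, min, max, sd with n-1 denominator) per
    continuous attribute over non-missing cells."""
    out = []
    for a in table.attributes:
        if a.role != "condition" or a.kind != "continuous":
            continue
        col = [v for v in table.column(a.name) if v is not MISSING]
        if not col:
            warnings.warn(f"attribute {a.name} is entirely missing; skipped")
            continue
        arr = np.asarray(col, dtype=float)
        sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
        out.append((a.name, float(arr.mean()), float(arr.min()), float(arr.max()), sd))
    return out
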