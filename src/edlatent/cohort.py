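"""Synthetic ED-visit cohort generator with known ground-truth causal effects.

Generates visit tables with the exact statistical structure the analysis
model assumes: a binary latent health state drawn from a logistic prior on
baseline characteristics, Gaussian/logistic proxy observations (vitals and
triage acuity), a two-boundary Wiener first-passage admission process whose
drift is linear in latent health, baseline and proxies, and identity-link
Bernoulli outcomes.  Default marginals are calibrated to a cohort of older
adults (65+) presenting to an emergency department with one of six gray-area
presentations (falls, weakness, syncope, UTI, pneumonia, cellulitis).

Because the generator realises the model forward, the implied average
treatment effect of admission on every outcome is known analytically and is
recorded alongside the cohort for recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

from .wiener import ThresholdParameters, simulate_first_passage

__all__ = [
    "BaselineSpec", "ProxySpec", "OutcomeSpec", "ScreeningSpec",
    "GeneratorConfig", "GroundTruth", "default_config", "generate_cohort",
    "inject_missingness", "true_ate_monte_carlo",
    "BASELINE_COLUMNS", "PROXY_COLUMNS", "OUTCOME_FAMILIES", "WINDOWS",
]

PRESENTATIONS = ["falls", "weakness", "syncope", "uti", "pneumonia", "cellulitis"]
INSURANCE_LEVELS = ["medicare", "medicaid", "commercial", "self_pay"]
OUTCOME_FAMILIES = ["revisit", "readmission", "mortality"]
WINDOWS = [3, 9, 30]

# encoded baseline design (order is the package-wide convention)
BASELINE_COLUMNS = ["age_z", "female", "ins_medicaid", "ins_commercial",
                    "ins_self_pay", "diabetes", "chf", "hypertension", "hcc_z"]
# encoded proxy design
PROXY_COLUMNS = ["acuity2", "temperature_z", "blood_pressure_z",
                 "respiration_rate_z", "heart_rate_z"]
CONTINUOUS_PROXIES = ["temperature", "blood_pressure",
                      "respiration_rate", "heart_rate"]

STUDY_START = date(2014, 1, 1)
STUDY_END = date(2018, 9, 27)


@dataclass
class BaselineSpec:
    """Marginal distributions of the seven baseline characteristics."""
    age_mean: float = 79.2
    age_sd: float = 8.9
    age_min: float = 65.0
    age_max: float = 110.0
    p_female: float = 0.585
    insurance_probs: dict = field(default_factory=lambda: {
        "medicare": 0.919, "medicaid": 0.004,
        "commercial": 0.076, "self_pay": 0.001})
    p_diabetes: float = 0.207
    p_chf: float = 0.115
    p_hypertension: float = 0.580
    hcc_mean: float = 1.65
    hcc_sd: float = 1.41


@dataclass
class ProxySpec:
    """Continuous proxy model: x_j = alpha + lambda*H + kappa.baseline + eps."""
    alpha: float
    lam: float
    sigma: float
    kappa: np.ndarray = field(default_factory=lambda: np.zeros(len(BASELINE_COLUMNS)))

    def __post_init__(self):
        self.kappa = np.asarray(self.kappa, dtype=float)
        if not self.sigma > 0:
            raise ValueError("proxy residual sd must be positive")


@dataclass
class OutcomeSpec:
    """Identity-link outcome: P(Y30=1) = b0 + bh*H + ba*A + bha*H*A + bx.x.

    ``bx`` (baseline effects) defaults to zero and exists so that scenarios
    with purely measured confounding can be generated.
    """
    b0: float
    bh: float
    ba: float
    bha: float = 0.0
    bx: np.ndarray = field(default_factory=lambda: np.zeros(len(BASELINE_COLUMNS)))

    def __post_init__(self):
        self.bx = np.asarray(self.bx, dtype=float)

    def cell_probs(self) -> np.ndarray:
        """Outcome probability for (H, A) in {0,1}^2 at baseline effects 0."""
        return np.array([[self.b0 + a * self.ba + h * self.bh + h * a * self.bha
                          for a in (0, 1)] for h in (0, 1)])


@dataclass
class ScreeningSpec:
    """Exclusion-screen fields (independent of the latent model)."""
    p_troponin_measured: float = 0.30
    troponin_log_mean: float = -3.7    # ~0.025 ng/mL median
    troponin_log_sd: float = 0.8
    pulse_ox_mean: float = 95.5
    pulse_ox_sd: float = 2.2
    systolic_mean: float = 136.0
    systolic_sd: float = 19.0
    p_stroke: float = 0.004
    p_mi: float = 0.004
    p_femur_fracture: float = 0.006
    p_acuity_out_of_range: float = 0.02   # ESI 1/4/5 despite gray-area sampling
    p_other_disposition: float = 0.01     # eloped / AMA / transfer


@dataclass
class GeneratorConfig:
    """Full generative specification of a synthetic cohort."""
    n_visits: int
    seed: int
    baseline_spec: BaselineSpec
    eta: np.ndarray                       # latent prior: intercept + baseline
    proxy_spec: dict                      # name -> ProxySpec (continuous)
    acuity_coef: np.ndarray               # logistic: intercept, lam_h, kappa
    threshold_spec: ThresholdParameters
    outcome_spec: dict                    # family -> OutcomeSpec (30-day)
    missingness_rates: dict = field(default_factory=dict)
    presentation_mix: dict = field(default_factory=lambda: {
        "falls": 0.440, "weakness": 0.157, "syncope": 0.130,
        "uti": 0.127, "pneumonia": 0.083, "cellulitis": 0.063})
    screening_spec: ScreeningSpec = field(default_factory=ScreeningSpec)
    # population standardisation constants used inside the drift
    proxy_standardization: dict = field(default_factory=dict)
    treatment_time_floor: float = 1e-3    # hours; keeps times strictly positive
    mortality_censors: bool = False

    def __post_init__(self):
        self.eta = np.asarray(self.eta, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        mix = np.array([self.presentation_mix[p] for p in PRESENTATIONS])
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-12:
            raise ValueError("presentation_mix must be a probability vector")
        ins = np.array([self.baseline_spec.insurance_probs[c]
                        for c in INSURANCE_LEVELS])
        if np.any(ins < 0) or abs(ins.sum() - 1.0) > 1e-12:
            raise ValueError("insurance_probs must be a probability vector")
        for r in self.missingness_rates.values():
            if not 0.0 <= r <= 1.0:
                raise ValueError("missingness rates must lie in [0, 1]")
        for fam, spec in self.outcome_spec.items():
            cells = spec.cell_probs()
            if np.any(cells < 0.0) or np.any(cells > 1.0):
                raise ValueError(
                    f"outcome '{fam}' yields probabilities outside [0, 1]")
        self.threshold_spec.validate()

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return _jsonify(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["baseline_spec"] = BaselineSpec(**d["baseline_spec"])
        d["proxy_spec"] = {k: ProxySpec(**v) for k, v in d["proxy_spec"].items()}
        d["outcome_spec"] = {k: OutcomeSpec(**v) for k, v in d["outcome_spec"].items()}
        d["threshold_spec"] = ThresholdParameters(**d["threshold_spec"])
        d["screening_spec"] = ScreeningSpec(**d.get("screening_spec", {}))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class GroundTruth:
    """Per-visit latent truth and the implied average treatment effects."""
    latent_states: np.ndarray
    drifts: np.ndarray
    true_ate: dict            # "family_Nd" -> float
    true_subgroup_ates: dict  # predicate name -> {"family_Nd": float}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(_jsonify({
                "latent_states": self.latent_states,
                "drifts": self.drifts,
                "true_ate": self.true_ate,
                "true_subgroup_ates": self.true_subgroup_ates,
            }), fh, indent=1)


def default_config(n_visits: int, seed: int, scenario: str = "default"
                   ) -> GeneratorConfig:
    """Named study scenarios.

    default             latent-driven confounding by indication (the study
                        condition: sicker patients drift toward admission and
                        have worse outcomes; vitals/acuity are noisy proxies).
    randomized          admission independent of everything (zero drift
                        effects) — all estimators should agree.
    measured_confounding  no latent effects anywhere; outcomes and admission
                        share a measured baseline covariate (HCC).
    null                default structure but zero admission effect.
    heterogeneous       default structure plus latent-by-admission
                        interactions in the outcomes.
    """
    nB = len(BASELINE_COLUMNS)
    kz = lambda **kw: _kappa(nB, **kw)

    eta = np.zeros(nB + 1)
    eta[0] = -0.9
    eta[1 + BASELINE_COLUMNS.index("age_z")] = 0.25
    eta[1 + BASELINE_COLUMNS.index("diabetes")] = 0.20
    eta[1 + BASELINE_COLUMNS.index("chf")] = 0.50
    eta[1 + BASELINE_COLUMNS.index("hypertension")] = 0.10
    eta[1 + BASELINE_COLUMNS.index("hcc_z")] = 0.45

    proxy_spec = {
        "temperature": ProxySpec(alpha=97.40, lam=0.80, sigma=1.20),
        "blood_pressure": ProxySpec(alpha=75.5, lam=-6.0, sigma=12.5,
                                    kappa=kz(hypertension=3.0)),
        "respiration_rate": ProxySpec(alpha=17.6, lam=1.8, sigma=2.9),
        "heart_rate": ProxySpec(alpha=76.0, lam=7.0, sigma=13.5,
                                kappa=kz(chf=2.0)),
    }
    acuity_coef = np.zeros(2 + nB)
    acuity_coef[0] = -1.5
    acuity_coef[1] = 1.4

    delta_x = _kappa(nB, age_z=0.10, hcc_z=0.15)
    delta_w = np.zeros(len(PROXY_COLUMNS))
    delta_w[PROXY_COLUMNS.index("acuity2")] = 0.50
    delta_w[PROXY_COLUMNS.index("temperature_z")] = 0.10
    delta_w[PROXY_COLUMNS.index("blood_pressure_z")] = -0.15
    delta_w[PROXY_COLUMNS.index("respiration_rate_z")] = 0.20
    delta_w[PROXY_COLUMNS.index("heart_rate_z")] = 0.20
    threshold = ThresholdParameters(boundary_a=3.4, start_w0=0.38,
                                    delta0=-0.55, delta_h=1.5,
                                    delta_x=delta_x, delta_w=delta_w)

    outcomes = {
        "revisit": OutcomeSpec(b0=0.210, bh=0.050, ba=-0.064),
        "readmission": OutcomeSpec(b0=0.020, bh=0.090, ba=0.058),
        "mortality": OutcomeSpec(b0=0.005, bh=0.060, ba=0.010),
    }

    missing = {"temperature": 0.05, "blood_pressure": 0.03,
               "respiration_rate": 0.03, "heart_rate": 0.02,
               "hcc": 0.02, "insurance": 0.01}

    # population-scale standardisation of the proxies entering the drift,
    # implied by the proxy models at the average latent prevalence (~0.32)
    std = {"temperature": (97.66, 1.32), "blood_pressure": (73.6, 12.9),
           "respiration_rate": (18.2, 3.0), "heart_rate": (78.3, 14.2)}

    cfg = GeneratorConfig(
        n_visits=n_visits, seed=seed, baseline_spec=BaselineSpec(),
        eta=eta, proxy_spec=proxy_spec, acuity_coef=acuity_coef,
        threshold_spec=threshold, outcome_spec=outcomes,
        missingness_rates=missing, proxy_standardization=std)

    if scenario == "default":
        return cfg
    if scenario == "randomized":
        cfg.threshold_spec = ThresholdParameters(
            boundary_a=3.4, start_w0=0.38, delta0=0.0, delta_h=0.0,
            delta_x=np.zeros(nB), delta_w=np.zeros(len(PROXY_COLUMNS)))
        return cfg
    if scenario == "measured_confounding":
        for spec in cfg.proxy_spec.values():
            spec.lam = 0.0
        cfg.acuity_coef[1] = 0.0
        cfg.threshold_spec.delta_h = 0.0
        cfg.threshold_spec.delta_x = _kappa(nB, hcc_z=0.6, age_z=0.15)
        cfg.outcome_spec = {
            "revisit": OutcomeSpec(b0=0.210, bh=0.0, ba=-0.064,
                                   bx=_kappa(nB, hcc_z=0.05)),
            "readmission": OutcomeSpec(b0=0.080, bh=0.0, ba=0.058,
                                       bx=_kappa(nB, hcc_z=0.05)),
            "mortality": OutcomeSpec(b0=0.030, bh=0.0, ba=0.010,
                                     bx=_kappa(nB, hcc_z=0.02)),
        }
        return cfg
    if scenario == "null":
        for spec in cfg.outcome_spec.values():
            spec.ba = 0.0
        return cfg
    if scenario == "heterogeneous":
        cfg.outcome_spec = {
            "revisit": OutcomeSpec(b0=0.210, bh=0.050, ba=-0.110, bha=0.120),
            "readmission": OutcomeSpec(b0=0.020, bh=0.090, ba=0.030, bha=0.080),
            "mortality": OutcomeSpec(b0=0.005, bh=0.060, ba=0.004, bha=0.020),
        }
        return cfg
    raise ValueError(f"unknown scenario '{scenario}'")


def _kappa(n, **kw) -> np.ndarray:
    v = np.zeros(n)
    for name, val in kw.items():
        v[BASELINE_COLUMNS.index(name)] = val
    return v


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _draw_baseline(cfg: GeneratorConfig, rng: np.random.Generator
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Raw baseline columns plus the encoded (standardised) design matrix."""
    bs = cfg.baseline_spec
    n = cfg.n_visits
    from scipy.stats import truncnorm
    a = (bs.age_min - bs.age_mean) / bs.age_sd
    b = (bs.age_max - bs.age_mean) / bs.age_sd
    age = truncnorm.rvs(a, b, loc=bs.age_mean, scale=bs.age_sd,
                        size=n, random_state=rng)
    female = (rng.random(n) < bs.p_female).astype(int)
    ins_p = np.array([bs.insurance_probs[c] for c in INSURANCE_LEVELS])
    insurance = rng.choice(INSURANCE_LEVELS, size=n, p=ins_p / ins_p.sum())
    diabetes = (rng.random(n) < bs.p_diabetes).astype(int)
    chf = (rng.random(n) < bs.p_chf).astype(int)
    hypertension = (rng.random(n) < bs.p_hypertension).astype(int)
    shape = (bs.hcc_mean / bs.hcc_sd) ** 2
    scale = bs.hcc_sd ** 2 / bs.hcc_mean
    hcc = rng.gamma(shape, scale, size=n)

    raw = pd.DataFrame({"age": age, "female": female, "insurance": insurance,
                        "diabetes": diabetes, "chf": chf,
                        "hypertension": hypertension, "hcc": hcc})
    X = np.column_stack([
        (age - bs.age_mean) / bs.age_sd,
        female,
        (insurance == "medicaid").astype(float),
        (insurance == "commercial").astype(float),
        (insurance == "self_pay").astype(float),
        diabetes, chf, hypertension,
        (hcc - bs.hcc_mean) / bs.hcc_sd,
    ])
    return raw, X


def _true_ates(cfg: GeneratorConfig, H: np.ndarray) -> dict:
    """Analytic per-outcome ATE over the generated cohort, all nine windows.

    The 30-day event is the primitive Bernoulli; the event day is uniform on
    (0, 30], so the w-day indicator probability is the 30-day probability
    scaled by w/30 and the per-visit effect scales the same way.
    """
    out = {}
    for fam, spec in cfg.outcome_spec.items():
        per_visit = spec.ba + spec.bha * H
        for w in WINDOWS:
            out[f"{fam}_{w}d"] = float(np.mean(per_visit) * (w / 30.0))
    return out


def generate_cohort(config: GeneratorConfig
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a full synthetic cohort and its ground truth.

    All VisitRecord fields are populated (missingness is injected separately
    by :func:`inject_missingness`); the ground truth is recorded before any
    masking.  Identical config + seed gives a bitwise-identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_visits

    raw, X = _draw_baseline(config, rng)
    mix = np.array([config.presentation_mix[p] for p in PRESENTATIONS])
    presentation = rng.choice(PRESENTATIONS, size=n, p=mix / mix.sum())

    # latent adverse health state
    pH = _expit(config.eta[0] + X @ config.eta[1:])
    H = (rng.random(n) < pH).astype(int)

    # proxies
    proxies = {}
    for name in CONTINUOUS_PROXIES:
        spec = config.proxy_spec[name]
        proxies[name] = (spec.alpha + spec.lam * H + X @ spec.kappa
                         + spec.sigma * rng.standard_normal(n))
    ac = config.acuity_coef
    p_ac2 = _expit(ac[0] + ac[1] * H + X @ ac[2:])
    acuity2 = (rng.random(n) < p_ac2).astype(int)
    acuity = np.where(acuity2 == 1, 2, 3)

    # admission process: first passage with covariate-linked drift
    W = np.column_stack(
        [acuity2.astype(float)] +
        [(proxies[nm] - config.proxy_standardization[nm][0])
         / config.proxy_standardization[nm][1] for nm in CONTINUOUS_PROXIES])
    drift = config.threshold_spec.drift(H, X, W)
    decision, ttime = simulate_first_passage(
        drift, config.threshold_spec.boundary_a,
        config.threshold_spec.start_w0, rng)
    ttime = np.maximum(ttime, config.treatment_time_floor)

    # outcomes: 30-day Bernoulli primitive, uniform day-of-event; families
    # absent from the config get no events
    event_days = {fam: np.full(n, np.nan) for fam in OUTCOME_FAMILIES}
    for fam, spec in config.outcome_spec.items():
        p30 = np.clip(spec.b0 + spec.bh * H + spec.ba * decision
                      + spec.bha * H * decision + X @ spec.bx, 0.0, 1.0)
        event = rng.random(n) < p30
        day = np.where(event, rng.uniform(0.0, 30.0, size=n), np.nan)
        day = np.where(event & (day == 0.0), 30.0, day)  # open at 0
        event_days[fam] = day
    if config.mortality_censors:
        dead = ~np.isnan(event_days["mortality"])
        for fam in ("revisit", "readmission"):
            later = dead & (event_days[fam] > event_days["mortality"])
            event_days[fam] = np.where(later, np.nan, event_days[fam])

    # screening / exclusion fields, independent of the latent model
    sc = config.screening_spec
    trop = np.where(rng.random(n) < sc.p_troponin_measured,
                    np.exp(sc.troponin_log_mean
                           + sc.troponin_log_sd * rng.standard_normal(n)),
                    np.nan)
    pulse_ox = np.minimum(sc.pulse_ox_mean
                          + sc.pulse_ox_sd * rng.standard_normal(n), 100.0)
    systolic = sc.systolic_mean + sc.systolic_sd * rng.standard_normal(n)
    stroke = rng.random(n) < sc.p_stroke
    mi = rng.random(n) < sc.p_mi
    femur = rng.random(n) < sc.p_femur_fracture
    oor = rng.random(n) < sc.p_acuity_out_of_range
    acuity = np.where(oor, rng.choice([1, 4, 5], size=n), acuity)
    span = (STUDY_END - STUDY_START).days
    visit_date = [STUDY_START + timedelta(days=int(d))
                  for d in rng.integers(0, span + 1, size=n)]

    dec_label = np.where(decision == 1, "admit", "discharge")
    dest = np.where(decision == 1, "hospital",
                    rng.choice(["home", "snf", "irf"], size=n,
                               p=[0.92, 0.06, 0.02]))
    other = rng.random(n) < sc.p_other_disposition
    dest = np.where(other, "other", dest)
    dec_label = np.where(other, "other", dec_label)

    table = pd.DataFrame({
        "visit_id": [f"v{i:07d}" for i in range(n)],
        "presentation": presentation,
        "visit_date": [d.isoformat() for d in visit_date],
        "age": raw["age"], "female": raw["female"],
        "insurance": raw["insurance"], "diabetes": raw["diabetes"],
        "chf": raw["chf"], "hypertension": raw["hypertension"],
        "hcc": raw["hcc"],
        "acuity": acuity,
        "temperature": proxies["temperature"],
        "blood_pressure": proxies["blood_pressure"],
        "respiration_rate": proxies["respiration_rate"],
        "heart_rate": proxies["heart_rate"],
        "troponin": trop, "pulse_oximetry": pulse_ox,
        "systolic_bp": systolic,
        "stroke_flag": stroke.astype(int), "mi_flag": mi.astype(int),
        "femur_fracture_flag": femur.astype(int),
        "decision": dec_label, "disposition_destination": dest,
        "treatment_time": ttime,
        "revisit_days": event_days["revisit"],
        "readmission_days": event_days["readmission"],
        "death_days": event_days["mortality"],
    })

    true_ate = _true_ates(config, H)
    subgroups = {
        "female": raw["female"].to_numpy() == 1,
        "male": raw["female"].to_numpy() == 0,
        "diabetes": raw["diabetes"].to_numpy() == 1,
        "chf": raw["chf"].to_numpy() == 1,
        "hcc_high": raw["hcc"].to_numpy() > config.baseline_spec.hcc_mean,
    }
    true_sub = {}
    for name, mask in subgroups.items():
        if mask.any():
            true_sub[name] = _true_ates(config, H[mask])
    gt = GroundTruth(latent_states=H, drifts=drift, true_ate=true_ate,
                     true_subgroup_ates=true_sub)
    return table, gt


MASKABLE_FIELDS = ["age", "female", "insurance", "diabetes", "chf",
                   "hypertension", "hcc", "acuity", "temperature",
                   "blood_pressure", "respiration_rate", "heart_rate",
                   "pulse_oximetry", "systolic_bp"]


def inject_missingness(table: pd.DataFrame, missingness_rates: dict,
                       seed: int) -> pd.DataFrame:
    """Independently mask fields at the given rates (MCAR); returns a copy.

    The admission decision and treatment time are never masked.
    """
    for name, rate in missingness_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for '{name}' outside [0, 1]")
        if name in ("decision", "treatment_time"):
            raise ValueError(f"'{name}' may not be masked")
        if name not in MASKABLE_FIELDS:
            raise ValueError(f"'{name}' is not a maskable field")
    out = table.copy()
    rng = np.random.default_rng(seed)
    for name in MASKABLE_FIELDS:      # fixed order: reproducible draws
        rate = missingness_rates.get(name, 0.0)
        if rate <= 0.0:
            continue
        mask = rng.random(len(out)) < rate
        col = out[name]
        if col.dtype.kind in "iub":
            out[name] = col.astype(float)
        out.loc[mask, name] = np.nan
    return out


def true_ate_monte_carlo(config: GeneratorConfig, n_mc: int, seed: int
                         ) -> dict:
    """Monte-Carlo oracle for the population ATE by forward simulation.

    Draws baseline and latent state, then evaluates *both* potential
    outcomes per draw; independent of the analytic bookkeeping in
    :class:`GroundTruth`.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000")
    cfg = GeneratorConfig.from_dict(config.to_dict())
    cfg.n_visits = n_mc
    cfg.seed = seed
    cfg.validate()
    rng = np.random.default_rng(seed)
    _, X = _draw_baseline(cfg, rng)
    pH = _expit(cfg.eta[0] + X @ cfg.eta[1:])
    H = (rng.random(n_mc) < pH).astype(int)
    out = {}
    for fam, spec in cfg.outcome_spec.items():
        base = spec.b0 + spec.bh * H + X @ spec.bx
        y1 = (rng.random(n_mc) < np.clip(base + spec.ba + spec.bha * H, 0, 1))
        y0 = (rng.random(n_mc) < np.clip(base, 0, 1))
        day1 = np.where(y1, rng.uniform(0.0, 30.0, n_mc), np.inf)
        day0 = np.where(y0, rng.uniform(0.0, 30.0, n_mc), np.inf)
        for w in WINDOWS:
            out[f"{fam}_{w}d"] = float(np.mean((day1 <= w).astype(float)
                                               - (day0 <= w).astype(float)))
    return out
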