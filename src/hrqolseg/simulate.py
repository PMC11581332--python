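"""Seeded synthetic MS-registry cohorts for pipeline testing and calibration.

Registry data on persons with MS are not publicly deposited, so this
module generates synthetic cohorts that emulate the published
cohort-level structure of a large national MS registry: the marginal
distributions of demographics, disease characteristics and symptoms;
a strong positive dependence between the two HRQoL instruments
(Spearman ~ 0.74); a ceiling point mass at EQ-5D = 100; covariate
effects of disability and symptom burden on HRQoL; and a small amount
of missingness on five categoricals and BMI, with EDSS observed for
roughly 55% of participants.

Generation model
----------------
1. age ~ truncated normal; disease duration ~ gamma truncated at
   age - 16 (diagnosis at 16 or later); sex and clinical phenotype
   categorical.
2. A latent severity score ``S`` is a linear function of duration and
   phenotype plus standard normal noise, standardised to a z-score
   ``z`` with frozen population constants.
3. The 12 current-symptom flags are Bernoulli(logistic(a_j + b_j z));
   the self-reported disability class (SRDSS) thresholds z; EDSS is a
   monotone affine map of z rounded to the 0-10 half-point grid.
4. Latent HRQoL: E* = P + e and V* = s_vas * P + v where P is the
   covariate linear predictor (disability, benefits, symptoms, small
   age/duration trends) and (e, v) are correlated standard normal
   residuals.  The observed EQ-5D index and VAS are monotone
   rank-quantile maps of E* and V* onto anchor-calibrated target
   marginals; the EQ-5D map is censored above, creating the ceiling
   mass at 100; VAS is rounded to the integer grid.
5. Social covariates, treatments, comorbidities and BMI are drawn from
   calibrated marginals, with a severity gradient where the published
   tables show one (disability benefits, employment, DMT class).

Every random effect used in generation is recorded in the returned
:class:`TruthRecord` so that downstream estimators can be tested for
parameter recovery.  Identical ``(config, seed)`` reproduce the cohort
bit for bit.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "generate_cohort",
    "inject_missingness",
    "default_config",
]

SYMPTOMS = (
    "balance",
    "bladder",
    "depression",
    "fatigue",
    "gait",
    "gastrointestinal",
    "memory",
    "pain",
    "paresthesia",
    "spasms",
    "tremors",
    "muscle_weakness",
)
PHENOTYPES = ("CIS", "PPMS", "RRMS", "SPMS", "unclear")
SRDSS_CLASSES = ("0-3.5", "4-6.5", ">=7")
BENEFIT_LEVELS = ("none", "applied", "receives")
DMT_LEVELS = ("oral", "monoclonal", "injectable", "other", "none")
FIRST_SYMPTOMS = ("visual", "paresthesia", "gait", "spasms")
COMORBIDITIES = ("mononucleosis", "hypertension", "cancer", "diabetes1", "diabetes2", "cardiovascular")
MISSABLE_CATEGORICALS = ("phenotype", "living_situation", "marital_status", "education", "smoking")


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic cohort.

    Loaded from YAML; the packaged default (``data/smsr_like.yaml``)
    encodes the published cohort marginals.  ``covariate_effects`` are
    the recoverable ground-truth effects on the latent HRQoL scale.
    """

    n: int
    seed: int
    age_params: dict
    duration_params: dict
    sex_p_female: float
    phenotype_probs: dict
    severity_loadings: dict
    severity_standardization: dict
    symptom_params: dict
    srdss_thresholds: list
    edss_params: dict
    covariate_effects: dict
    residual_rho: float
    residual_sd: float
    eq5d_marginal: dict
    vas_marginal: dict
    social_params: dict
    missingness: dict
    msss_fraction: float

    def validate(self) -> None:
        if self.n < 2:
            raise ConfigurationError(f"n must be >= 2, got {self.n}")
        if not 0.0 <= self.sex_p_female <= 1.0:
            raise ConfigurationError("sex_p_female must lie in [0, 1]")
        probs = np.array([self.phenotype_probs[p] for p in PHENOTYPES], dtype=float)
        if (probs < 0).any() or (probs > 1).any():
            raise ConfigurationError("phenotype_probs must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"phenotype_probs must sum to 1 within 1e-9, got {probs.sum()!r}"
            )
        if not -1.0 < self.residual_rho < 1.0:
            raise ConfigurationError("residual_rho must lie strictly inside (-1, 1)")
        mass = self.eq5d_marginal["ceiling_mass"]
        if not 0.0 <= mass < 0.5:
            raise ConfigurationError("eq5d_marginal.ceiling_mass must lie in [0, 0.5)")
        if len(self.srdss_thresholds) != 2 or not (
            self.srdss_thresholds[0] < self.srdss_thresholds[1]
        ):
            raise ConfigurationError("srdss_thresholds must be two increasing cutpoints")
        for name in SYMPTOMS:
            if name not in self.symptom_params:
                raise ConfigurationError(f"symptom_params missing symptom {name!r}")
        for var, rate in self.missingness.items():
            if not 0.0 <= float(rate) <= 1.0:
                raise ConfigurationError(f"missingness rate for {var!r} outside [0, 1]")
        if not 0.0 <= self.msss_fraction <= 1.0:
            raise ConfigurationError("msss_fraction must lie in [0, 1]")
        for key, marg in (("eq5d_marginal", self.eq5d_marginal), ("vas_marginal", self.vas_marginal)):
            anchors = np.asarray(marg["anchors"], dtype=float)
            if (np.diff(anchors[:, 0]) <= 0).any() or (np.diff(anchors[:, 1]) < 0).any():
                raise ConfigurationError(f"{key}.anchors must be strictly increasing in p and monotone in value")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw.update(overrides)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def default_config(**overrides) -> GeneratorConfig:
    """The packaged registry-calibrated default configuration."""
    ref = importlib.resources.files("hrqolseg.data") / "smsr_like.yaml"
    with importlib.resources.as_file(ref) as path:
        return GeneratorConfig.from_yaml(path, **overrides)


@dataclass
class TruthRecord:
    """Ground truth retained from a generation run, for recovery tests."""

    seed: int
    covariate_effects: dict
    residual_rho: float
    latent_severity: np.ndarray
    latent_eq5d: np.ndarray
    latent_vas: np.ndarray
    linear_predictor: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "covariate_effects": self.covariate_effects,
            "residual_rho": self.residual_rho,
            "latent_severity": np.asarray(self.latent_severity).tolist(),
            "latent_eq5d": np.asarray(self.latent_eq5d).tolist(),
            "latent_vas": np.asarray(self.latent_vas).tolist(),
            "linear_predictor": np.asarray(self.linear_predictor).tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def _quantile_map(latent: np.ndarray, marginal: dict, *, integer_grid: bool) -> np.ndarray:
    """Monotone rank-quantile map of a latent score onto a target marginal.

    Ranks are converted to plotting positions (r - 0.5)/n and pushed
    through the piecewise-linear anchor quantile function; positions at
    or above 1 - ceiling_mass are censored to the ceiling value.
    """
    n = latent.size
    order = np.argsort(latent, kind="stable")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    p = (ranks - 0.5) / n
    anchors = np.asarray(marginal["anchors"], dtype=float)
    values = np.interp(p, anchors[:, 0], anchors[:, 1])
    mass = float(marginal.get("ceiling_mass", 0.0))
    if mass > 0:
        values = np.where(p >= 1.0 - mass, float(marginal["ceiling_value"]), values)
    if integer_grid:
        values = np.rint(values)
    return values


def _softmax_categorical(rng, levels, base_probs, gammas, z):
    """Categorical draw with log-probability intercepts shifted by a
    severity gradient: p_k(z) proportional to base_k * exp(gamma_k * z)."""
    logp = np.log(np.array([base_probs[k] for k in levels], dtype=float))
    g = np.array([gammas.get(k, 0.0) for k in levels], dtype=float)
    logits = logp[None, :] + z[:, None] * g[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(z.size)
    cum = np.cumsum(probs, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return np.array(levels, dtype=object)[idx]


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw one complete synthetic cohort (no missingness injected).

    Returns the participant table and the :class:`TruthRecord` of latent
    quantities and effects used.  Deterministic given ``(config, seed)``.
    """
    config.validate()
    n = config.n
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))

    # 1. demographics ---------------------------------------------------
    ap = config.age_params
    a, b = (ap["lower"] - ap["loc"]) / ap["scale"], (ap["upper"] - ap["loc"]) / ap["scale"]
    age = stats.truncnorm.ppf(rng.random(n), a, b, loc=ap["loc"], scale=ap["scale"])

    dp = config.duration_params
    gamma = stats.gamma(dp["shape"], scale=dp["scale"])
    max_dur = age - dp["min_age_at_diagnosis"]
    duration = gamma.ppf(rng.random(n) * gamma.cdf(max_dur))

    sex = np.where(rng.random(n) < config.sex_p_female, "female", "male")
    phen_p = np.array([config.phenotype_probs[p] for p in PHENOTYPES])
    phenotype = np.array(PHENOTYPES, dtype=object)[
        (rng.random(n)[:, None] > np.cumsum(phen_p)[None, :]).sum(axis=1)
    ]

    # 2. latent severity ------------------------------------------------
    sl = config.severity_loadings
    phen_eff = np.array([sl["phenotype"][p] for p in phenotype], dtype=float)
    severity = sl["duration"] * duration + phen_eff + rng.normal(0.0, sl["noise_sd"], n)
    std = config.severity_standardization
    z = (severity - std["mean"]) / std["sd"]

    # 3. symptoms, SRDSS, EDSS ------------------------------------------
    symptoms = {}
    for name in SYMPTOMS:
        a_j, b_j = config.symptom_params[name]
        prob = 1.0 / (1.0 + np.exp(-(a_j + b_j * z)))
        symptoms[name] = rng.random(n) < prob
    symptom_count = np.sum([symptoms[s] for s in SYMPTOMS], axis=0)
    symptom_count_class = np.where(
        symptom_count <= 2, "0-2", np.where(symptom_count <= 6, "3-6", ">=7")
    )
    t1, t2 = config.srdss_thresholds
    srdss = np.where(z < t1, SRDSS_CLASSES[0], np.where(z < t2, SRDSS_CLASSES[1], SRDSS_CLASSES[2]))
    ep = config.edss_params
    edss = np.clip(np.round(2.0 * (ep["intercept"] + ep["slope"] * z)) / 2.0, 0.0, 10.0)

    # 4. latent HRQoL ----------------------------------------------------
    eff = config.covariate_effects
    # benefits / employment drawn with a severity gradient first, since
    # benefit status carries its own HRQoL effect
    sp = config.social_params
    benefits = _softmax_categorical(
        rng, BENEFIT_LEVELS, sp["benefit_probs"], sp["benefit_gammas"], z
    )
    emp = sp["employed"]
    employed = rng.random(n) < 1.0 / (1.0 + np.exp(-(emp["intercept"] + emp["gamma"] * z)))

    predictor = (
        eff["age_per_year"] * (age - eff["age_center"])
        + eff["duration_per_year"] * (duration - eff["duration_center"])
        + eff["srdss"]["4-6.5"] * (srdss == SRDSS_CLASSES[1])
        + eff["srdss"][">=7"] * (srdss == SRDSS_CLASSES[2])
        + eff["benefit"]["applied"] * (benefits == "applied")
        + eff["benefit"]["receives"] * (benefits == "receives")
    )
    for name in SYMPTOMS:
        predictor = predictor + eff["symptoms"][name] * symptoms[name]

    rho = config.residual_rho
    sd = config.residual_sd
    eps = rng.multivariate_normal(
        [0.0, 0.0], [[sd**2, rho * sd**2], [rho * sd**2, sd**2]], size=n
    )
    latent_eq = predictor + eps[:, 0]
    latent_vas = eff["vas_scale"] * predictor + eps[:, 1]

    eq5d = _quantile_map(latent_eq, config.eq5d_marginal, integer_grid=False)
    vas = _quantile_map(latent_vas, config.vas_marginal, integer_grid=True)

    # 5. remaining covariates -------------------------------------------
    citizen = rng.random(n) < sp["citizen_p"]
    education = _softmax_categorical(rng, list(sp["education_probs"]), sp["education_probs"], {}, z)
    living = _softmax_categorical(rng, list(sp["living_probs"]), sp["living_probs"], {}, z)
    marital = _softmax_categorical(rng, list(sp["marital_probs"]), sp["marital_probs"], {}, z)
    smoking = _softmax_categorical(rng, list(sp["smoking_probs"]), sp["smoking_probs"], {}, z)
    dmt = _softmax_categorical(rng, DMT_LEVELS, sp["dmt_probs"], sp["dmt_gammas"], z)
    first_sym = {}
    for name in FIRST_SYMPTOMS:
        pr, g = sp["first_symptom_params"][name]
        first_sym[name] = rng.random(n) < 1.0 / (
            1.0 + np.exp(-(np.log(pr / (1 - pr)) + g * z))
        )
    family_ms = rng.random(n) < sp["family_ms_p"]
    comorb = {c: rng.random(n) < sp["comorbidity_probs"][c] for c in COMORBIDITIES}
    bp = sp["bmi_params"]
    bmi_w = bp["severity_loading"] * z + np.sqrt(1 - bp["severity_loading"] ** 2) * rng.normal(
        0.0, 1.0, n
    )
    bmi = np.exp(np.log(bp["median"]) + bp["log_sd"] * bmi_w)

    # survey date: one cross-sectional measurement per participant
    date = pd.Timestamp("2022-06-30").toordinal() - rng.integers(0, 365, n)

    table = pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "measurement_date": date,
            "age_years": age,
            "years_since_diagnosis": duration,
            "sex": sex,
            "phenotype": phenotype,
            "srdss_class": srdss,
            **{f"symptom_{s}": symptoms[s].astype(int) for s in SYMPTOMS},
            "symptom_count_class": symptom_count_class,
            "disability_benefit": benefits,
            "employed": employed.astype(int),
            "swiss_citizen": citizen.astype(int),
            "education": education,
            "living_situation": living,
            "marital_status": marital,
            "smoking": smoking,
            "dmt_class": dmt,
            **{f"first_symptom_{s}": first_sym[s].astype(int) for s in FIRST_SYMPTOMS},
            "family_ms": family_ms.astype(int),
            **{f"comorbidity_{c}": comorb[c].astype(int) for c in COMORBIDITIES},
            "bmi": np.round(bmi, 1),
            "edss": edss,
            "eq5d_index": np.round(eq5d, 1),
            "vas": vas.astype(int),
        }
    )
    truth = TruthRecord(
        seed=int(config.seed),
        covariate_effects=eff,
        residual_rho=rho,
        latent_severity=z,
        latent_eq5d=latent_eq,
        latent_vas=latent_vas,
        linear_predictor=predictor,
    )
    return table, truth


def inject_missingness(table: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Set values missing completely at random at the configured rates.

    Five categoricals and BMI go missing independently at their
    per-variable rates; EDSS is retained with probability
    ``msss_fraction`` (emulating partial registry linkage).  Age,
    duration and the HRQoL scores are never missing, matching the
    study's inclusion criteria.
    """
    config.validate()
    out = table.copy()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    n = len(out)
    for var in MISSABLE_CATEGORICALS + ("bmi",):
        rate = float(config.missingness.get(var, 0.0))
        if rate > 0.0:
            mask = rng.random(n) < rate
            out.loc[mask, var] = np.nan if var == "bmi" else pd.NA
    keep = rng.random(n) < config.msss_fraction
    out.loc[~keep, "edss"] = np.nan
    return out
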