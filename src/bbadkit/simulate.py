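"""Synthetic memory-clinic cohorts with prescribed group structure.

The generator emulates a cross-sectional cohort labeled by a CSF amyloid
reference standard: fixed group sizes (A-/A+), group-specific demographics,
and biomarker concentrations drawn from moment-matched lognormal (or
normal) families coupled through a latent Gaussian factor copula.  The CSF
Abeta42/40 ratio — the quantity that *defines* the reference label — is
drawn per group from a one-sided truncated normal whose parent parameters
are solved so the truncated distribution has exactly the requested mean and
SD; classification of the generated ratio therefore reproduces the assigned
groups with no label noise.

Randomness discipline: one integer seed governs everything.  Every draw for
subject ``i`` comes from a counter-based substream keyed by ``(i, stream)``
where ``stream`` hashes the purpose ("demographics", "noise:<biomarker>",
...), so adding a biomarker to the configuration does not perturb any other
biomarker's values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats

from .cohort import CohortTable

__all__ = [
    "BiomarkerSpec",
    "AmyloidRatioSpec",
    "GroupMoments",
    "GeneratorConfig",
    "default_config",
    "load_config",
    "lognormal_from_moments",
    "truncated_normal_from_moments",
    "inject_outliers",
    "generate_cohort",
]


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Parameters (mu, sigma) of the lognormal with the given mean and SD.

    Closed form: sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2/2.
    ``sd = 0`` is the degenerate point mass (sigma = 0, mu = ln mean).
    """
    if mean <= 0 or sd < 0:
        raise ValueError(f"need mean > 0 and sd >= 0, got mean={mean}, sd={sd}")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def truncated_normal_from_moments(mean: float, sd: float,
                                  lower: float = -np.inf,
                                  upper: float = np.inf) -> tuple[float, float]:
    """Parent (m, s) of a truncated normal with given post-truncation moments.

    Finds the normal N(m, s^2) such that its restriction to (lower, upper)
    has exactly ``mean`` and ``sd``.  Used for the label-defining amyloid
    ratio, where naive truncation of N(mean, sd^2) would bias the group
    moments beyond Monte-Carlo error.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not (lower < mean < upper):
        raise ValueError(
            f"target mean {mean} must lie inside the truncation interval "
            f"({lower}, {upper})")

    def resid(p):
        m, log_s = p
        s = np.exp(log_s)
        a, b = (lower - m) / s, (upper - m) / s
        tm, tv = stats.truncnorm.stats(a, b, loc=m, scale=s, moments="mv")
        return [float(tm) - mean, float(np.sqrt(tv)) - sd]

    tol = 1e-9 * max(abs(mean), sd)
    # a handful of starts: the objective is smooth but the feasible region
    # narrows sharply when the target mean approaches a finite bound
    starts = [(mean, np.log(sd)), (mean, np.log(sd * 2)),
              (mean + sd, np.log(sd)), (mean - sd, np.log(sd)),
              (mean, np.log(sd / 2))]
    for x0 in starts:
        sol = optimize.least_squares(resid, x0=x0, xtol=1e-15, ftol=1e-15,
                                     gtol=1e-15)
        if max(abs(r) for r in resid(sol.x)) <= tol:
            return float(sol.x[0]), float(np.exp(sol.x[1]))
    raise ValueError(
        f"cannot moment-match truncated normal (mean={mean}, sd={sd}, "
        f"interval=({lower}, {upper})); the target moments may be "
        f"unreachable within this family")


def inject_outliers(values: np.ndarray, rate: float, scale: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Multiply (or divide, with equal probability) a Bernoulli subset by ``scale``.

    Emulates the heavy-tailed excursions seen in plasma amyloid assays.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if scale < 1.0:
        raise ValueError(f"scale must be >= 1, got {scale}")
    values = np.asarray(values, dtype=float)
    out = values.copy()
    hit = rng.random(values.shape) < rate
    up = rng.random(values.shape) < 0.5
    out[hit & up] *= scale
    out[hit & ~up] /= scale
    return out


def _outlier_multiplier_moments(rate: float, scale: float) -> tuple[float, float]:
    """E[M] and E[M^2] of the outlier multiplier (1, scale or 1/scale)."""
    em = 1.0 - rate + rate * (scale + 1.0 / scale) / 2.0
    em2 = 1.0 - rate + rate * (scale ** 2 + scale ** -2) / 2.0
    return em, em2


@dataclass(frozen=True)
class GroupMoments:
    mean_neg: float
    sd_neg: float
    mean_pos: float
    sd_pos: float

    def moments(self, positive: bool) -> tuple[float, float]:
        return ((self.mean_pos, self.sd_pos) if positive
                else (self.mean_neg, self.sd_neg))


@dataclass(frozen=True)
class BiomarkerSpec:
    """Per-group moments and sampling family of one biomarker (pg/ml)."""

    name: str
    mean_neg: float
    sd_neg: float
    mean_pos: float
    sd_pos: float
    family: str = "lognormal"          # "lognormal" | "normal"
    family_group: str = "other"        # copula family: amyloid/tau/neuro/...
    outlier_rate: float = 0.0
    outlier_scale: float = 1.0

    def __post_init__(self):
        if min(self.sd_neg, self.sd_pos) <= 0:
            raise ValueError(f"{self.name}: sds must be positive")
        if min(self.mean_neg, self.mean_pos) <= 0:
            raise ValueError(f"{self.name}: means must be positive")
        if not 0.0 <= self.outlier_rate <= 0.2:
            raise ValueError(f"{self.name}: outlier_rate must be in [0, 0.2]")
        if self.family not in {"lognormal", "normal"}:
            raise ValueError(f"{self.name}: unknown family {self.family!r}")

    def moments(self, positive: bool) -> tuple[float, float]:
        return ((self.mean_pos, self.sd_pos) if positive
                else (self.mean_neg, self.sd_neg))


@dataclass(frozen=True)
class AmyloidRatioSpec:
    """Label-defining CSF Abeta42/40 ratio: truncated-normal per group."""

    cutoff: float = 0.069
    mean_neg: float = 0.09332
    sd_neg: float = 0.010
    mean_pos: float = 0.04459
    sd_pos: float = 0.010

    def moments(self, positive: bool) -> tuple[float, float]:
        return ((self.mean_pos, self.sd_pos) if positive
                else (self.mean_neg, self.sd_neg))


@dataclass
class GeneratorConfig:
    n_neg: int = 33
    n_pos: int = 69
    age: GroupMoments = field(default_factory=lambda: GroupMoments(66.9, 8.6, 73.0, 6.1))
    education: GroupMoments = field(default_factory=lambda: GroupMoments(10.4, 3.1, 9.4, 4.2))
    mmse: GroupMoments = field(default_factory=lambda: GroupMoments(24.2, 4.16, 22.4, 4.21))
    male_fraction: tuple[float, float] = (0.364, 0.551)            # (neg, pos)
    apoe_e4_carrier_fraction: tuple[float, float] = (0.182, 0.493)
    missing_diagnosis_rate: tuple[float, float] = (0.242, 0.029)
    mci_fraction_given_known: tuple[float, float] = (0.360, 0.507)
    amyloid_ratio: AmyloidRatioSpec = field(default_factory=AmyloidRatioSpec)
    biomarkers: Sequence[BiomarkerSpec] = ()
    rho_global: float = 0.3
    rho_family: float = 0.7
    #: optional structural MMSE model, e.g.
    #: {"intercept": 24, "mci_effect": 2, "slopes": {"plasma_ptau217": -2}, "sd": 2}
    mmse_model: dict | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n_neg < 2 or self.n_pos < 2:
            raise ValueError("need at least 2 subjects per group")
        for name, pair in (("male_fraction", self.male_fraction),
                           ("apoe_e4_carrier_fraction", self.apoe_e4_carrier_fraction),
                           ("missing_diagnosis_rate", self.missing_diagnosis_rate),
                           ("mci_fraction_given_known", self.mci_fraction_given_known)):
            if not all(0.0 <= p <= 1.0 for p in pair):
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
        if not (0.0 <= self.rho_global <= self.rho_family <= 1.0):
            raise ValueError(
                "need 0 <= rho_global <= rho_family <= 1 for a valid "
                "factor correlation structure")


def _config_from_dict(doc: dict) -> GeneratorConfig:
    demo = doc.get("demographics", {})

    def gm(key, default):
        if key not in demo:
            return default
        d = demo[key]
        return GroupMoments(d["mean_neg"], d["sd_neg"], d["mean_pos"], d["sd_pos"])

    def pair(key, default):
        if key not in demo:
            return default
        return (demo[key]["neg"], demo[key]["pos"])

    ar = doc.get("amyloid_ratio", {})
    corr = doc.get("correlation", {})
    specs = tuple(
        BiomarkerSpec(
            name=b["name"],
            mean_neg=b["mean_neg"], sd_neg=b["sd_neg"],
            mean_pos=b["mean_pos"], sd_pos=b["sd_pos"],
            family=b.get("distribution", "lognormal"),
            family_group=b.get("family", "other"),
            outlier_rate=b.get("outlier_rate", 0.0),
            outlier_scale=b.get("outlier_scale", 1.0),
        )
        for b in doc.get("biomarkers", ())
    )
    return GeneratorConfig(
        n_neg=doc.get("n_neg", 33),
        n_pos=doc.get("n_pos", 69),
        age=gm("age", GroupMoments(66.9, 8.6, 73.0, 6.1)),
        education=gm("education", GroupMoments(10.4, 3.1, 9.4, 4.2)),
        mmse=gm("mmse", GroupMoments(24.2, 4.16, 22.4, 4.21)),
        male_fraction=pair("male_fraction", (0.364, 0.551)),
        apoe_e4_carrier_fraction=pair("apoe_e4_carrier_fraction", (0.182, 0.493)),
        missing_diagnosis_rate=pair("missing_diagnosis_rate", (0.242, 0.029)),
        mci_fraction_given_known=pair("mci_fraction_given_known", (0.360, 0.507)),
        amyloid_ratio=AmyloidRatioSpec(
            cutoff=ar.get("cutoff", 0.069),
            mean_neg=ar.get("mean_neg", 0.09332), sd_neg=ar.get("sd_neg", 0.010),
            mean_pos=ar.get("mean_pos", 0.04459), sd_pos=ar.get("sd_pos", 0.010)),
        rho_global=corr.get("rho_global", 0.3),
        rho_family=corr.get("rho_family", 0.7),
        biomarkers=specs,
        mmse_model=doc.get("mmse_model"),
        seed=doc.get("seed"),
    )


def load_config(path) -> GeneratorConfig:
    """Load a generator configuration from YAML."""
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh))


def default_config() -> GeneratorConfig:
    """The shipped configuration matching the study's summary tables."""
    text = resources.files("bbadkit").joinpath("data/table12_default.yaml").read_text()
    return _config_from_dict(yaml.safe_load(text))


def _stream(seed: int, subject: int, purpose: str) -> np.random.Generator:
    key = zlib.crc32(purpose.encode())
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(subject, key)))


def generate_cohort(config: GeneratorConfig | None = None,
                    seed: int | None = None) -> CohortTable:
    """Draw one cohort; fully reproducible given the seed.

    The first ``n_neg`` subjects are amyloid-negative, the rest positive;
    classifying the generated CSF Abeta42/40 ratio against the configured
    cut-off recovers these groups exactly by construction.
    """
    if config is None:
        config = default_config()
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (config.seed or the seed argument)")
    seed = int(seed)

    n = config.n_neg + config.n_pos
    positive = np.zeros(n, dtype=bool)
    positive[config.n_neg:] = True

    families = sorted({s.family_group for s in config.biomarkers} | {"amyloid"})
    a_g = np.sqrt(config.rho_global)
    a_f = np.sqrt(config.rho_family - config.rho_global)
    a_e = np.sqrt(1.0 - config.rho_family)

    # latent standard normals, one substream per (subject, purpose)
    g_global = np.empty(n)
    g_family = {f: np.empty(n) for f in families}
    eps = {s.name: np.empty(n) for s in config.biomarkers}
    eps_ratio = np.empty(n)
    demo_u = np.empty((n, 4))    # sex, apoe, dx-missing, dx-mci
    demo_z = np.empty((n, 3))    # age, education, mmse noise
    out_u = {s.name: np.empty((n, 2)) for s in config.biomarkers
             if s.outlier_rate > 0}
    for i in range(n):
        g_global[i] = _stream(seed, i, "factor:global").standard_normal()
        for f in families:
            g_family[f][i] = _stream(seed, i, f"factor:{f}").standard_normal()
        for s in config.biomarkers:
            eps[s.name][i] = _stream(seed, i, f"noise:{s.name}").standard_normal()
        eps_ratio[i] = _stream(seed, i, "noise:csf_ab42_40").standard_normal()
        d = _stream(seed, i, "demographics")
        demo_u[i] = d.random(4)
        demo_z[i] = d.standard_normal(3)
        for name in out_u:
            out_u[name][i] = _stream(seed, i, f"outlier:{name}").random(2)

    def latent(family_group: str, e: np.ndarray) -> np.ndarray:
        return a_g * g_global + a_f * g_family[family_group] + a_e * e

    data: dict[str, np.ndarray] = {}

    # label-defining CSF Abeta42/40 ratio: truncated normal per group,
    # moment-matched after truncation, sampled by inverse CDF
    ratio = np.empty(n)
    z_ratio = latent("amyloid", eps_ratio)
    for positive_group in (False, True):
        mean, sd = config.amyloid_ratio.moments(positive_group)
        cut = config.amyloid_ratio.cutoff
        lo, hi = ((0.0, cut) if positive_group else (cut, np.inf))
        if not (lo < mean < hi):
            raise ValueError(
                f"amyloid ratio group mean {mean} lies on the wrong side of "
                f"the cut-off {cut}")
        m, s = truncated_normal_from_moments(mean, sd, lo, hi)
        a, b = (lo - m) / s, (hi - m) / s
        mask = positive == positive_group
        u = special.ndtr(z_ratio[mask])
        ratio[mask] = stats.truncnorm.ppf(u, a, b, loc=m, scale=s)

    for spec in config.biomarkers:
        z = latent(spec.family_group, eps[spec.name])
        x = np.empty(n)
        for positive_group in (False, True):
            mean, sd = spec.moments(positive_group)
            if spec.outlier_rate > 0:
                em, em2 = _outlier_multiplier_moments(
                    spec.outlier_rate, spec.outlier_scale)
                pre_mean = mean / em
                pre_var = (sd ** 2 + mean ** 2) / em2 - pre_mean ** 2
                if pre_var <= 0:
                    raise ValueError(
                        f"{spec.name}: outlier settings incompatible with "
                        f"target moments")
                mean, sd = pre_mean, np.sqrt(pre_var)
            mask = positive == positive_group
            if spec.family == "lognormal":
                mu, sigma = lognormal_from_moments(mean, sd)
                x[mask] = np.exp(mu + sigma * z[mask])
            else:
                x[mask] = mean + sd * z[mask]
        if spec.outlier_rate > 0:
            u = out_u[spec.name]
            hit = u[:, 0] < spec.outlier_rate
            up = u[:, 1] < 0.5
            x[hit & up] *= spec.outlier_scale
            x[hit & ~up] /= spec.outlier_scale
        data[spec.name] = x

    if "csf_ab40" not in data:
        raise ValueError("configuration must include csf_ab40 (csf_ab42 is "
                         "derived as ratio * csf_ab40)")
    data["csf_ab42"] = ratio * data["csf_ab40"]

    # demographics
    def group_param(pair):
        return np.where(positive, pair[1], pair[0])

    sex = np.where(demo_u[:, 0] < group_param(config.male_fraction),
                   "male", "female")
    apoe = np.where(demo_u[:, 1] < group_param(config.apoe_e4_carrier_fraction),
                    "carrier", "noncarrier")
    true_mci = demo_u[:, 3] < group_param(config.mci_fraction_given_known)
    dx_missing = demo_u[:, 2] < group_param(config.missing_diagnosis_rate)
    diagnosis = np.where(true_mci, "MCI", "dementia").astype(object)
    diagnosis[dx_missing] = np.nan

    age_m = np.where(positive, config.age.mean_pos, config.age.mean_neg)
    age_s = np.where(positive, config.age.sd_pos, config.age.sd_neg)
    age = age_m + age_s * demo_z[:, 0]
    edu_m = np.where(positive, config.education.mean_pos, config.education.mean_neg)
    edu_s = np.where(positive, config.education.sd_pos, config.education.sd_neg)
    education = np.clip(edu_m + edu_s * demo_z[:, 1], 0.0, None)

    if config.mmse_model:
        mm = config.mmse_model
        mmse = np.full(n, float(mm.get("intercept", 24.0)))
        mmse += float(mm.get("mci_effect", 0.0)) * true_mci
        for name, slope in mm.get("slopes", {}).items():
            mmse += float(slope) * data[name]
        mmse += float(mm.get("sd", 2.0)) * demo_z[:, 2]
    else:
        mm_m = np.where(positive, config.mmse.mean_pos, config.mmse.mean_neg)
        mm_s = np.where(positive, config.mmse.sd_pos, config.mmse.sd_neg)
        mmse = mm_m + mm_s * demo_z[:, 2]
    mmse = np.clip(mmse, 0.0, 30.0)

    df = pd.DataFrame({
        "id": [f"S{i + 1:04d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "education": education,
        "mmse": mmse,
        "apoe_e4": apoe,
        "diagnosis": diagnosis,
        "csf_ab42": data["csf_ab42"],
        "csf_ab40": data["csf_ab40"],
        "csf_ttau": data["csf_ttau"],
        "csf_ptau181": data["csf_ptau181"],
        "plasma_ab42": data["plasma_ab42"],
        "plasma_ab40": data["plasma_ab40"],
        "plasma_ptau181": data["plasma_ptau181"],
        "plasma_ptau217": data["plasma_ptau217"],
        "plasma_nfl": data["plasma_nfl"],
    })
    return CohortTable(df)
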