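"""Synthetic cohort generator emulating a CyTOF CAD case-control study.

The generator produces discovery/validation cohorts with the structure the
downstream analysis assumes:

* ages truncated-normal, sex Bernoulli;
* CAD label drawn from a logistic model in age and sex, so that older male
  patients are more likely CAD+ (the confounding the adjusted models must
  undo);
* 82 subset proportions (11 major populations as % of total live cells plus
  71 marker-defined subsets as % of their parent population), each drawn
  logit-normally with a CAD shift ``delta``, an age trend ``gamma`` (per
  decade) and, for the validation cohort, an additive batch shift;
* risk-factor and medication booleans with age-dependent prevalences.

Default subset baselines and CAD shifts for the 18 headline subsets are set
from the group means and SDs of the motivating cohort, so the implied
per-percent odds ratios span roughly 1.05-1.25.  For conventional CD4/CD8
T-cell subsets most of the marginal CAD association is routed through the
age trend (so age/sex adjustment attenuates it); for Treg, B-cell and pDC
subsets it is carried by the CAD shift itself (so adjustment leaves it
largely intact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .datatypes import (
    BOOL_FIELDS,
    MAJOR_POPULATIONS,
    PatientRecord,
    ProportionsMatrix,
    SubsetCatalog,
    SubsetDefinition,
    ValidationError,
)

import pandas as pd

# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

# (id-suffix, label, parent, CAD- mean %, CAD+ mean %, CAD- SD, CAD+ SD)
# The 18 headline subsets: 15 T-cell, 2 B-cell, and pDC (% of total live).
_HEADLINE_PARENT = [
    ("tconv_naive", "Tconv naive", "CD4 Tconv", 45.4, 37.9, 15.4, 14.0),
    ("tconv_tem", "Tconv TEM", "CD4 Tconv", 24.7, 31.7, 11.6, 12.9),
    ("tconv_ccr2", "Tconv CCR2+", "CD4 Tconv", 20.8, 24.2, 8.7, 9.5),
    ("tconv_ccr4", "Tconv CCR4+", "CD4 Tconv", 24.2, 28.4, 8.6, 8.7),
    ("tconv_klrg1_cd27neg", "Tconv KLRG1+CD27-", "CD4 Tconv", 7.3, 13.4, 7.4, 13.0),
    ("treg_ccr2", "Treg CCR2+", "Treg", 14.7, 17.9, 5.9, 5.3),
    ("treg_ccr4", "Treg CCR4+", "Treg", 64.1, 73.7, 14.1, 9.2),
    ("treg_ccr6", "Treg CCR6+", "Treg", 10.1, 13.1, 5.7, 6.8),
    ("treg_cd38_cd45ro", "Treg CD38+CD45RO+", "Treg", 9.7, 11.5, 3.6, 4.3),
    ("treg_cd39", "Treg CD39+", "Treg", 43.2, 53.8, 21.6, 20.5),
    ("treg_hladr", "Treg HLA-DR+", "Treg", 12.3, 15.1, 6.7, 7.1),
    ("treg_ki67", "Treg Ki67+", "Treg", 7.0, 9.2, 2.9, 4.2),
    ("cd8_naive", "CD8 naive", "CD8 T cells", 21.1, 13.7, 14.2, 10.7),
    ("cd8_cd56", "CD8 CD56+", "CD8 T cells", 8.8, 12.7, 7.6, 8.9),
    ("cd8_klrg1_cd27neg", "CD8 KLRG1+CD27-", "CD8 T cells", 30.2, 38.7, 16.4, 20.5),
    ("b_cxcr3", "B CXCR3+", "B cells", 4.0, 5.5, 3.1, 4.0),
    ("b_ki67", "B Ki67+", "B cells", 0.5, 0.8, 0.3, 0.7),
]

#: Populations whose marginal CAD association is mostly an age effect.
_AGE_DRIVEN = {"CD4 Tconv", "CD8 T cells"}

# major population, baseline % of total live cells; pDC carries a CAD shift
_MAJOR_BASELINES = {
    "CD4 Tconv": 25.0,
    "Treg": 2.5,
    "CD8 T cells": 15.0,
    "gd T cells": 2.0,
    "NKT cells": 1.5,
    "B cells": 10.0,
    "NK cells": 10.0,
    "Monocytes": 18.0,
    "pDC": 2.8,  # CAD- mean; CAD+ mean 2.0
    "mDC": 1.5,
    "Basophils": 0.5,
}

# filler %parent subsets per population (marker labels, no planted CAD shift)
_FILLER_MARKERS = {
    "CD4 Tconv": ["TCM", "TEMRA", "CCR6+", "CXCR3+", "KLRG1+", "PD-1+", "Ki67+"],
    "Treg": ["naive", "memory", "CCR6+CCR4+", "CD45RA+", "CTLA-4+"],
    "CD8 T cells": ["TCM", "TEM", "TEMRA", "CCR4+", "KLRG1+", "PD-1+", "Ki67+"],
    "gd T cells": ["Vd2+", "CD27+", "CD57+", "Ki67+", "CCR6+"],
    "NKT cells": ["CD4+", "CD8+", "CD57+", "Ki67+"],
    "B cells": ["naive", "memory", "CD27+IgD-", "transitional", "plasmablast", "CD5+"],
    "NK cells": ["CD56bright", "CD56dim", "CD57+", "CD16+", "NKG2A+", "Ki67+", "CD8+"],
    "Monocytes": ["classical", "intermediate", "non-classical", "CCR2+", "HLA-DRhi", "CD9+", "Ki67+"],
    "pDC": ["CD2+", "Ki67+"],
    "mDC": ["CD1c+", "CD141+"],
    "Basophils": ["CD63+", "FcER1hi"],
}

_FILLER_MEANS = (3.0, 6.0, 10.0, 15.0, 22.0, 30.0, 40.0, 55.0)

HEADLINE_SUBSETS: tuple[str, ...] = tuple(
    s[0] for s in _HEADLINE_PARENT
) + ("pdc",)


def _pop_id(name: str) -> str:
    return name.lower().replace(" ", "_").replace("-", "_").replace("+", "")


def default_catalog() -> SubsetCatalog:
    """The 82-subset catalog: 11 %total major populations + 71 %parent subsets."""
    subsets = []
    for pop in MAJOR_POPULATIONS:
        subsets.append(
            SubsetDefinition(_pop_id(pop), f"{pop} (%total)", pop, "total_live")
        )
    for sid, label, pop, *_ in _HEADLINE_PARENT:
        subsets.append(SubsetDefinition(sid, label, pop, "parent_population"))
    for pop, markers in _FILLER_MARKERS.items():
        for marker in markers:
            sid = f"{_pop_id(pop)}_{_pop_id(marker).replace('.', '')}"
            subsets.append(
                SubsetDefinition(sid, f"{pop} {marker}", pop, "parent_population")
            )
    return SubsetCatalog(subsets)


# ---------------------------------------------------------------------------
# simulation config
# ---------------------------------------------------------------------------


@dataclass
class SubsetParams:
    """Logit-scale generative parameters for one subset."""

    mu: float  # baseline mean on logit scale
    sigma: float  # between-patient SD on logit scale
    delta: float = 0.0  # additive shift when CAD+
    gamma: float = 0.0  # additive shift per decade of age above the mean

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class LabelModel:
    """logit P(CAD) = beta0 + beta_age * (age - age_mean)/10 + beta_sex * male."""

    beta0: float = 0.45
    beta_age: float = 1.0
    beta_sex: float = 1.0


@dataclass
class SimConfig:
    n_discovery: int = 117
    n_validation: int = 58
    age_mean: float = 61.0
    age_sd: float = 12.0
    age_bounds: tuple[float, float] = (30.0, 95.0)
    p_male: float = 0.49
    label_model: LabelModel = field(default_factory=LabelModel)
    subset_params: dict[str, SubsetParams] = field(default_factory=dict)
    batch_shift: float = -0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_male < 1:
            raise ValidationError("p_male must be in (0,1)")
        if self.n_discovery < 10 or self.n_validation < 10:
            raise ValidationError("cohort sizes must be >= 10")
        if self.age_sd <= 0:
            raise ValidationError("age_sd must be > 0")
        if not self.subset_params:
            self.subset_params = default_subset_params()

    def spawn_seeds(self) -> tuple[int, int]:
        ss = np.random.SeedSequence(self.seed)
        d, v = ss.spawn(2)
        return int(d.generate_state(1)[0] % 2**31), int(v.generate_state(1)[0] % 2**31)


def _logit_params(m0: float, m1: float, s0: float, s1: float) -> tuple[float, float, float]:
    """Map CAD-/CAD+ percent means and SDs to (mu, sigma, total logit shift).

    Uses the delta-method SD on the logit scale, averaged over the two
    groups; mu anchors at the CAD- mean.
    """
    p0, p1 = m0 / 100.0, m1 / 100.0
    mu = logit(p0)
    shift = logit(p1) - logit(p0)
    sig0 = (s0 / 100.0) / (p0 * (1 - p0))
    sig1 = (s1 / 100.0) / (p1 * (1 - p1))
    return mu, 0.5 * (sig0 + sig1), shift


#: mean age gap (decades) between CAD+ and CAD- under the default label model
_AGE_GAP_DECADES = 1.05


def default_subset_params() -> dict[str, SubsetParams]:
    params: dict[str, SubsetParams] = {}
    # major populations (%total): no CAD shift except pDC
    for pop, base in _MAJOR_BASELINES.items():
        sid = _pop_id(pop)
        if pop == "pDC":
            mu, sigma, shift = _logit_params(2.8, 2.0, 2.1, 1.3)
            # pDC association survives adjustment only partially
            delta = 0.7 * shift
            gamma = 0.3 * shift / _AGE_GAP_DECADES
        else:
            p = base / 100.0
            mu, sigma = logit(p), 0.45
            delta, gamma = 0.0, 0.0
        params[sid] = SubsetParams(mu, sigma, delta, gamma)
    # headline %parent subsets with planted effects
    for sid, _label, pop, m0, m1, s0, s1 in _HEADLINE_PARENT:
        mu, sigma, shift = _logit_params(m0, m1, s0, s1)
        if pop in _AGE_DRIVEN:
            delta = 0.3 * shift
            gamma = 0.7 * shift / _AGE_GAP_DECADES
        else:
            delta = 0.85 * shift
            gamma = 0.15 * shift / _AGE_GAP_DECADES
        params[sid] = SubsetParams(mu, sigma, delta, gamma)
    # filler subsets: cycling baselines, mild alternating age trends, no CAD shift
    i = 0
    for pop, markers in _FILLER_MARKERS.items():
        for marker in markers:
            sid = f"{_pop_id(pop)}_{_pop_id(marker).replace('.', '')}"
            mean = _FILLER_MEANS[i % len(_FILLER_MEANS)]
            gamma = (0.0, 0.08, -0.08)[i % 3]
            params[sid] = SubsetParams(logit(mean / 100.0), 0.5, 0.0, gamma)
            i += 1
    return params


@dataclass
class SyntheticCohort:
    records: list[PatientRecord]
    proportions: ProportionsMatrix
    truth: SimConfig


# age-dependent prevalence (baseline at the mean age, logit slope per decade)
_RISK_PREVALENCE = {
    "hypertension": (0.43, 0.55),
    "diabetes": (0.07, 0.40),
    "hyperlipidaemia": (0.53, 0.50),
    "current_smoking": (0.11, -0.20),
    "smoking_history_gt10py": (0.20, 0.30),
    "family_history": (0.28, 0.00),
    "statin": (0.33, 0.60),
    "ace_arb": (0.35, 0.60),
    "antiplatelet": (0.20, 0.40),
    "beta_blocker": (0.16, 0.40),
}


def _draw_ages(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.age_bounds
    a = (lo - cfg.age_mean) / cfg.age_sd
    b = (hi - cfg.age_mean) / cfg.age_sd
    return stats.truncnorm.rvs(
        a, b, loc=cfg.age_mean, scale=cfg.age_sd, size=n, random_state=rng
    )


def generate_single_cohort(
    cfg: SimConfig,
    cohort: str,
    n: int,
    seed: int,
    catalog: SubsetCatalog | None = None,
) -> SyntheticCohort:
    """Generate one cohort; the validation cohort receives the batch shift."""
    if catalog is None:
        catalog = default_catalog()
    rng = np.random.default_rng(seed)
    ages = _draw_ages(cfg, n, rng)
    male = rng.random(n) < cfg.p_male
    adec = (ages - cfg.age_mean) / 10.0
    lm = cfg.label_model
    p_cad = expit(lm.beta0 + lm.beta_age * adec + lm.beta_sex * male)
    cad = rng.random(n) < p_cad

    batch = cfg.batch_shift if cohort == "validation" else 0.0
    cols = {}
    for sid in catalog.subset_ids:
        sp = cfg.subset_params[sid]
        z = (
            sp.mu
            + sp.delta * cad
            + sp.gamma * adec
            + batch
            + sp.sigma * rng.standard_normal(n)
        )
        cols[sid] = 100.0 * expit(z)
    prefix = "D" if cohort == "discovery" else "V"
    ids = [f"{prefix}{i + 1:03d}" for i in range(n)]
    values = pd.DataFrame(cols, index=ids)

    # compositional repair: rescale %total rows whose sum exceeds 100
    total_ids = catalog.total_live_ids()
    sums = values[total_ids].sum(axis=1)
    over = sums > 100.0
    if over.any():
        scale = (100.0 / sums[over]).to_numpy()[:, None]
        values.loc[over, total_ids] = values.loc[over, total_ids].to_numpy() * scale

    bools = {
        name: rng.random(n) < expit(logit(base) + slope * adec)
        for name, (base, slope) in _RISK_PREVALENCE.items()
    }
    bmi = np.clip(rng.normal(27.1, 4.8, size=n), 17.0, 45.0)
    gensini = np.where(cad, np.exp(rng.normal(np.log(7.5), 1.0, size=n)), 0.0)

    records = [
        PatientRecord(
            patient_id=ids[i],
            age=float(np.round(ages[i], 1)),
            sex="male" if male[i] else "female",
            **{b: bool(bools[b][i]) for b in BOOL_FIELDS},
            gensini=float(np.round(gensini[i], 2)),
            cohort=cohort,
            bmi=float(np.round(bmi[i], 1)),
        )
        for i in range(n)
    ]
    matrix = ProportionsMatrix(values)
    matrix.validate_against(catalog)
    return SyntheticCohort(records, matrix, cfg)


def generate_cohort(
    cfg: SimConfig, catalog: SubsetCatalog | None = None
) -> SyntheticCohort:
    """Generate the combined discovery + validation study population."""
    if catalog is None:
        catalog = default_catalog()
    seed_d, seed_v = cfg.spawn_seeds()
    disc = generate_single_cohort(cfg, "discovery", cfg.n_discovery, seed_d, catalog)
    vali = generate_single_cohort(cfg, "validation", cfg.n_validation, seed_v, catalog)
    records = disc.records + vali.records
    values = pd.concat([disc.proportions.values, vali.proportions.values])
    return SyntheticCohort(records, ProportionsMatrix(values), cfg)


# ---------------------------------------------------------------------------
# implied (planted) odds ratios
# ---------------------------------------------------------------------------


def _weighted_logistic_slope(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted 2-parameter logistic MLE slope by Newton iteration."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(100):
        eta = X @ beta
        p = expit(eta)
        grad = X.T @ (w * (y - p))
        W = w * p * (1 - p)
        H = X.T @ (X * W[:, None])
        step = np.linalg.solve(H, grad)
        beta += step
        if np.max(np.abs(grad)) < 1e-10:
            break
    return float(beta[1])


def planted_or(
    cfg: SimConfig,
    subset_id: str,
    cohort: str = "discovery",
    n_quad: int = 200_000,
) -> float:
    """Large-sample per-percent odds ratio implied by the generative model.

    Computed by numerical integration: covariates are sampled on a fixed
    quasi-random stream, each draw is split into CAD-/CAD+ branches weighted
    by the label-model probability, and the population logistic slope is
    obtained from the weighted score equations.  Deterministic for a given
    config (the integration stream is fixed, independent of cfg.seed).
    """
    sp = cfg.subset_params[subset_id]  # KeyError for unknown subset
    if sp.delta == 0.0 and sp.gamma == 0.0:
        return 1.0  # subset independent of the label: OR is exactly 1
    rng = np.random.default_rng(12345)
    ages = _draw_ages(cfg, n_quad, rng)
    male = rng.random(n_quad) < cfg.p_male
    adec = (ages - cfg.age_mean) / 10.0
    lm = cfg.label_model
    pi = expit(lm.beta0 + lm.beta_age * adec + lm.beta_sex * male)
    eps = rng.standard_normal(n_quad)
    batch = cfg.batch_shift if cohort == "validation" else 0.0
    base = sp.mu + sp.gamma * adec + batch + sp.sigma * eps
    p0 = 100.0 * expit(base)
    p1 = 100.0 * expit(base + sp.delta)
    x = np.concatenate([p0, p1])
    y = np.concatenate([np.zeros(n_quad), np.ones(n_quad)])
    w = np.concatenate([1 - pi, pi])
    return float(np.exp(_weighted_logistic_slope(x, y, w)))


def delta_for_target_or(
    cfg: SimConfig, subset_id: str, target_or: float, n_quad: int = 100_000
) -> float:
    """Solve for the CAD logit shift giving a target per-percent odds ratio."""
    from copy import deepcopy

    def f(delta: float) -> float:
        c = deepcopy(cfg)
        c.subset_params[subset_id] = SubsetParams(
            cfg.subset_params[subset_id].mu,
            cfg.subset_params[subset_id].sigma,
            delta,
            cfg.subset_params[subset_id].gamma,
        )
        return planted_or(c, subset_id, n_quad=n_quad) - target_or

    return float(optimize.brentq(f, -3.0, 3.0, xtol=1e-5))
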