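"""Seeded generators for every input the inference chain consumes.

The individual-level cohort the biomarker analysis needs is restricted
data, so this module emulates it: sex-specific log-normal biomarker
distributions calibrated to the published control medians (12.1 ng/mL in
men, 18.3 ng/mL in women, overall control SD near 8.9 ng/mL), standard
confounders, exponential event times whose log-rate is linear in the
standardized biomarker, and 1:1 incidence-density matching on sex, age,
and study center. Generators for two-sample GWAS summary statistics and
LD regions with known causal configurations complete the set; every
generator carries its ground truth so that recovery tests can compare
estimates against it.

All generators are bit-reproducible given (params, seed); one global
integer seed fans out to per-component child streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .summary_associations import VariantAssociation

# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortParams:
    """Conditions of the emulated prospective cohort.

    Biomarker medians and the log-scale SD are chosen so that the control
    distribution reproduces the published sex-specific medians and an
    overall control SD of about 8.9 ng/mL. The hazard depends only on the
    matched factors (sex, age, center) and the standardized biomarker
    unless the mediator-path parameters are set, in which case the
    biomarker becomes a linear mediator of waist circumference and the
    hazard carries the direct and mediated effects explicitly.
    """

    n_subjects: int = 20000
    fraction_female: float = 0.5
    biomarker_median_male: float = 12.1
    biomarker_median_female: float = 18.3
    biomarker_log_sd: float = 0.45
    biomarker_bmi_corr: float = 0.4
    log_rr_per_sd: float = 0.0
    # mediator-path parameters: set all three to activate the linear
    # exposure (waist) -> mediator (biomarker) -> outcome structure
    alpha1: float | None = None  # ng/mL per cm of waist
    beta_mediator: float | None = None  # log-HR per ng/mL
    beta_exposure: float | None = None  # direct log-HR per cm of waist
    mediator_sd: float = 6.0  # residual SD of the linear mediator model
    baseline_hazard: float = 0.004  # events per person-year
    follow_up_years: float = 12.0
    n_centers: int = 8
    log_hr_age: float = 0.04  # per year, matched away by design
    log_hr_male: float = 0.2  # matched away by design
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_female <= 1.0:
            raise ValueError("fraction_female must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        med = (self.alpha1, self.beta_mediator, self.beta_exposure)
        if any(v is not None for v in med) and any(v is None for v in med):
            raise ValueError("set all of alpha1, beta_mediator, beta_exposure or none")

    @property
    def mediation_mode(self) -> bool:
        return self.alpha1 is not None

    def biomarker_sd_theoretical(self) -> float:
        """Population SD of the log-normal biomarker mixture implied by the params."""
        s2 = self.biomarker_log_sd**2
        fracs = (1.0 - self.fraction_female, self.fraction_female)
        meds = (self.biomarker_median_male, self.biomarker_median_female)
        means = [m * np.exp(s2 / 2) for m in meds]
        varis = [(np.exp(s2) - 1.0) * m**2 * np.exp(s2) for m in meds]
        mean = sum(f * m for f, m in zip(fracs, means))
        second = sum(f * (v + m**2) for f, m, v in zip(fracs, means, varis))
        return float(np.sqrt(second - mean**2))


def simulate_cohort(params: CohortParams) -> pd.DataFrame:
    """Generate one subject per row with covariates, biomarker, and event time.

    Event times are exponential with log-rate linear in the standardized
    biomarker (and the mediator-path terms when active); censoring occurs
    at the follow-up horizon. The returned frame carries ``event`` (0/1)
    and ``event_time`` (years).
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n = params.n_subjects
    if n == 0:
        return pd.DataFrame(
            columns=["subject_id", "sex", "age", "center", "education", "activity",
                     "smoking", "alcohol", "height", "bmi", "waist", "biomarker",
                     "event", "event_time"]
        )
    female = rng.random(n) < params.fraction_female
    sex = np.where(female, "female", "male")
    age = np.clip(rng.normal(58.0, 7.0, n), 35.0, 75.0)
    center = rng.integers(0, params.n_centers, n)
    education = rng.integers(0, 5, n)
    activity = rng.integers(0, 4, n)
    smoking = rng.integers(0, 3, n)
    alcohol = np.round(np.exp(rng.normal(1.8, 1.0, n)), 1)
    height = np.where(female, rng.normal(162.0, 6.0, n), rng.normal(175.0, 7.0, n))
    bmi = np.clip(rng.normal(26.0, 3.6, n) + 0.05 * (age - 58.0), 16.0, 50.0)
    waist = (
        -40.0 + 2.5 * bmi + 0.3 * height + 6.0 * (~female)
        + rng.normal(0.0, 4.5, n)
    )

    if params.mediation_mode:
        # linear mediator of waist, per the product-method mediation model
        alpha0 = np.where(female, params.biomarker_median_female,
                          params.biomarker_median_male) - params.alpha1 * waist.mean()
        biomarker = alpha0 + params.alpha1 * waist + rng.normal(0.0, params.mediator_sd, n)
        eta = (
            params.beta_exposure * (waist - waist.mean())
            + params.beta_mediator * (biomarker - biomarker.mean())
        )
    else:
        log_med = np.where(female, np.log(params.biomarker_median_female),
                           np.log(params.biomarker_median_male))
        z_bmi = (bmi - bmi.mean()) / bmi.std()
        rho = params.biomarker_bmi_corr
        z = rho * z_bmi + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        biomarker = np.exp(log_med + params.biomarker_log_sd * z)
        sd_ref = params.biomarker_sd_theoretical()
        eta = params.log_rr_per_sd * (biomarker - biomarker.mean()) / sd_ref
    eta = eta + params.log_hr_age * (age - age.mean()) + params.log_hr_male * (~female)

    rate = params.baseline_hazard * np.exp(eta)
    t = rng.exponential(1.0 / rate)
    event = t <= params.follow_up_years
    event_time = np.where(event, t, params.follow_up_years)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "sex": sex,
            "age": age,
            "center": center,
            "education": education,
            "activity": activity,
            "smoking": smoking,
            "alcohol": alcohol,
            "height": height,
            "bmi": bmi,
            "waist": waist,
            "biomarker": biomarker,
            "event": event.astype(int),
            "event_time": event_time,
        }
    )


def incidence_density_match(
    cohort: pd.DataFrame,
    age_caliper: float = 2.0,
    seed: int = 0,
    max_sets: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """1:1 incidence-density matching on sex, age caliper, and center.

    For each case (in event-time order) one control is drawn uniformly
    from the risk set: subjects event-free at the case's event time whose
    sex and center match and whose age lies within ``age_caliper`` years.
    A sampled control may itself become a case later — the defining
    property of incidence-density sampling. Cases with an empty risk set
    are dropped; the second return value counts them.

    Returns (long DataFrame with set_id / is_case rows, dropped count).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cohort = cohort.reset_index(drop=True)
    case_order = cohort.index[cohort["event"] == 1][
        np.argsort(cohort.loc[cohort["event"] == 1, "event_time"].to_numpy(), kind="stable")
    ]
    # group candidates by exact strata once; ages/times compared per case
    strata: dict = {}
    for key, grp in cohort.groupby(["sex", "center"]):
        strata[key] = (
            grp.index.to_numpy(),
            grp["age"].to_numpy(dtype=float),
            grp["event_time"].to_numpy(dtype=float),
            grp["event"].to_numpy(dtype=int),
        )
    age_all = cohort["age"].to_numpy(dtype=float)
    sex_all = cohort["sex"].to_numpy()
    center_all = cohort["center"].to_numpy()
    time_all = cohort["event_time"].to_numpy(dtype=float)
    dropped = 0
    case_rows: list[int] = []
    control_rows: list[int] = []
    for ci in case_order:
        if max_sets is not None and len(case_rows) >= max_sets:
            break
        rows_idx, ages, times, events = strata[(sex_all[ci], center_all[ci])]
        t0 = time_all[ci]
        at_risk = (times > t0) | ((events == 0) & (times >= t0))
        eligible = at_risk & (np.abs(ages - age_all[ci]) <= age_caliper) & (rows_idx != ci)
        idx = np.flatnonzero(eligible)
        if len(idx) == 0:
            dropped += 1
            continue
        case_rows.append(ci)
        control_rows.append(rows_idx[idx[rng.integers(0, len(idx))]])
    n_sets = len(case_rows)
    matched = cohort.iloc[np.repeat(np.arange(0), 0) if n_sets == 0 else
                          np.column_stack([case_rows, control_rows]).ravel()].copy()
    matched["set_id"] = np.repeat([f"set{i}" for i in range(n_sets)], 2)
    matched["is_case"] = np.tile([1, 0], n_sets)
    return matched.reset_index(drop=True), dropped


# ---------------------------------------------------------------------------
# two-sample GWAS summaries


@dataclass
class GwasSimParams:
    """Conditions of the two-sample MR simulation (non-overlapping samples)."""

    k: int = 3
    eafs: Sequence[float] = (0.2, 0.3, 0.4)
    target_r2: float = 0.01
    n_exposure: int = 20000
    n_cases: int = 20000
    n_controls: int = 20000
    theta: float = 0.1  # true causal log-OR per exposure SD
    pleiotropy: Sequence[float] | None = None  # per-SNP direct log-odds effects
    seed: int = 0

    def __post_init__(self) -> None:
        self.eafs = tuple(float(p) for p in self.eafs)
        if len(self.eafs) != self.k:
            raise ValueError("eafs length must equal k")
        if not all(0.0 < p < 1.0 for p in self.eafs):
            raise ValueError("eafs must lie strictly in (0, 1)")
        if not 0.0 < self.target_r2 < 1.0:
            raise ValueError(f"target R^2 {self.target_r2} unattainable (need (0, 1))")
        if self.pleiotropy is None:
            self.pleiotropy = tuple(0.0 for _ in range(self.k))
        else:
            self.pleiotropy = tuple(float(d) for d in self.pleiotropy)
            if len(self.pleiotropy) != self.k:
                raise ValueError("pleiotropy length must equal k")


@dataclass(frozen=True)
class GwasTruth:
    theta: float
    r2: float
    per_allele_effects: tuple[float, ...]
    pleiotropy: tuple[float, ...]


def _marginal_ols(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column simple-regression slopes and SEs, vectorized."""
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    ss_g = (gc**2).sum(axis=0)
    beta = gc.T @ yc / ss_g
    n = len(y)
    resid_var = ((yc**2).sum() - beta**2 * ss_g) / (n - 2)
    se = np.sqrt(resid_var / ss_g)
    return beta, se


def _marginal_logistic_score(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column logistic score-test effect estimates and SEs, vectorized.

    beta = U/V and se = V^{-1/2} with U = sum g_c (y - ybar) and
    V = ybar (1-ybar) sum g_c^2 — the standard GWAS approximation to the
    per-variant logistic MLE.
    """
    gc = g - g.mean(axis=0)
    ybar = y.mean()
    u = gc.T @ (y - ybar)
    v = ybar * (1.0 - ybar) * (gc**2).sum(axis=0)
    return u / v, 1.0 / np.sqrt(v)


def simulate_gwas_summary(
    params: GwasSimParams,
) -> tuple[list[VariantAssociation], list[VariantAssociation], GwasTruth]:
    """Two-sample GWAS summary statistics with known causal effect.

    Exposure sample: genotypes Binomial(2, EAF); exposure built as a
    unit-variance trait with the target total variance explained split
    equally across variants; per-variant OLS summaries. Outcome sample
    (independent): binary outcome from a logistic model with log-odds
    theta per exposure SD plus any per-variant direct (pleiotropic)
    effects; per-variant logistic score summaries.
    """
    root = np.random.SeedSequence(params.seed).spawn(2)
    rng_x = np.random.default_rng(root[0])
    rng_y = np.random.default_rng(root[1])
    p = np.array(params.eafs)
    # equal-split per-allele effects on the unit-variance exposure scale
    beta_true = np.sqrt((params.target_r2 / params.k) / (2.0 * p * (1.0 - p)))

    g_exp = rng_x.binomial(2, p, size=(params.n_exposure, params.k)).astype(float)
    noise = rng_x.standard_normal(params.n_exposure) * np.sqrt(1.0 - params.target_r2)
    x = (g_exp - 2.0 * p) @ beta_true + noise
    bx, sx = _marginal_ols(g_exp, x)

    n_out = params.n_cases + params.n_controls
    g_out = rng_y.binomial(2, p, size=(n_out, params.k)).astype(float)
    noise_out = rng_y.standard_normal(n_out) * np.sqrt(1.0 - params.target_r2)
    x_out = (g_out - 2.0 * p) @ beta_true + noise_out
    gamma0 = float(logit(params.n_cases / n_out))
    lin = gamma0 + params.theta * x_out + g_out @ np.array(params.pleiotropy)
    y = (rng_y.random(n_out) < expit(lin)).astype(float)
    by, sy = _marginal_logistic_score(g_out, y)

    def records(beta, se, g, label, n) -> list[VariantAssociation]:
        out = []
        for j in range(params.k):
            out.append(
                VariantAssociation(
                    variant_id=f"sim{j}",
                    chromosome="1",
                    position=(j + 1) * 1000,
                    effect_allele="A",
                    other_allele="G",
                    effect_allele_freq=float(g[:, j].mean() / 2.0),
                    beta=float(beta[j]),
                    se=float(se[j]),
                    sample_size=n,
                    trait_label=label,
                )
            )
        return out

    exposure = records(bx, sx, g_exp, "simulated exposure (SD units)", params.n_exposure)
    outcome = records(by, sy, g_out, "simulated outcome (log-odds)", n_out)
    truth = GwasTruth(
        theta=params.theta,
        r2=params.target_r2,
        per_allele_effects=tuple(float(b) for b in beta_true),
        pleiotropy=tuple(params.pleiotropy),
    )
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# LD regions for colocalization


@dataclass
class RegionSimParams:
    """Conditions of the regional two-trait colocalization simulation."""

    m: int = 50
    rho_ld: float = 0.8
    eaf: float = 0.3
    configuration: str = "shared"  # shared | distinct | none
    causal_indices: tuple[int, ...] | None = None
    n1: int = 10000
    n2: int = 10000
    effect1: float = 0.3  # trait-1 effect per genotype SD (trait-SD units)
    effect2: float = 0.3  # trait-2 effect per genotype SD (log-odds)
    trait1_type: str = "quantitative"
    trait2_type: str = "binary"
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.rho_ld) < 1:
            raise ValueError("|rho_ld| must be < 1")
        if self.configuration not in ("shared", "distinct", "none"):
            raise ValueError(f"unknown configuration {self.configuration!r}")
        if self.causal_indices is None:
            if self.configuration == "shared":
                self.causal_indices = (self.m // 2,)
            elif self.configuration == "distinct":
                self.causal_indices = (self.m // 3, (2 * self.m) // 3)
            else:
                self.causal_indices = ()
        self.causal_indices = tuple(int(i) for i in self.causal_indices)
        if any(i >= self.m or i < 0 for i in self.causal_indices):
            raise ValueError("causal indices must lie in [0, m)")


@dataclass(frozen=True)
class RegionTruth:
    configuration: str
    causal1: int | None
    causal2: int | None


def _haplotypes(rng, n: int, m: int, p: float, rho: float) -> np.ndarray:
    """Markov-chain haplotypes: copy the previous allele with probability
    rho, else draw a fresh Bernoulli(p). Gives allele correlation exactly
    rho^|i-j| for a shared allele frequency."""
    h = np.empty((n, m), dtype=np.int8)
    h[:, 0] = rng.random(n) < p
    for i in range(1, m):
        copy = rng.random(n) < rho
        fresh = rng.random(n) < p
        h[:, i] = np.where(copy, h[:, i - 1], fresh)
    return h


def _genotypes(rng, n: int, m: int, p: float, rho: float) -> np.ndarray:
    return (_haplotypes(rng, n, m, p, rho) + _haplotypes(rng, n, m, p, rho)).astype(float)


def simulate_ld_region(
    params: RegionSimParams,
) -> tuple[list[VariantAssociation], list[VariantAssociation], RegionTruth]:
    """Regional summary statistics for two traits with known causal structure.

    Two independent samples share the LD structure; each trait is driven
    by its designated causal variant (standardized dosage). Per-variant
    marginal summaries are emitted for both traits.
    """
    root = np.random.SeedSequence(params.seed).spawn(2)
    causal1 = causal2 = None
    if params.configuration == "shared":
        causal1 = causal2 = params.causal_indices[0]
    elif params.configuration == "distinct":
        causal1, causal2 = params.causal_indices[:2]

    def one_trait(rng, n, causal, effect, trait_type):
        g = _genotypes(rng, n, params.m, params.eaf, params.rho_ld)
        if causal is None:
            signal = np.zeros(n)
        else:
            gc = g[:, causal]
            signal = effect * (gc - gc.mean()) / gc.std()
        if trait_type == "quantitative":
            y = signal + rng.standard_normal(n)
            return _marginal_ols(g, y)
        y = (rng.random(n) < expit(signal)).astype(float)
        return _marginal_logistic_score(g, y)

    b1, s1 = one_trait(np.random.default_rng(root[0]), params.n1, causal1,
                       params.effect1, params.trait1_type)
    b2, s2 = one_trait(np.random.default_rng(root[1]), params.n2, causal2,
                       params.effect2, params.trait2_type)

    def records(beta, se, label):
        return [
            VariantAssociation(
                variant_id=f"rv{i}",
                chromosome="1",
                position=(i + 1) * 1000,
                effect_allele="A",
                other_allele="G",
                effect_allele_freq=params.eaf,
                beta=float(beta[i]),
                se=float(se[i]),
                trait_label=label,
            )
            for i in range(params.m)
        ]

    truth = RegionTruth(configuration=params.configuration, causal1=causal1, causal2=causal2)
    return records(b1, s1, "trait1"), records(b2, s2, "trait2"), truth
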