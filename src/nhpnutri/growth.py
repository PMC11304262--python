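"""Weight-for-age z-score (WAZ) reference construction and undernutrition screening.

The screening model: for each sex, a reference population of healthy animals
(body condition score at or above a threshold) defines the mean ``mu`` and
standard deviation ``sigma`` of the weight-for-age ratio (kg of body weight
per year of age).  An animal's WAZ is then

    waz = (X - mu_sex) / sigma_sex

where ``X`` is the animal's own weight-for-age ratio.  Animals whose WAZ
falls at or below a cutoff (derived as the mean WAZ of a clinically flagged,
non-thriving group) are classified as undernourished.

The module also provides the resource-equation sample-size rule
``n = DF/k + 1`` with a casualty provision, Welch's unequal-variance t test
for group comparisons, and t-based summary confidence intervals for
anthropometric measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReferenceStandard",
    "SexParams",
    "WAZResult",
    "CutoffEstimate",
    "SummaryCI",
    "SampleSizePlan",
    "build_reference",
    "compute_waz",
    "derive_cutoff",
    "classify",
    "summarize_measure",
    "welch_t",
    "sample_size",
    "protein_energy",
]


@dataclass(frozen=True)
class SexParams:
    """Reference parameters for one sex: mean/SD of the weight-for-age ratio."""

    mu: float  # kg/year
    sigma: float  # kg/year
    n: int

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"reference sigma must be > 0, got {self.sigma}")
        if self.n < 2:
            raise ValueError(f"reference requires n >= 2 per sex, got {self.n}")


@dataclass(frozen=True)
class ReferenceStandard:
    """Sex-stratified weight-for-age reference standard."""

    per_sex: dict[str, SexParams] = field(default_factory=dict)

    def __getitem__(self, sex: str) -> SexParams:
        try:
            return self.per_sex[sex]
        except KeyError:
            raise KeyError(
                f"sex {sex!r} not in reference standard "
                f"(available: {sorted(self.per_sex)})"
            ) from None


@dataclass(frozen=True)
class WAZResult:
    animal_id: str
    ratio: float  # kg/year
    waz: float
    sex: str


@dataclass(frozen=True)
class CutoffEstimate:
    """Mean WAZ of a flagged group with its t-based 95% confidence interval."""

    mean: float
    ci_lower: float
    ci_upper: float
    n: int


@dataclass(frozen=True)
class SummaryCI:
    mean: float
    sd: float
    n: int
    ci_lower: float
    ci_upper: float


@dataclass(frozen=True)
class SampleSizePlan:
    df_target: int
    k_groups: int
    base_n: int
    casualty_frac: float
    final_n: int


def _validate_cohort(cohort: pd.DataFrame) -> None:
    required = {"sex", "age_years", "weight_kg"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort missing required columns: {sorted(missing)}")
    if (cohort["age_years"] <= 0).any():
        raise ValueError("cohort contains non-positive ages")
    if (cohort["weight_kg"] <= 0).any():
        raise ValueError("cohort contains non-positive weights")


def build_reference(cohort: pd.DataFrame, bcs_threshold: float = 2.0) -> ReferenceStandard:
    """Build the sex-stratified reference standard from a cohort table.

    Animals with body condition score below ``bcs_threshold`` are excluded;
    for each sex the mean and sample standard deviation (n-1 denominator) of
    the weight/age ratio define the standard.

    Parameters
    ----------
    cohort
        Table with columns ``sex``, ``age_years``, ``weight_kg``, ``bcs``.
    bcs_threshold
        Minimum body condition score for inclusion in the reference.
    """
    _validate_cohort(cohort)
    if "bcs" not in cohort.columns:
        raise ValueError("cohort missing required column 'bcs'")
    kept = cohort[cohort["bcs"] >= bcs_threshold]
    if kept.empty:
        raise ValueError("no animals pass the BCS threshold")
    per_sex: dict[str, SexParams] = {}
    for sex, grp in kept.groupby("sex", observed=True):
        ratios = (grp["weight_kg"] / grp["age_years"]).to_numpy(float)
        if ratios.size < 2:
            raise ValueError(f"fewer than 2 reference animals for sex {sex!r}")
        sigma = float(np.std(ratios, ddof=1))
        if sigma <= 0:
            raise ValueError(f"degenerate reference spread (sigma=0) for sex {sex!r}")
        per_sex[str(sex)] = SexParams(mu=float(np.mean(ratios)), sigma=sigma, n=ratios.size)
    return ReferenceStandard(per_sex=per_sex)


def compute_waz(animals: pd.DataFrame, ref: ReferenceStandard) -> pd.DataFrame:
    """Score animals against a reference standard.

    Returns a copy of ``animals`` with ``ratio`` and ``waz`` columns appended.
    The ratio X entering the z-score is the animal's weight/age ratio, the
    only reading dimensionally consistent with a reference mean expressed in
    kg/year.
    """
    _validate_cohort(animals)
    out = animals.copy()
    ratio = out["weight_kg"] / out["age_years"]
    mu = out["sex"].map(lambda s: ref[str(s)].mu)
    sigma = out["sex"].map(lambda s: ref[str(s)].sigma)
    out["ratio"] = ratio
    out["waz"] = (ratio - mu) / sigma
    return out


def derive_cutoff(
    flagged: pd.DataFrame,
    ref: ReferenceStandard,
    method: str = "mean",
    quantile: float = 0.95,
) -> CutoffEstimate:
    """Screening cutoff from a flagged (non-thriving) group's WAZ values.

    The default (and recommended) definition is the group *mean* with a
    t-based 95% CI — that is how a cutoff like -1.83 arises.  ``method=
    "quantile"`` instead returns the upper ``quantile`` of the flagged WAZ
    distribution (a screening threshold capturing that fraction of the
    flagged group), with a bootstrap-free CI set to the point estimate.
    """
    scored = compute_waz(flagged, ref)
    waz = scored["waz"].to_numpy(float)
    n = waz.size
    if n < 2:
        raise ValueError("derive_cutoff requires at least 2 flagged animals")
    if method == "mean":
        mean = float(np.mean(waz))
        sd = float(np.std(waz, ddof=1))
        half = float(stats.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
        return CutoffEstimate(mean=mean, ci_lower=mean - half, ci_upper=mean + half, n=n)
    if method == "quantile":
        if not 0.0 < quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")
        q = float(np.quantile(waz, quantile))
        return CutoffEstimate(mean=q, ci_lower=q, ci_upper=q, n=n)
    raise ValueError(f"unknown cutoff method {method!r}")


def classify(animals: pd.DataFrame, ref: ReferenceStandard, cutoff: float) -> pd.DataFrame:
    """Flag animals with WAZ at or below ``cutoff`` as undernourished.

    A WAZ exactly equal to the cutoff is flagged (conservative screening).
    """
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    out = compute_waz(animals, ref)
    out["undernourished"] = out["waz"] <= cutoff
    return out


def summarize_measure(values) -> SummaryCI:
    """Mean, sample SD and t-based 95% CI of a measurement vector."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("summarize_measure requires n >= 2")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    half = float(stats.t.ppf(0.975, x.size - 1)) * sd / math.sqrt(x.size)
    return SummaryCI(mean=mean, sd=sd, n=int(x.size), ci_lower=mean - half, ci_upper=mean + half)


def welch_t(group1, group2) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t test.

    Each group is either a vector of raw values or a ``(mean, sd, n)``
    summary.  Returns ``(t, df, p)`` with the Satterthwaite degrees of
    freedom and a two-sided p-value.
    """

    def _summary(g):
        if isinstance(g, tuple) and len(g) == 3:
            mean, sd, n = float(g[0]), float(g[1]), int(g[2])
        else:
            x = np.asarray(g, dtype=float)
            mean, sd, n = float(np.mean(x)), float(np.std(x, ddof=1)), int(x.size)
        if n < 2:
            raise ValueError("welch_t requires n >= 2 per group")
        return mean, sd, n

    m1, s1, n1 = _summary(group1)
    m2, s2, n2 = _summary(group2)
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("welch_t requires positive variance in at least one group")
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p


def sample_size(df_target: int, k: int, casualty_frac: float = 0.0) -> SampleSizePlan:
    """Resource-equation sample size: n = DF/k + 1, rounded up, with an
    optional casualty provision inflating the final per-group count."""
    if df_target < 1:
        raise ValueError("DF must be >= 1")
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0 <= casualty_frac < 1:
        raise ValueError("casualty fraction must be in [0, 1)")
    base_n = math.ceil(df_target / k + 1)
    final_n = math.ceil(base_n * (1 + casualty_frac))
    return SampleSizePlan(
        df_target=df_target, k_groups=k, base_n=base_n,
        casualty_frac=casualty_frac, final_n=final_n,
    )


def protein_energy(dose_g_per_kg_day: float, kcal_per_g: float = 4.0) -> float:
    """Energy supplied by a protein(-equivalent) dose, kcal per kg per day.

    The conventional 4 kcal/g protein energy density is the default; e.g. a
    1.5 g/kg/day supplement supplies 6.0 kcal/kg/day.
    """
    if dose_g_per_kg_day < 0 or kcal_per_g < 0:
        raise ValueError("dose and energy density must be non-negative")
    return dose_g_per_kg_day * kcal_per_g
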