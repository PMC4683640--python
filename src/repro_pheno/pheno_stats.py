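"""Strain-level statistics for a phenotype table.

The phenotype table is a tidy animals-by-traits DataFrame with mandatory
``animal_id``, ``strain`` and ``age_days`` columns; missing trait cells
are NaN. Four analyses apply to each trait:

* **Modified z-scores** flag outlier strains robustly:
  ``z = 0.6745 * (strain median - population median) / strain MAD``, and
  when the median absolute deviation is zero the fallback
  ``z = 0.98 * (strain median - population median) / strain meanAD`` is
  used (mean absolute deviation from the strain median). Scores beyond
  +1/+3 are classed high/very high, beyond -1/-3 low/very low, strictly.
* **Broad-sense heritability** ``h2 = VA / (VA + VE)``: the share of total
  phenotypic variance attributable to between-strain (genetic) variance.
  Two VA/VE estimators are provided — the variance of strain means
  (default) and an ANOVA method-of-moments estimator.
* **Pairwise-complete Pearson correlations** between traits, dropping
  only the rows missing for each specific pair.
* **One- and two-way ANOVA**, the latter fitting
  ``trait ~ strain + age + strain:age`` with age continuous in days and
  sequential (type-I) sums of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "StrainTraitSummary",
    "HeritabilityResult",
    "CorrelationMatrix",
    "AnovaResult",
    "ZClass",
    "validate_phenotype_table",
    "classify_z",
    "strain_summaries",
    "heritability",
    "pairwise_pearson",
    "one_way_anova",
    "two_way_anova",
]

ZClass = Literal["very_low", "low", "normal", "high", "very_high"]

REQUIRED_COLUMNS = ("animal_id", "strain", "age_days")


def validate_phenotype_table(table: pd.DataFrame) -> list[str]:
    """Schema check; returns a list of human-readable problems (empty = ok)."""
    problems = []
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            problems.append(f"missing required column {col!r}")
    traits = [c for c in table.columns if c not in REQUIRED_COLUMNS]
    if not traits:
        problems.append("no trait columns")
    if "strain" in table.columns and table["strain"].isna().any():
        problems.append("strain column has missing values")
    if "age_days" in table.columns:
        ages = pd.to_numeric(table["age_days"], errors="coerce")
        if ages.isna().any() or (ages <= 0).any():
            problems.append("age_days must be positive numbers")
    return problems


def trait_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in REQUIRED_COLUMNS]


# ---------------------------------------------------------------------------
# modified z-scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrainTraitSummary:
    """Location, spread and the modified z-score of one strain for one trait."""

    strain: str
    n: int
    mean: float
    median: float
    sd: float
    mad: float
    mean_ad: float
    z: float
    z_class: ZClass


def classify_z(z: float) -> ZClass:
    """Outlier class of a modified z-score; thresholds strictly beyond ±1/±3."""
    if z > 3:
        return "very_high"
    if z > 1:
        return "high"
    if z < -3:
        return "very_low"
    if z < -1:
        return "low"
    return "normal"


def _modified_z(strain_values: np.ndarray, population_median: float) -> float:
    """The robust outlier score of one strain against the pooled population.

    MAD here is the raw median absolute deviation from the strain median
    (no 1.4826 consistency factor — the 0.6745 multiplier plays that
    role); the mean-absolute-deviation fallback (multiplier 0.98) covers
    strains whose MAD degenerates to zero.
    """
    med = float(np.median(strain_values))
    num = med - population_median
    mad = float(np.median(np.abs(strain_values - med)))
    if mad > 0:
        return 0.6745 * num / mad
    mean_ad = float(np.mean(np.abs(strain_values - med)))
    if mean_ad > 0:
        return 0.98 * num / mean_ad
    if num == 0:
        return 0.0
    warnings.warn(
        "strain has zero MAD and zero mean absolute deviation but its median "
        "differs from the population median; reporting a signed infinite z",
        RuntimeWarning,
        stacklevel=3,
    )
    return float(np.inf if num > 0 else -np.inf)


def strain_summaries(table: pd.DataFrame, trait: str) -> list[StrainTraitSummary]:
    """Per-strain summaries and modified z-scores for one trait.

    The population median pools all non-missing animals of all strains,
    including the strain being scored. Strains with no data for the trait
    are omitted.
    """
    vals = pd.to_numeric(table[trait], errors="coerce")
    non_missing = table.loc[vals.notna()].assign(**{trait: vals[vals.notna()]})
    if non_missing.empty:
        raise ValueError(f"trait {trait!r} is entirely missing")
    if non_missing["strain"].nunique() < 2:
        raise ValueError("need at least two strains with data")
    pop_median = float(non_missing[trait].median())
    out = []
    for strain, grp in non_missing.groupby("strain", sort=True):
        x = grp[trait].to_numpy(dtype=float)
        med = float(np.median(x))
        z = _modified_z(x, pop_median)
        out.append(
            StrainTraitSummary(
                strain=str(strain),
                n=len(x),
                mean=float(np.mean(x)),
                median=med,
                sd=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                mad=float(np.median(np.abs(x - med))),
                mean_ad=float(np.mean(np.abs(x - med))),
                z=z,
                z_class=classify_z(z) if np.isfinite(z) else ("very_high" if z > 0 else "very_low"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# broad-sense heritability
# ---------------------------------------------------------------------------

EstimatorTag = Literal["strain_mean_variance", "anova_mom"]


@dataclass(frozen=True)
class HeritabilityResult:
    """Variance components and h2 = VA / (VA + VE) for one trait."""

    trait: str
    va: float
    ve: float
    h2: float
    estimator_tag: EstimatorTag


def heritability(
    table: pd.DataFrame, trait: str, estimator_tag: EstimatorTag = "strain_mean_variance"
) -> HeritabilityResult:
    """Broad-sense heritability of a trait across the strain panel.

    ``strain_mean_variance``: VA is the sample variance of the strain
    means and VE the unweighted mean of the within-strain sample
    variances. ``anova_mom``: the one-way ANOVA method of moments,
    VA = (MSB - MSW) / n0 clipped at zero with VE = MSW, where n0 is the
    effective per-strain sample size for (possibly) unbalanced designs.
    """
    vals = pd.to_numeric(table[trait], errors="coerce")
    df = table.loc[vals.notna(), ["strain"]].assign(y=vals[vals.notna()])
    groups = df.groupby("strain")["y"]
    k = groups.ngroups
    if k < 2:
        raise ValueError("need at least two strains with data")
    sizes = groups.size()
    if (sizes < 2).all():
        raise ValueError("need at least one strain with two or more animals")

    if estimator_tag == "strain_mean_variance":
        va = float(groups.mean().var(ddof=1))
        within = groups.var(ddof=1).dropna()
        ve = float(within.mean())
    elif estimator_tag == "anova_mom":
        n = len(df)
        grand = df["y"].mean()
        ssb = float((sizes * (groups.mean() - grand) ** 2).sum())
        ssw = float(((df["y"] - df["strain"].map(groups.mean())) ** 2).sum())
        msb = ssb / (k - 1)
        msw = ssw / (n - k)
        n0 = (n - float((sizes**2).sum()) / n) / (k - 1)
        va = max(0.0, (msb - msw) / n0)
        ve = msw
    else:
        raise ValueError(f"unknown estimator {estimator_tag!r}")

    total = va + ve
    if total <= 0:
        raise ValueError(f"trait {trait!r} has no variance; h2 undefined")
    return HeritabilityResult(trait=trait, va=va, ve=ve, h2=va / total, estimator_tag=estimator_tag)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise-complete Pearson r between traits, with per-pair n."""

    r: pd.DataFrame
    n: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        traits = list(self.r.columns)
        for i, a in enumerate(traits):
            for b in traits[i + 1:]:
                rows.append((a, b, self.r.loc[a, b], int(self.n.loc[a, b])))
        return pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "n"])


def pairwise_pearson(
    table: pd.DataFrame, traits: Sequence[str], min_pairs: int = 3
) -> CorrelationMatrix:
    """Pearson correlations computed on pairwise-complete observations.

    Each cell uses only the rows where both traits are present; cells with
    fewer than ``min_pairs`` complete pairs are reported missing. The
    diagonal is 1 by construction.
    """
    sub = table[list(traits)].apply(pd.to_numeric, errors="coerce")
    r = sub.corr(method="pearson", min_periods=min_pairs)
    present = sub.notna().astype(int)
    n = pd.DataFrame(present.T.values @ present.values, index=r.index, columns=r.columns)
    np.fill_diagonal(r.values, 1.0)
    return CorrelationMatrix(r=r, n=n)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    """Per-term decomposition: df, sum of squares, F, p."""

    trait: str
    table: pd.DataFrame  # index: term; columns: df, sum_sq, F, p


def _clean(table: pd.DataFrame, trait: str, extra: Sequence[str]) -> pd.DataFrame:
    vals = pd.to_numeric(table[trait], errors="coerce")
    df = table.loc[vals.notna(), list(extra)].copy()
    df["y"] = vals[vals.notna()]
    return df


def one_way_anova(
    table: pd.DataFrame, trait: str, factor: str = "strain", as_factor: bool | None = None
) -> AnovaResult:
    """One-way ANOVA of a trait on a single explanatory column.

    Categorical columns (or ``as_factor=True``) give the classic
    between/within decomposition; numeric columns default to a continuous
    regression F-test (the natural reading for age in days).
    """
    if factor not in table.columns:
        raise ValueError(f"unknown factor column {factor!r}")
    df = _clean(table, trait, [factor])
    numeric = pd.api.types.is_numeric_dtype(df[factor])
    treat_as_factor = as_factor if as_factor is not None else not numeric
    if treat_as_factor:
        if df[factor].nunique() < 2:
            raise ValueError("factor needs at least two levels with data")
        model = smf.ols("y ~ C(Q('%s'))" % factor, data=df).fit()
    else:
        if df[factor].nunique() < 2:
            raise ValueError("regressor is constant")
        model = smf.ols("y ~ Q('%s')" % factor, data=df).fit()
    aov = sm.stats.anova_lm(model, typ=1)
    renames = {f"Q('{factor}')": factor, f"C(Q('{factor}'))": factor}
    return AnovaResult(trait=trait, table=_tidy_anova(aov, renames))


def two_way_anova(table: pd.DataFrame, trait: str) -> AnovaResult:
    """Strain + age + strain:age ANOVA with age continuous in days.

    Sequential (type-I) sums of squares in the order strain, age,
    interaction.
    """
    df = _clean(table, trait, ["strain", "age_days"])
    if df["strain"].nunique() < 2:
        raise ValueError("need at least two strains with data")
    if df["age_days"].nunique() < 2:
        raise ValueError("age does not vary")
    if float(df["y"].var(ddof=1)) == 0.0:
        raise ValueError("trait has zero variance")
    model = smf.ols("y ~ C(strain) + age_days + C(strain):age_days", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # unbalanced designs trigger benign df warnings
        aov = sm.stats.anova_lm(model, typ=1)
    return AnovaResult(trait=trait, table=_tidy_anova(aov, {}))


_TERM_RENAMES = {
    "C(strain)": "strain",
    "age_days": "age",
    "C(strain):age_days": "strain:age",
}


def _tidy_anova(aov: pd.DataFrame, extra_renames: dict[str, str]) -> pd.DataFrame:
    tidy = aov.rename(index={**_TERM_RENAMES, **extra_renames})
    tidy = tidy.rename(columns={"PR(>F)": "p"})
    tidy.index.name = "term"
    return tidy[["df", "sum_sq", "F", "p"]]
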