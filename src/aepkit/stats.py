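"""Cohort-level inference.

Three families of analysis operate on the cohort table (one row per
animal x stimulated ear):

* a Gaussian GLM predictor screen with per-coefficient Wald tests
  (``measure ~ C(genotype) + C(gender) + age + threshold_contra +
  threshold_ipsi``),
* a randomization test comparing the observed within-animal rank
  correlation of a paired measure to the null distribution obtained by
  re-pairing ears across animals, and
* a nonparametric comparison battery (Kruskal-Wallis H with Dunn
  post-hoc z tests, Mann-Whitney U for two groups, Spearman rank
  correlation), all two-tailed at alpha = 0.05.

Wald p-values use the standard-normal reference by default (consistent
with large-sample GLM practice); pass ``use_t=True`` for a t reference.
Dunn post-hoc p-values are unadjusted by default with an optional
Bonferroni flag.  Missing responses are dropped listwise with the count
logged on the result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _st

__all__ = [
    "GLMResult",
    "RandTestResult",
    "GroupCompareResult",
    "RankCorrelation",
    "COHORT_COLUMNS",
    "DEFAULT_GLM_FORMULA_RHS",
    "validate_cohort_table",
    "fit_glm",
    "within_between_randomization",
    "group_compare",
    "rank_correlation",
]

ALPHA = 0.05

#: Minimal column set of a cohort table.
COHORT_COLUMNS = (
    "animal_id",
    "genotype",
    "gender",
    "age_weeks",
    "ear",
    "threshold_contra",
    "threshold_ipsi",
    "hi_class",
)

DEFAULT_GLM_FORMULA_RHS = (
    "C(genotype) + C(gender) + age_weeks + threshold_contra + threshold_ipsi"
)


def validate_cohort_table(table: pd.DataFrame, require=COHORT_COLUMNS) -> None:
    missing = [c for c in require if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    counts = table.groupby("animal_id").size()
    if (counts > 2).any():
        bad = counts[counts > 2].index.tolist()
        raise ValueError(f"more than two rows for animals: {bad}")


@dataclass
class GLMResult:
    """Per-predictor coefficients, standard errors and Wald p-values."""

    response: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    significant: pd.Series
    n_obs: int
    n_dropped: int
    degenerate: bool
    model_result: object = field(repr=False, default=None)


@dataclass
class RandTestResult:
    """Within- vs between-animal correlation randomization test."""

    measure: str
    observed: float
    null: np.ndarray
    ci_low: float
    ci_high: float
    inside_ci: bool
    n_perm: int
    n_animals: int


@dataclass
class GroupCompareResult:
    """Omnibus rank test plus pairwise post-hoc comparisons."""

    method: str
    statistic: float
    p_value: float
    pairwise: dict
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < ALPHA)


@dataclass
class RankCorrelation:
    rho: float
    p_value: float
    n: int
    defined: bool = True


def fit_glm(
    table: pd.DataFrame,
    response: str,
    formula_rhs: str = DEFAULT_GLM_FORMULA_RHS,
    use_t: bool = False,
) -> GLMResult:
    """Fit a Gaussian GLM of ``response`` on the cohort predictors.

    Rows with missing response or predictors are dropped listwise and
    counted in ``n_dropped``.  A rank-deficient (collinear) design is
    rejected with a diagnostic.  A zero-residual (perfect) fit is
    flagged ``degenerate``: coefficients are exact but Wald p-values are
    meaningless.
    """
    if response not in table.columns:
        raise ValueError(f"response {response!r} not in table")
    formula = f"{response} ~ {formula_rhs}"
    model = sm.GLM.from_formula(
        formula, data=table, family=sm.families.Gaussian(), missing="drop"
    )
    exog = np.asarray(model.exog, dtype=float)
    n_obs, n_params = exog.shape
    if np.linalg.matrix_rank(exog) < n_params:
        raise ValueError("collinear design matrix: predictors are linearly dependent")
    if n_obs < n_params + 2:
        raise ValueError(
            f"too few complete rows ({n_obs}) for {n_params} parameters"
        )
    res = model.fit(use_t=use_t)
    degenerate = bool(res.scale <= 1e-12)
    pvalues = res.pvalues
    return GLMResult(
        response=response,
        params=res.params,
        bse=res.bse,
        pvalues=pvalues,
        significant=pvalues < ALPHA,
        n_obs=int(n_obs),
        n_dropped=int(len(table) - n_obs),
        degenerate=degenerate,
        model_result=res,
    )


def _standardized_ranks(values: np.ndarray) -> np.ndarray:
    ranks = _st.rankdata(values)
    ranks = ranks - ranks.mean()
    sd = np.sqrt(np.sum(ranks**2))
    if sd == 0:
        raise ValueError("constant values: correlation undefined")
    return ranks / sd


def within_between_randomization(
    table: pd.DataFrame,
    measure: str,
    n_perm: int = 10000,
    seed=None,
) -> RandTestResult:
    """Test whether ears within an animal are more correlated than ears
    of different animals.

    The observed statistic is the Spearman correlation, across animals
    with both ears measured, of the left-ear and right-ear values of
    ``measure``.  The null distribution re-pairs the right-ear values
    with randomly permuted animal assignments ``n_perm`` times; the 95%
    interval is the 2.5th-97.5th percentile of the null.  ``inside_ci``
    is True when the observed within-animal correlation is consistent
    with independent ears.
    """
    wide = (
        table.pivot(index="animal_id", columns="ear", values=measure)
        .dropna()
    )
    for side in ("left", "right"):
        if side not in wide.columns:
            raise ValueError(f"no {side}-ear rows in table")
    if len(wide) < 5:
        raise ValueError(f"need >=5 animals with both ears, got {len(wide)}")
    left = wide["left"].to_numpy(dtype=float)
    right = wide["right"].to_numpy(dtype=float)
    a = _standardized_ranks(left)
    b = _standardized_ranks(right)
    observed = float(np.dot(a, b))
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, len(b))), axis=1)
    null = b[perms] @ a
    ci_low, ci_high = np.percentile(null, [2.5, 97.5])
    return RandTestResult(
        measure=measure,
        observed=observed,
        null=null,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        inside_ci=bool(ci_low <= observed <= ci_high),
        n_perm=int(n_perm),
        n_animals=int(len(wide)),
    )


def _dunn_posthoc(groups: Mapping, adjust: str | None) -> dict:
    names = list(groups)
    values = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = _st.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, vals in zip(names, values):
        mean_ranks[name] = ranks[start : start + len(vals)].mean()
        start += len(vals)
    # tie correction on the pooled ranks
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise = {}
    for a, b in itertools.combinations(names, 2):
        var = base_var * (1.0 / len(groups[a]) + 1.0 / len(groups[b]))
        if var <= 0:
            z, p = 0.0, float("nan")
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
            p = 2.0 * _st.norm.sf(abs(z))
            if adjust == "bonferroni":
                p = min(1.0, p * n_pairs)
        pairwise[(a, b)] = {"z": float(z), "p": float(p)}
    return pairwise


def group_compare(groups: Mapping, adjust: str | None = None) -> GroupCompareResult:
    """Compare a measure across groups with rank-based tests.

    Two groups: two-tailed Mann-Whitney U.  Three or more: Kruskal-
    Wallis H omnibus plus pairwise Dunn z tests (unadjusted by default;
    ``adjust='bonferroni'`` applies a multiplicity correction).  With
    every observation identical the statistics are tie-degenerate: the
    result is flagged and never significant.
    """
    groups = {name: np.asarray(v, dtype=float) for name, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than two observations")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        return GroupCompareResult(
            method="kruskal" if len(groups) > 2 else "mannwhitneyu",
            statistic=float("nan"),
            p_value=float("nan"),
            pairwise={},
            degenerate=True,
        )
    if len(groups) == 2:
        (name_a, a), (name_b, b) = groups.items()
        stat, p = _st.mannwhitneyu(a, b, alternative="two-sided")
        return GroupCompareResult(
            method="mannwhitneyu",
            statistic=float(stat),
            p_value=float(p),
            pairwise={(name_a, name_b): {"u": float(stat), "p": float(p)}},
        )
    stat, p = _st.kruskal(*groups.values())
    pairwise = _dunn_posthoc(groups, adjust=adjust)
    return GroupCompareResult(
        method="kruskal",
        statistic=float(stat),
        p_value=float(p),
        pairwise=pairwise,
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    rx = _st.rankdata(x)
    ry = _st.rankdata(y)
    a = rx - rx.mean()
    a = a / np.sqrt(np.sum(a**2))
    b = ry - ry.mean()
    b = b / np.sqrt(np.sum(b**2))
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(b))):
        rho = float(np.dot(a, b[list(perm)]))
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def rank_correlation(x, y, exact_max_n: int = 8) -> RankCorrelation:
    """Spearman rank correlation with a two-tailed p-value.

    For n <= ``exact_max_n`` the p-value is computed by exhaustive
    enumeration of rank permutations; otherwise the large-sample t
    approximation is used.  Constant inputs leave the correlation
    undefined (NaN, flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least three observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return RankCorrelation(float("nan"), float("nan"), len(x), defined=False)
    rho, p_approx = _st.spearmanr(x, y)
    if len(x) <= exact_max_n:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(p_approx)
    return RankCorrelation(float(rho), float(p), len(x))
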