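"""Inferential statistics: demographic tests and covariate-adjusted GLMs.

Two families live here. The first are the demographic comparisons that are
closed-form functions of printed group summaries: the Welch (unequal
variance) two-sample t test from means/SDs/ns, and the Yates
continuity-corrected chi-square for 2x2 sex tables — the dialects under
which the published Table-1 statistics reproduce (pooled-variance t and
the uncorrected chi-square do not).

The second are ordinary-least-squares general linear models in the
statsmodels Model/Results idiom: :class:`GroupDifferenceModel` regresses a
standardized emodiversity metric on a CHR indicator, and
:class:`SymptomAssociationModel` regresses a standardized SIPS symptom
total on a standardized diversity metric, both adjusting for current
antipsychotic use and the matching-valence mean emotion level. Each
``fit()`` returns a :class:`GlmResult` carrying the focal coefficient, its
95% CI from the t distribution, a two-sided p value, and the focal term's
squared partial correlation as the per-term effect size (whole-model R² is
reported alongside for transparency).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("emodiv")

METRIC_COLUMNS = {
    "total": "diversity_total",
    "positive": "diversity_positive",
    "negative": "diversity_negative",
}
SYMPTOM_TOTAL_COLUMNS = {
    "positive": "sips_total_positive",
    "negative": "sips_total_negative",
}


class ModelSpecificationError(ValueError):
    pass


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample t test: statistic, Welch-Satterthwaite df, p."""

    t: float
    df: float
    p: float


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    yates_correction: bool


@dataclass(frozen=True)
class GlmResult:
    """Focal-term summary of a fitted OLS general linear model."""

    outcome: str
    focal_term: str
    b: float
    ci_low: float
    ci_high: float
    r2_partial: float
    r2_model: float
    p: float
    n: int
    covariates: tuple[str, ...]
    standardized: bool

    def conf_int(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)

    def summary(self) -> str:
        lines = [
            f"GLM: {self.outcome} ~ {self.focal_term}"
            + (" + " + " + ".join(self.covariates) if self.covariates else ""),
            f"  n = {self.n}"
            + ("  (standardized variables)" if self.standardized else ""),
            f"  b[{self.focal_term}] = {self.b:+.3f}"
            f"  95% CI [{self.ci_low:+.3f}, {self.ci_high:+.3f}]",
            f"  partial R2 = {self.r2_partial:.3f}"
            f"  model R2 = {self.r2_model:.3f}  p = {self.p:.4g}",
        ]
        return "\n".join(lines)


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> WelchResult:
    """Welch t test from group summary statistics.

    t = (mean1 - mean2) / sqrt(sd1^2/n1 + sd2^2/n2), with
    Welch-Satterthwaite degrees of freedom and a two-sided p value.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ModelSpecificationError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ModelSpecificationError("each group needs n >= 2")
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return WelchResult(t=float(t), df=float(df), p=float(p))


def yates_chi_square(table, correction: bool = True) -> ChiSquareResult:
    """Chi-square test of independence for a 2x2 count table.

    The Yates continuity correction (on by default) subtracts N/2 from
    |ad - bc| before squaring, flooring at zero.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ModelSpecificationError("table must be 2x2")
    if np.any(arr < 0):
        raise ModelSpecificationError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ModelSpecificationError("all row and column margins must be positive")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=correction)
    return ChiSquareResult(
        statistic=float(stat), df=int(df), p=float(p), yates_correction=correction
    )


def standardize(values) -> np.ndarray:
    """z-score a vector: mean 0, sample SD 1 (n-1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ModelSpecificationError("standardize needs a vector of >= 2 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ModelSpecificationError("cannot standardize a constant vector")
    return (arr - arr.mean()) / sd


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return []
    involved = []
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            involved.append(names[j])
    return involved


def fit_glm(
    outcome,
    focal,
    covariates=None,
    outcome_name: str = "outcome",
    focal_name: str = "focal",
    covariate_names: tuple[str, ...] = (),
    standardized: bool = False,
) -> GlmResult:
    """OLS fit with intercept; focal-term CI from the t distribution.

    ``r2_partial`` is the focal term's squared partial correlation,
    t^2 / (t^2 + df_resid) — the per-term effect size reported next to each
    coefficient. Raises on rank-deficient designs, naming the collinear
    columns.
    """
    y = np.asarray(outcome, dtype=float)
    f = np.asarray(focal, dtype=float)
    cols = [f]
    names = [focal_name]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != y.size:
            C = C.T
        for j in range(C.shape[1]):
            cols.append(C[:, j])
            names.append(
                covariate_names[j] if j < len(covariate_names) else f"cov{j}"
            )
    X = np.column_stack(cols)
    n, p = X.shape
    if n <= p + 1:
        raise ModelSpecificationError(
            f"n = {n} too small for {p} terms plus intercept"
        )
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, ["intercept"] + names)
        raise ModelSpecificationError(f"rank-deficient design; collinear: {bad}")
    model = sm.OLS(y, design)
    res = model.fit()
    b = float(res.params[1])
    ci = res.conf_int(alpha=0.05)
    t_focal = float(res.tvalues[1])
    df_resid = float(res.df_resid)
    return GlmResult(
        outcome=outcome_name,
        focal_term=focal_name,
        b=b,
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        r2_partial=t_focal**2 / (t_focal**2 + df_resid),
        r2_model=float(res.rsquared),
        p=float(res.pvalues[1]),
        n=n,
        covariates=tuple(names[1:]),
        standardized=standardized,
    )


def _matching_mean_columns(metric: str) -> list[str]:
    if metric == "positive":
        return ["mean_positive_emotion"]
    if metric == "negative":
        return ["mean_negative_emotion"]
    if metric == "total":
        return ["mean_positive_emotion", "mean_negative_emotion"]
    raise ModelSpecificationError(
        f"metric must be total|positive|negative, got {metric!r}"
    )


class GroupDifferenceModel:
    """CHR-vs-HC difference in a standardized emodiversity metric.

    outcome: z-scored diversity metric; focal: CHR indicator (CHR = 1);
    covariates: antipsychotic flag plus the matching-valence mean emotion
    (both valence means when metric = "total").
    """

    def __init__(self, scores: pd.DataFrame, metric: str):
        if metric not in METRIC_COLUMNS:
            raise ModelSpecificationError(f"unknown metric {metric!r}")
        self.metric = metric
        cols = (
            ["group", "antipsychotic", METRIC_COLUMNS[metric]]
            + _matching_mean_columns(metric)
        )
        data = scores.dropna(subset=[c for c in cols if c in scores.columns])
        dropped = len(scores) - len(data)
        if dropped:
            logger.warning(
                "GroupDifferenceModel: %d row(s) dropped for missingness", dropped
            )
        groups = set(data["group"].unique())
        if not {"CHR", "HC"} <= groups:
            raise ModelSpecificationError(
                f"both CHR and HC required, found {sorted(groups)}"
            )
        self.data = data

    def fit(self) -> GlmResult:
        d = self.data
        mean_cols = _matching_mean_columns(self.metric)
        return fit_glm(
            standardize(d[METRIC_COLUMNS[self.metric]]),
            (d["group"] == "CHR").astype(float).to_numpy(),
            np.column_stack(
                [d["antipsychotic"].to_numpy(float)]
                + [d[c].to_numpy(float) for c in mean_cols]
            ),
            outcome_name=f"z({METRIC_COLUMNS[self.metric]})",
            focal_name="group_chr",
            covariate_names=tuple(["antipsychotic"] + mean_cols),
            standardized=True,
        )


class SymptomAssociationModel:
    """Association of a SIPS symptom total with an emodiversity metric.

    outcome: z-scored symptom total; focal: z-scored diversity metric;
    covariates: antipsychotic flag plus the matching-valence mean emotion.
    Defaults to the CHR subsample (symptom variance in HCs is minimal);
    ``chr_only=False`` analyses the full sample.
    """

    MIN_CHR_N = 10

    def __init__(
        self,
        scores: pd.DataFrame,
        metric: str,
        symptom_total: str,
        chr_only: bool = True,
    ):
        if metric not in METRIC_COLUMNS:
            raise ModelSpecificationError(f"unknown metric {metric!r}")
        if symptom_total not in SYMPTOM_TOTAL_COLUMNS:
            raise ModelSpecificationError(
                f"symptom_total must be positive|negative, got {symptom_total!r}"
            )
        self.metric = metric
        self.symptom_total = symptom_total
        self.chr_only = chr_only
        data = scores
        if chr_only:
            data = data[data["group"] == "CHR"]
            if len(data) < self.MIN_CHR_N:
                raise ModelSpecificationError(
                    f"chr_only analysis needs >= {self.MIN_CHR_N} CHR rows, "
                    f"got {len(data)}"
                )
        cols = (
            ["antipsychotic", METRIC_COLUMNS[metric],
             SYMPTOM_TOTAL_COLUMNS[symptom_total]]
            + _matching_mean_columns(metric)
        )
        kept = data.dropna(subset=[c for c in cols if c in data.columns])
        if len(data) - len(kept):
            logger.warning(
                "SymptomAssociationModel: %d row(s) dropped for missingness",
                len(data) - len(kept),
            )
        self.data = kept

    def fit(self) -> GlmResult:
        d = self.data
        mean_cols = _matching_mean_columns(self.metric)
        return fit_glm(
            standardize(d[SYMPTOM_TOTAL_COLUMNS[self.symptom_total]]),
            standardize(d[METRIC_COLUMNS[self.metric]]),
            np.column_stack(
                [d["antipsychotic"].to_numpy(float)]
                + [d[c].to_numpy(float) for c in mean_cols]
            ),
            outcome_name=f"z({SYMPTOM_TOTAL_COLUMNS[self.symptom_total]})",
            focal_name=f"z({METRIC_COLUMNS[self.metric]})",
            covariate_names=tuple(["antipsychotic"] + mean_cols),
            standardized=True,
        )


def group_difference_model(scores: pd.DataFrame, metric: str) -> GlmResult:
    """Functional wrapper around :class:`GroupDifferenceModel`."""
    return GroupDifferenceModel(scores, metric).fit()


def symptom_association_model(
    scores: pd.DataFrame,
    metric: str,
    symptom_total: str,
    chr_only: bool = True,
) -> GlmResult:
    """Functional wrapper around :class:`SymptomAssociationModel`."""
    return SymptomAssociationModel(scores, metric, symptom_total, chr_only).fit()
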