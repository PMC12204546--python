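"""Mixed-effects comparisons, multiple-testing correction, and summaries.

The central model is a linear mixed-effects model with subject-specific
random intercepts and no random slopes,

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2),

fitted by maximum likelihood (not REML).  Wald t-tests per coefficient use
residual degrees of freedom ``n_obs - rank(X)``.  Direct posture and
sensor-height comparisons fit one two-condition contrast at a time
(``metric ~ condition + (1 | subject)``) and the resulting family of
p-values is corrected with the step-down Holm–Šidák procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
import statsmodels.api as sm

from .io_formats import Condition, ValidationError, condition_dummies

__all__ = [
    "ModelSpec",
    "MixedModelResult",
    "TestFamily",
    "fit_lmm",
    "fit_contrast",
    "enumerate_direct_comparisons",
    "holm_sidak",
    "boxplot_stats",
    "metric_r2",
    "summarize_metric",
    "covariate_model_spec",
    "METRICS",
]

#: The three signal-quality metric columns of a metrics table.
METRICS = ("snr_db", "pi_percent", "tmcc")

#: Covariate fixed effects of the participant-characteristics model, in
#: reporting order.  Gender, diabetes and skin enter as numeric codes
#: (single-coefficient rows), not as factors.
COVARIATE_ORDER = ("age", "gender", "bmi", "diabetes", "skin", "sbp", "pp")
CONDITION_DUMMIES = ("posture_sitting", "posture_supine", "height_arm_up", "height_hand_in_lap")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one mixed model fit.

    ``fixed_terms`` are column names of the cohort table (plus condition
    dummies, which are derived from a ``condition`` column when absent).
    The random intercept on subject is always included.
    """

    response: str
    fixed_terms: tuple[str, ...]
    random_intercept: bool = True


def covariate_model_spec(
    response: str, include_dc_amplitude: bool = True, with_conditions: bool = False
) -> ModelSpec:
    """The participant-characteristics model for one quality metric.

    ``with_conditions`` adds posture and sensor-height fixed effects (the
    oscillometric-style model); ``include_dc_amplitude=False`` drops the
    device-characteristic DC-amplitude term (the second model variant).
    """
    terms = list(COVARIATE_ORDER)
    if include_dc_amplitude:
        terms.append("dc_amplitude")
    if with_conditions:
        terms.extend(CONDITION_DUMMIES)
    return ModelSpec(response=response, fixed_terms=tuple(terms))


@dataclass
class MixedModelResult:
    """Fixed-effect table and variance components of one fitted model.

    ``table`` has one row per fixed term (including the intercept) with
    columns estimate, se, t, p, ci_lo, ci_hi (95% CIs at
    ``estimate ± t_crit·SE`` with residual degrees of freedom).
    """

    table: pd.DataFrame
    var_subject: float
    var_resid: float
    loglik: float
    n_obs: int
    n_subjects: int
    n_dropped: int

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _check_collinearity(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        flagged, running = [], 0
        for j in range(X.shape[1]):
            r = np.linalg.matrix_rank(arr[:, : j + 1])
            if r == running:
                flagged.append(X.columns[j])
            running = r
        raise ValidationError(f"singular design: collinear term(s) {flagged}")


def _prepare(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, int]:
    df = table.copy()
    needs_dummies = [t for t in spec.fixed_terms if t in CONDITION_DUMMIES and t not in df.columns]
    if needs_dummies:
        if "condition" not in df.columns:
            raise ValidationError(
                f"terms {needs_dummies} need condition dummies but no 'condition' column present"
            )
        df = pd.concat([df, condition_dummies(df["condition"])], axis=1)
    missing_cols = [t for t in spec.fixed_terms if t not in df.columns] + (
        [] if spec.response in df.columns else [spec.response]
    )
    if missing_cols:
        raise ValidationError(f"cohort table lacks column(s) {missing_cols}")
    used = [spec.response, *spec.fixed_terms]
    n_before = len(df)
    df = df.dropna(subset=used)
    return df, n_before - len(df)


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> MixedModelResult:
    """Fit the random-intercept mixed model by maximum likelihood.

    Rows with missing values in any used column are dropped listwise (the
    count is reported in the result).  Requires at least two subjects with
    at least two rows each.
    """
    df, n_dropped = _prepare(table, spec)
    counts = df["subject_id"].value_counts()
    if (counts >= 2).sum() < 2:
        raise ValidationError(
            "need >= 2 subjects with >= 2 rows each for a random-intercept model"
        )
    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    for t in spec.fixed_terms:
        X[t] = df[t].astype(float)
    _check_collinearity(X)
    y = df[spec.response].to_numpy(dtype=float)

    model = sm.MixedLM(y, X, groups=df["subject_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False)
    if not np.all(np.isfinite(res.fe_params)):
        raise RuntimeError(f"mixed-model fit did not converge: {res.summary()}")

    est = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    dof = len(df) - rank
    tstat = est / se
    p = 2.0 * spstats.t.sf(np.abs(tstat), dof)
    tcrit = spstats.t.ppf(0.975, dof)
    out = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "t": tstat,
            "p": p,
            "ci_lo": est - tcrit * se,
            "ci_hi": est + tcrit * se,
        },
        index=list(X.columns),
    )
    return MixedModelResult(
        table=out,
        var_subject=float(np.asarray(res.cov_re)[0, 0]),
        var_resid=float(res.scale),
        loglik=float(res.llf),
        n_obs=len(df),
        n_subjects=df["subject_id"].nunique(),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# direct posture / sensor-height comparisons

#: The four comparison groups behind the 10-contrast family per metric:
#: natural arm positions across postures, heart-height positions across
#: postures, sitting sensor heights, and standing sensor heights.
COMPARISON_GROUPS: dict[str, tuple[Condition, ...]] = {
    "natural_position": (
        Condition.STANDING_ARM_DOWN,
        Condition.SITTING_ARM_LAP,
        Condition.SUPINE,
    ),
    "heart_height": (
        Condition.SUPINE,
        Condition.SITTING_ARM_UP,
        Condition.STANDING_ARM_UP,
    ),
    "sitting_heights": (
        Condition.SITTING_ARM_DOWN,
        Condition.SITTING_ARM_LAP,
        Condition.SITTING_ARM_UP,
    ),
    "standing_heights": (Condition.STANDING_ARM_DOWN, Condition.STANDING_ARM_UP),
}


@dataclass(frozen=True)
class Contrast:
    metric: str
    group: str
    cond_a: Condition
    cond_b: Condition

    @property
    def label(self) -> str:
        return f"{self.metric}: {self.cond_a.value} vs {self.cond_b.value} ({self.group})"


def enumerate_direct_comparisons(
    conditions: Sequence[Condition],
    metrics: Sequence[str] = METRICS,
) -> list[Contrast]:
    """Enumerate the pairwise posture/height contrasts for each metric.

    With the full six-condition design this yields 10 contrasts per metric
    (30 in total for the three quality metrics).  On a subset, only pairs
    whose both conditions are present are kept; if none can be formed the
    absent levels are reported.
    """
    present = {Condition(c) for c in conditions}
    contrasts = []
    for metric in metrics:
        for group, conds in COMPARISON_GROUPS.items():
            for i in range(len(conds)):
                for j in range(i + 1, len(conds)):
                    if conds[i] in present and conds[j] in present:
                        contrasts.append(Contrast(metric, group, conds[i], conds[j]))
    if not contrasts:
        absent = sorted(
            {c.value for g in COMPARISON_GROUPS.values() for c in g} - {c.value for c in present}
        )
        raise ValidationError(f"no contrast can be formed; absent condition levels: {absent}")
    return contrasts


def fit_contrast(table: pd.DataFrame, contrast: Contrast) -> tuple[float, float]:
    """Fit ``metric ~ condition + (1 | subject)`` on a two-condition subset.

    Returns the condition-B coefficient (B minus A) and its p-value.
    """
    sub = table[table["condition"].isin([contrast.cond_a.value, contrast.cond_b.value])].copy()
    sub["_is_b"] = (sub["condition"] == contrast.cond_b.value).astype(float)
    spec = ModelSpec(response=contrast.metric, fixed_terms=("_is_b",))
    res = fit_lmm(sub, spec)
    return res.coef("_is_b"), res.pvalue("_is_b")


# ---------------------------------------------------------------------------
# Holm–Šidák step-down correction


@dataclass
class TestFamily:
    """A family of tests with Holm–Šidák adjusted p-values."""

    labels: list[str]
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    reject: np.ndarray
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "p_raw": self.p_raw,
                "p_adjusted": self.p_adjusted,
                "reject": self.reject,
            }
        )


def holm_sidak(
    pvals: Sequence[float],
    alpha: float = 0.05,
    labels: Optional[Sequence[str]] = None,
) -> TestFamily:
    """Step-down Holm–Šidák family-wise error correction.

    Sorted ascending, the i-th smallest p-value is adjusted to
    ``1 - (1 - p_(i))^(m - i + 1)``; a running maximum enforces
    monotonicity, and hypotheses are rejected step-down while the adjusted
    p-value is below ``alpha``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("pvals must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)

    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if adj_sorted[i] < alpha:
            reject_sorted[i] = True
        else:
            break
    reject = np.zeros(m, dtype=bool)
    reject[order] = reject_sorted

    if labels is None:
        labels = [f"test_{i}" for i in range(m)]
    return TestFamily(list(labels), p, adj, reject, alpha)


# ---------------------------------------------------------------------------
# descriptive summaries


def boxplot_stats(values: Sequence[float]) -> dict:
    """Median, quartiles, whiskers and outliers of one metric's values.

    Quartiles use linear interpolation of order statistics; whiskers sit at
    the most extreme data within 1.5 IQR of the quartiles; anything beyond
    is listed as an outlier.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValidationError("boxplot_stats needs at least one finite value")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "outliers": np.sort(x[(x < lo_fence) | (x > hi_fence)]).tolist(),
    }


def metric_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation between two metrics, pairwise-complete.

    Returns NaN when fewer than 3 complete pairs remain or either side has
    zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def summarize_metric(values: Sequence[float]) -> dict:
    """Non-parametric (median, quartiles) and parametric (mean, SD) summary."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValidationError("summarize_metric needs at least one finite value")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "n": int(x.size),
    }
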