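"""Linear/quadratic age models for connectivity metrics.

For every metric and scope the pipeline fits both Y = b0 + b1*age and
Y = b0 + b1*age + b2*age^2 by ordinary least squares, selects between them
with the extra-sum-of-squares F test (quadratic only when its added term is
significant), reports the overall regression p-value and the coefficient of
multiple correlation r of the chosen model, and summarizes the lifespan
effect as the predicted values at ages 20 and 80 plus their percent
difference.  Report tables round values to 2 decimals and percentages to 1
decimal (half away from zero); internal results carry full precision.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ParcellationAtlas
from .exceptions import InputError
from .metrics import compute_nodal_metrics, count_hubs_by_scope, identify_hubs, network_summaries
from .network import ConnectivityMatrix

__all__ = [
    "ModelFit",
    "AgeModelFit",
    "CohortGroups",
    "fit_age_models",
    "select_model",
    "predict_and_diff",
    "round_half_away",
    "tertile_groups",
    "group_matrix_summary",
    "run_full_analysis",
    "hub_count_table",
]

METRIC_NAMES = ("mean_strength", "char_path_length", "clustering", "local_efficiency")


@dataclass(frozen=True)
class ModelFit:
    """One polynomial OLS fit: coefficients in increasing order of power."""

    kind: str
    beta: tuple[float, ...]
    sse: float
    sst: float
    n: int
    p_value: float

    @property
    def df_model(self) -> int:
        return len(self.beta) - 1


@dataclass(frozen=True)
class AgeModelFit:
    """The model chosen by the F test, with goodness of fit."""

    kind: str
    beta: tuple[float, ...]
    p_value: float
    r: float
    n: int
    significant: bool
    metric: str = ""
    scope: str = ""

    def predict(self, age: float) -> float:
        return float(np.polynomial.polynomial.polyval(age, self.beta))


@dataclass
class CohortGroups:
    """Age-tertile group labels (young / middle / old) per subject."""

    labels: np.ndarray
    sizes: dict[str, int]


def _ols_poly(y: np.ndarray, ages: np.ndarray, degree: int) -> ModelFit:
    x = np.vander(ages, degree + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    n = y.size
    df_m = degree
    df_e = n - df_m - 1
    if sst <= 0:
        p = 1.0
    elif sse <= 1e-14 * max(sst, 1.0):
        p = 0.0
    else:
        f = ((sst - sse) / df_m) / (sse / df_e)
        p = float(stats.f.sf(max(f, 0.0), df_m, df_e))
    kind = "linear" if degree == 1 else "quadratic"
    return ModelFit(kind, tuple(float(b) for b in beta), sse, sst, n, p)


def fit_age_models(values, ages) -> tuple[ModelFit, ModelFit]:
    """Fit the linear and the quadratic age model by OLS."""
    y = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if y.shape != a.shape or y.ndim != 1:
        raise InputError("values and ages must be 1-d and aligned")
    if y.size < 4:
        raise InputError("need at least 4 subjects")
    if np.ptp(a) == 0:
        raise InputError("ages are all equal (rank-deficient design)")
    return _ols_poly(y, a, 1), _ols_poly(y, a, 2)


def select_model(linear: ModelFit, quadratic: ModelFit, alpha: float = 0.05) -> AgeModelFit:
    """Extra-sum-of-squares F test between the nested age models.

    F = (SSE_lin - SSE_quad) / (SSE_quad / (n - 3)); quadratic is chosen iff
    the added term is significant at ``alpha``.  When both models
    interpolate exactly (SSE = 0) the simpler linear model is retained.
    The returned fit is flagged non-significant when its overall regression
    p-value is at or above ``alpha`` (the "/" convention in report tables).
    """
    if linear.n != quadratic.n:
        raise InputError("fits come from different data")
    n = linear.n
    if n <= 3:
        raise InputError("need n > 3 for the nested F test")
    tol = 1e-14 * max(linear.sst, 1.0)
    if linear.sse <= tol and quadratic.sse <= tol:
        chosen = linear  # tie: simpler model
    elif quadratic.sse <= tol:
        chosen = quadratic
    else:
        f_add = (linear.sse - quadratic.sse) / (quadratic.sse / (n - 3))
        p_add = float(stats.f.sf(max(f_add, 0.0), 1, n - 3))
        chosen = quadratic if p_add < alpha else linear
    r = float(np.sqrt(max(0.0, 1.0 - chosen.sse / chosen.sst))) if chosen.sst > 0 else 0.0
    return AgeModelFit(
        kind=chosen.kind,
        beta=chosen.beta,
        p_value=chosen.p_value,
        r=r,
        n=n,
        significant=chosen.p_value < alpha,
    )


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (report-table convention)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def predict_and_diff(
    fit: AgeModelFit,
    age_low: float = 20.0,
    age_high: float = 80.0,
    round_output: bool = True,
) -> tuple[float, float, float]:
    """Model predictions at the two reference ages plus the % difference.

    %diff = 100 * (Y(age_high) - Y(age_low)) / Y(age_low).  With
    ``round_output`` the predictions are rounded to 2 decimals and the
    percentage to 1 decimal, half away from zero; rounding is applied to
    the full-precision results, never propagated.
    """
    y_low = fit.predict(age_low)
    y_high = fit.predict(age_high)
    pct = 100.0 * (y_high - y_low) / y_low if y_low != 0 else np.nan
    if round_output:
        return round_half_away(y_low, 2), round_half_away(y_high, 2), round_half_away(pct, 1)
    return y_low, y_high, pct


def tertile_groups(ages, subject_ids=None) -> CohortGroups:
    """Age-sorted split into three near-equal groups.

    Sizes are as equal as possible with the remainder going to the oldest
    groups (n = 67 gives 22/22/23).  Ties in age are broken by subject id.
    """
    a = np.asarray(ages, dtype=float)
    n = a.size
    if n < 3:
        raise InputError("need at least 3 subjects for tertiles")
    sids = np.arange(n) if subject_ids is None else np.asarray(subject_ids)
    order = np.lexsort((sids, a))
    base, rem = divmod(n, 3)
    sizes = [base, base + (1 if rem == 2 else 0), base + (1 if rem >= 1 else 0)]
    labels = np.empty(n, dtype=object)
    start = 0
    for name, size in zip(("young", "middle", "old"), sizes):
        labels[order[start : start + size]] = name
        start += size
    return CohortGroups(labels, {"young": sizes[0], "middle": sizes[1], "old": sizes[2]})


def group_matrix_summary(
    matrices: list[ConnectivityMatrix],
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise mean and coefficient of variation across subjects.

    CoV is the sample standard deviation (ddof=1) divided by the mean;
    cells with zero mean get CoV 0.
    """
    if len(matrices) < 2:
        raise InputError("need at least 2 matrices per group")
    ids0 = matrices[0].node_ids
    for m in matrices[1:]:
        if not np.array_equal(m.node_ids, ids0):
            raise InputError("matrices have mismatching node sets")
    stack = np.stack([m.weights for m in matrices])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    cov = np.divide(sd, mean, out=np.zeros_like(sd), where=mean != 0)
    return mean, cov


def _cohort_metric_table(
    matrices: list[ConnectivityMatrix],
    atlas: ParcellationAtlas | pd.DataFrame,
    metrics: tuple[str, ...],
    include_pairs: bool,
) -> pd.DataFrame:
    frames = []
    for i, m in enumerate(matrices):
        t = network_summaries(m, atlas, include_pairs=include_pairs, metrics=metrics)
        t.insert(0, "subject", i)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def run_full_analysis(
    matrices: list[ConnectivityMatrix],
    ages,
    atlas: ParcellationAtlas | pd.DataFrame,
    alpha: float = 0.05,
    metrics: tuple[str, ...] = METRIC_NAMES,
    include_pairs: bool = True,
    age_low: float = 20.0,
    age_high: float = 80.0,
) -> pd.DataFrame:
    """Regress every metric x scope on age and tabulate the chosen models.

    One row per metric and scope (whole brain, each functional network,
    and - for mean strength - every between-network pair): chosen model,
    overall p, r, coefficients, predictions at the reference ages and the
    lifespan percent difference.  Rows with overall p >= alpha are flagged
    non-significant; report writers render them with the "/" convention.
    """
    ages = np.asarray(ages, dtype=float)
    if len(matrices) != ages.size:
        raise InputError("one matrix per subject required")
    if ages.size < 4:
        raise InputError("need at least 4 subjects")
    long = _cohort_metric_table(matrices, atlas, metrics, include_pairs)
    rows = []
    for scope, sub in long.groupby("scope", sort=False):
        sub = sub.sort_values("subject")
        for metric in metrics:
            if metric not in sub.columns:
                continue
            y = sub[metric].to_numpy(dtype=float)
            if np.isnan(y).any():
                continue  # scope too small for this metric
            lin, quad = fit_age_models(y, ages)
            fit = select_model(lin, quad, alpha=alpha)
            y20, y80, pct = predict_and_diff(fit, age_low, age_high, round_output=False)
            beta = fit.beta + (np.nan,) * (3 - len(fit.beta))
            rows.append(
                {
                    "metric": metric,
                    "scope": scope,
                    "model": fit.kind,
                    "p_value": fit.p_value,
                    "p_linear": lin.p_value,
                    "r": fit.r,
                    "beta0": beta[0],
                    "beta1": beta[1],
                    "beta2": beta[2],
                    "pred_low": y20,
                    "pred_high": y80,
                    "pct_diff": pct,
                    "significant": fit.significant,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)


def render_report(report: pd.DataFrame) -> pd.DataFrame:
    """Rounded, "/"-styled view of an analysis report (string cells)."""
    out = []
    for _, row in report.iterrows():
        if not row["significant"]:
            styled = {k: "/" for k in ("model", "r", "beta0", "beta1", "beta2", "pred_low", "pred_high", "pct_diff")}
        else:
            styled = {
                "model": row["model"],
                "r": f"{round_half_away(row['r'], 2):.2f}",
                "beta0": f"{round_half_away(row['beta0'], 4):.4f}",
                "beta1": f"{row['beta1']:.3e}",
                "beta2": "/" if np.isnan(row["beta2"]) else f"{row['beta2']:.3e}",
                "pred_low": f"{round_half_away(row['pred_low'], 2):.2f}",
                "pred_high": f"{round_half_away(row['pred_high'], 2):.2f}",
                "pct_diff": f"{round_half_away(row['pct_diff'], 1):.1f}",
            }
        out.append({"metric": row["metric"], "scope": row["scope"], "p_value": f"{row['p_value']:.4f}", **styled})
    return pd.DataFrame(out)


def hub_count_table(
    matrices: list[ConnectivityMatrix],
    ages,
    atlas: ParcellationAtlas | pd.DataFrame,
    top_fraction: float = 0.20,
) -> pd.DataFrame:
    """Median (IQR) hub counts per scope for the whole cohort and the
    young / middle / old tertile groups."""
    groups = tertile_groups(ages)
    per_subject = []
    for m in matrices:
        nodal = compute_nodal_metrics(m, include_local_efficiency=False)
        hubs = identify_hubs(nodal, top_fraction=top_fraction)
        per_subject.append(count_hubs_by_scope(hubs, atlas))
    counts = pd.DataFrame(per_subject).reset_index(drop=True)
    counts["group"] = groups.labels

    def med_iqr(s: pd.Series) -> str:
        q1, med, q3 = np.percentile(s.to_numpy(dtype=float), [25, 50, 75])
        return f"{med:g} ({q1:g}-{q3:g})"

    scopes = [c for c in counts.columns if c != "group"]
    rows = []
    for scope in scopes:
        row = {"scope": scope, "all": med_iqr(counts[scope])}
        for g in ("young", "middle", "old"):
            row[g] = med_iqr(counts.loc[counts["group"] == g, scope])
        rows.append(row)
    return pd.DataFrame(rows)
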