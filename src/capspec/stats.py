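"""Statistical tail: robust outlier removal, two-way ANOVA, summaries.

Outliers are flagged with the ROUT procedure (robust fit followed by an
FDR-controlled residual test at level Q) applied to a constant model: the
robust center is an iterative Lorentzian-weighted mean, the robust scale is
the RSDR (68.27th percentile of absolute residuals with a small-sample
correction), and points are tested with a Benjamini-Hochberg-style threshold
on their t-like residual ratios.  Fields of view flagged in any imaging
period are excluded from all periods to preserve matching across time.
Group-by-period effects are assessed with a two-factor fixed-effects ANOVA
and Bonferroni-adjusted per-period contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class OutlierMask:
    flags: np.ndarray
    q: float

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)


@dataclass
class AnovaResult:
    f_group: float
    p_group: float
    f_period: float
    p_period: float
    f_interaction: float
    p_interaction: float
    posthoc: pd.DataFrame
    cell_means: pd.DataFrame
    mse: float
    df_resid: int


def _rsdr(residuals: np.ndarray, n_params: int = 1) -> float:
    """Robust standard deviation of residuals: corrected 68.27th percentile."""
    n = residuals.size
    p68 = np.percentile(np.abs(residuals), 68.27)
    return float(p68 * n / max(n - n_params, 1))


def _robust_center(values: np.ndarray, max_iter: int = 100, tol: float = 1e-10) -> float:
    """Lorentzian-weighted robust mean (constant-model robust fit)."""
    c = float(np.median(values))
    for _ in range(max_iter):
        r = values - c
        s = _rsdr(r)
        if s <= 0:
            return c
        w = 1.0 / (1.0 + (r / s) ** 2)
        c_new = float(np.sum(w * values) / np.sum(w))
        if abs(c_new - c) < tol * max(abs(c), 1.0):
            return c_new
        c = c_new
    return c


def rout_outliers(values, q: float = 0.01) -> OutlierMask:
    """ROUT outlier detection at FDR level ``q`` on a column of values.

    Fits the robust center, forms t-like ratios ``|r| / RSDR`` whose
    one-tailed P values (standard-normal reference on the absolute ratio)
    are screened with a Benjamini-Hochberg threshold at level ``q``; the
    largest residuals passing are flagged.  ``q = 0`` is the degenerate
    limit where nothing is flagged.  Requires ``n >= 10`` for a stable
    robust scale.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 10:
        raise ValueError(f"ROUT needs at least 10 values, got {n}")
    if not (0.0 <= q <= 0.1):
        raise ValueError("Q must be in [0, 0.1]")
    flags = np.zeros(n, dtype=bool)
    if q == 0.0:  # vanishing threshold: nothing can be flagged
        return OutlierMask(flags, q)
    c = _robust_center(values)
    r = values - c
    s = _rsdr(r)
    if s <= 0:
        return OutlierMask(flags, q)
    t = np.abs(r) / s
    p = sps.norm.sf(t)
    order = np.argsort(p)
    thresholds = q * (np.arange(1, n + 1)) / n
    passing = p[order] <= thresholds
    if np.any(passing):
        k = int(np.max(np.flatnonzero(passing))) + 1
        flags[order[:k]] = True
    return OutlierMask(flags, q)


def rout_flags_by_period(
    table: pd.DataFrame, q: float = 0.01, value_col: str = "value"
) -> pd.Series:
    """Apply ROUT within each imaging period; boolean flags aligned to rows."""
    flags = pd.Series(False, index=table.index)
    for period, sub in table.groupby("imaging_period"):
        mask = rout_outliers(sub[value_col].to_numpy(), q)
        flags.loc[sub.index] = mask.flags
    return flags


def matched_field_exclusion(
    table: pd.DataFrame, flags: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Drop every row of any field of view flagged in *any* imaging period.

    Removal counts per period are logged.  Idempotent: re-applying with the
    surviving rows' flags changes nothing.
    """
    flags = pd.Series(np.asarray(flags, dtype=bool), index=table.index)
    bad_fovs = set(table.loc[flags, "fov_id"])
    if not bad_fovs:
        return table.copy()
    removed = table[table["fov_id"].isin(bad_fovs)]
    for period, sub in removed.groupby("imaging_period"):
        logger.info(
            "matched_field_exclusion: removed %d rows at period %s", len(sub), period
        )
    return table[~table["fov_id"].isin(bad_fovs)].copy()


def _check_cells(table: pd.DataFrame) -> None:
    groups = sorted(table["group_label"].unique())
    periods = sorted(table["imaging_period"].unique())
    if len(groups) < 2 or len(periods) < 2:
        raise ValueError("need both groups and at least 2 imaging periods")
    for g in groups:
        for p in periods:
            if ((table["group_label"] == g) & (table["imaging_period"] == p)).sum() == 0:
                raise ValueError(f"empty cell: group={g!r}, period={p!r}")


def two_way_anova(
    table: pd.DataFrame, value_col: str = "value", n_comparisons: int | None = None
) -> AnovaResult:
    """Two-factor fixed-effects ANOVA (group x period) with Bonferroni contrasts.

    Effects use type-III sums of squares with sum-to-zero coding (robust to
    unbalanced tables).  Post-hoc: per-period control-vs-treatment contrasts
    on the pooled residual variance, raw P multiplied by the number of
    periods and capped at 1.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    _check_cells(table)
    df = table.rename(columns={value_col: "value"})[
        ["group_label", "imaging_period", "value"]
    ].copy()
    periods = sorted(df["imaging_period"].unique())
    groups = sorted(df["group_label"].unique())
    n_comp = n_comparisons if n_comparisons is not None else len(periods)

    cell_means = (
        df.groupby(["group_label", "imaging_period"])["value"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count")
        .reset_index()
    )

    if np.ptp(df["value"].to_numpy()) == 0:
        posthoc = pd.DataFrame(
            {
                "imaging_period": periods,
                "t": 0.0,
                "p_raw": 1.0,
                "p_adjusted": 1.0,
                "diff": 0.0,
            }
        )
        return AnovaResult(0.0, 1.0, 0.0, 1.0, 0.0, 1.0, posthoc, cell_means, 0.0, 0)

    model = smf.ols(
        "value ~ C(group_label, Sum) * C(imaging_period, Sum)", data=df
    ).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = anova_lm(model, typ=3)
    f_group = float(aov.loc["C(group_label, Sum)", "F"])
    p_group = float(aov.loc["C(group_label, Sum)", "PR(>F)"])
    f_period = float(aov.loc["C(imaging_period, Sum)", "F"])
    p_period = float(aov.loc["C(imaging_period, Sum)", "PR(>F)"])
    inter = "C(group_label, Sum):C(imaging_period, Sum)"
    f_inter = float(aov.loc[inter, "F"])
    p_inter = float(aov.loc[inter, "PR(>F)"])
    mse = float(aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"])
    df_resid = int(aov.loc["Residual", "df"])

    rows = []
    for p in periods:
        a = df[(df["imaging_period"] == p) & (df["group_label"] == groups[0])]["value"]
        b = df[(df["imaging_period"] == p) & (df["group_label"] == groups[1])]["value"]
        diff = b.mean() - a.mean()
        se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
        t = diff / se if se > 0 else 0.0
        p_raw = 2.0 * sps.t.sf(abs(t), df=df_resid) if se > 0 else 1.0
        rows.append(
            {
                "imaging_period": p,
                "diff": diff,
                "t": t,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * n_comp),
            }
        )
    posthoc = pd.DataFrame(rows)
    return AnovaResult(
        f_group, p_group, f_period, p_period, f_inter, p_inter,
        posthoc, cell_means, mse, df_resid,
    )


def summarize_groups(table: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Mean and SEM per (group, period) cell; SEM is NaN (with a warning) at n=1."""
    rows = []
    for (g, p), sub in table.groupby(["group_label", "imaging_period"]):
        n = len(sub)
        mean = sub[value_col].mean()
        if n >= 2:
            sem = sub[value_col].std(ddof=1) / np.sqrt(n)
        else:
            warnings.warn(
                f"cell (group={g}, period={p}) has n=1; SEM undefined", stacklevel=2
            )
            sem = np.nan
        rows.append(
            {"group_label": g, "imaging_period": p, "n": n, "mean": mean, "sem": sem}
        )
    return pd.DataFrame(rows)


def power_heatmap_table(table: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """FOV x imaging-period matrix of band-peak Power.

    Rows are fields of view ordered by (animal, fov); columns are the
    imaging periods; missing cells are NaN.  Duplicate (fov, period)
    entries are an error.
    """
    dup = table.duplicated(subset=["fov_id", "imaging_period"])
    if dup.any():
        bad = table.loc[dup, ["fov_id", "imaging_period"]].iloc[0]
        raise ValueError(
            f"duplicate entry for fov={bad['fov_id']!r}, period={bad['imaging_period']!r}"
        )
    cols = ["animal_id", "fov_id"] if "animal_id" in table.columns else ["fov_id"]
    pivot = table.pivot(index=cols, columns="imaging_period", values=value_col)
    return pivot.sort_index()


def plot_power_heatmap(pivot: pd.DataFrame, ax=None, **imshow_kw):
    """Render a heat-map table with matplotlib; returns the Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, max(2, 0.25 * len(pivot))))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", **imshow_kw)
    ax.set_xticks(range(pivot.shape[1]), [str(c) for c in pivot.columns])
    labels = [
        "/".join(str(part) for part in (idx if isinstance(idx, tuple) else (idx,)))
        for idx in pivot.index
    ]
    ax.set_yticks(range(pivot.shape[0]), labels)
    ax.set_xlabel("imaging period")
    ax.figure.colorbar(im, ax=ax, label="peak Power (amplitude$^2$)")
    return ax
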