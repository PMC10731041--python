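"""Group assignment and statistics for temporal metrics and edgewise strength.

Groups are defined from the Epworth Sleepiness Scale (ESS): scores ≥ 10
define the excessive-daytime-sleepiness (EDS) group, ≤ 3 the non-EDS
group, and 4–9 are excluded.  Continuous metrics are compared with a
two-sample t test when both groups look normal with comparable
variances (Shapiro–Wilk and Levene screens) and a Mann–Whitney U test
otherwise; p-values are Benjamini–Hochberg FDR-adjusted within a family.
Metric–ESS associations use Spearman correlation partialled for
covariates by rank residualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "assign_groups",
    "compare_groups",
    "fdr_adjust",
    "partial_spearman",
    "chi_squared",
    "temporal_metric_comparison",
    "edgewise_state_comparison",
]

EDS_THRESHOLD = 10
NOEDS_THRESHOLD = 3


@dataclass
class TestResult:
    """Outcome of one two-group comparison."""

    variable: str
    test: str
    statistic: float
    p: float
    q: float | None = None
    summaries: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def assign_groups(ess_scores) -> np.ndarray:
    """Map ESS scores to {'EDS', 'noEDS', 'excluded'}.

    ≥ 10 → EDS; ≤ 3 → noEDS; 4–9 → excluded from group tests.
    """
    ess = np.asarray(ess_scores, dtype=float)
    if np.any(~np.isfinite(ess)) or np.any(ess < 0) or np.any(ess > 24):
        raise ValueError("ESS scores must lie in [0, 24]")
    out = np.where(ess >= EDS_THRESHOLD, "EDS", np.where(ess <= NOEDS_THRESHOLD, "noEDS", "excluded"))
    return out.astype(object)


def _two_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = [g for g in pd.unique(groups) if g != "excluded"]
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {names}")
    a = values[groups == names[0]]
    b = values[groups == names[1]]
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs at least 2 observations")
    return names, a, b


def compare_groups(
    values,
    groups,
    variable: str = "metric",
    normality_alpha: float = 0.05,
    variance_alpha: float = 0.05,
) -> TestResult:
    """Two-sided two-group comparison with automatic test choice.

    Two-sample t when both Shapiro–Wilk p ≥ ``normality_alpha`` and
    Levene p ≥ ``variance_alpha``; Mann–Whitney U otherwise.  Degenerate
    zero-variance-in-both input returns p = 1 with a flag.
    """
    names, a, b = _two_groups(values, groups)
    summaries = {
        names[0]: {"n": a.size, "mean": float(a.mean()), "sd": float(a.std(ddof=1)),
                   "median": float(np.median(a))},
        names[1]: {"n": b.size, "mean": float(b.mean()), "sd": float(b.std(ddof=1)),
                   "median": float(np.median(b))},
    }
    if a.std() == 0 and b.std() == 0:
        flags = ["zero variance in both groups"]
        stat = 0.0 if a.mean() == b.mean() else np.inf
        p = 1.0 if a.mean() == b.mean() else 0.0
        return TestResult(variable, "degenerate", stat, p, summaries=summaries, flags=flags)
    use_t = False
    if a.std() > 0 and b.std() > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw_a = sps.shapiro(a).pvalue
            sw_b = sps.shapiro(b).pvalue
            lev = sps.levene(a, b).pvalue
        use_t = sw_a >= normality_alpha and sw_b >= normality_alpha and lev >= variance_alpha
    if use_t:
        res = sps.ttest_ind(a, b)
        return TestResult(variable, "t", float(res.statistic), float(res.pvalue), summaries=summaries)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(variable, "mann-whitney", float(res.statistic), float(res.pvalue), summaries=summaries)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, ≤ 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def partial_spearman(x, y, covariates=None) -> tuple[float, float]:
    """Spearman correlation of ``x`` and ``y`` partialled for covariates.

    Both variables are rank-transformed; ranks are residualized on the
    covariates (plus intercept) by least squares and the Pearson
    correlation of the residuals is tested with the t approximation at
    n − 2 − #covariates degrees of freedom.  With no covariates this
    reduces to ordinary Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    ncov = z.shape[1]
    if n <= ncov + 2:
        raise ValueError("need n > number of covariates + 2")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant input: partial Spearman undefined", stacklevel=2)
        return np.nan, np.nan
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    design = np.column_stack([np.ones(n), z])
    rx = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ry = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    rho = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - ncov
    rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = rho_c * np.sqrt(df / (1 - rho_c**2))
    p = float(2 * sps.t.sf(abs(t), df))
    return rho, p


def chi_squared(categorical, groups, yates: bool = False, variable: str = "categorical") -> TestResult:
    """Pearson chi-squared test of association between category and group.

    Continuity correction is off by default (``yates`` enables it for
    2×2 tables).  Empty categories are dropped with a warning.
    """
    cat = pd.Series(categorical, name="cat").reset_index(drop=True)
    grp = pd.Series(np.asarray(groups, dtype=object), name="grp")
    keep = grp != "excluded"
    table = pd.crosstab(grp[keep], cat[keep], dropna=False)
    empty_cols = table.columns[(table.sum(axis=0) == 0)]
    if len(empty_cols):
        warnings.warn(f"dropping empty categories: {list(empty_cols)}", stacklevel=2)
        table = table.drop(columns=empty_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(table.to_numpy(), correction=yates)
    return TestResult(
        variable, "chi2", float(chi2), float(p),
        summaries={"table": table.to_dict(), "dof": int(dof)},
    )


def temporal_metric_comparison(
    metrics: pd.DataFrame,
    groups,
    family: str = "all",
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Group contrasts for every temporal-metric column, FDR within family.

    ``metrics`` holds one row per subject with fractional-time, dwell and
    transition columns (as produced by ``temporal_metrics_table``).
    ``family='all'`` adjusts all metric×state tests jointly;
    ``family='per-metric'`` adjusts fractional-time, dwell and transition
    families separately.
    """
    groups = np.asarray(groups)
    cols = [
        c for c in metrics.columns
        if c.startswith("frac_time_s") or c == "n_transitions"
        or (c.startswith("dwell_s") and not c.startswith("dwell_sec"))
    ]
    results = [
        compare_groups(metrics[c].to_numpy(), groups, variable=c, normality_alpha=normality_alpha)
        for c in cols
    ]
    df = pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "test": [r.test for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p for r in results],
        }
    )
    if family == "all":
        df["q"] = fdr_adjust(df["p"].to_numpy())
    elif family == "per-metric":
        df["q"] = np.nan
        for prefix in ("frac_time_s", "dwell_s", "n_transitions"):
            mask = df["variable"].str.startswith(prefix)
            if mask.any():
                df.loc[mask, "q"] = fdr_adjust(df.loc[mask, "p"].to_numpy())
    else:
        raise ValueError("family must be 'all' or 'per-metric'")
    for r, q in zip(results, df["q"]):
        r.q = float(q)
    df.attrs["results"] = results
    return df


def edgewise_state_comparison(
    strength_tables: dict[int, pd.DataFrame],
    groups_by_subject: pd.Series,
    alpha: float = 0.05,
    family: str = "per-state",
) -> dict[int, pd.DataFrame]:
    """Per-state edgewise two-sample t tests with BH-FDR across edges.

    ``strength_tables`` maps state → subjects×edges mean-z table (missing
    subjects already dropped).  Edgewise contrasts use the t test
    throughout; the FDR family is the set of edges within each state
    (default) or every edge of every state jointly (``family='pooled'``).
    States visited by fewer than 2 subjects per group are skipped with a
    warning.
    """
    if family not in ("per-state", "pooled"):
        raise ValueError("family must be 'per-state' or 'pooled'")
    out: dict[int, pd.DataFrame] = {}
    for state, table in strength_tables.items():
        grp = groups_by_subject.reindex(table.index)
        keep = grp.isin(["EDS", "noEDS"])
        table = table.loc[keep]
        grp = grp.loc[keep]
        n_eds = int((grp == "EDS").sum())
        n_no = int((grp == "noEDS").sum())
        if min(n_eds, n_no) < 2:
            warnings.warn(
                f"state {state}: fewer than 2 subjects per group ({n_eds} EDS, "
                f"{n_no} noEDS); skipped",
                stacklevel=2,
            )
            continue
        a = table.loc[grp == "EDS"].to_numpy()
        b = table.loc[grp == "noEDS"].to_numpy()
        res = sps.ttest_ind(a, b, axis=0)
        out[state] = pd.DataFrame(
            {
                "edge": table.columns,
                "t": res.statistic,
                "p": res.pvalue,
                "mean_EDS": a.mean(axis=0),
                "mean_noEDS": b.mean(axis=0),
            }
        )
    if family == "pooled" and out:
        pooled = fdr_adjust(np.concatenate([df["p"].to_numpy() for df in out.values()]))
        offset = 0
        for df in out.values():
            df["q"] = pooled[offset : offset + len(df)]
            offset += len(df)
    else:
        for df in out.values():
            df["q"] = fdr_adjust(df["p"].to_numpy())
    for df in out.values():
        df["significant"] = df["q"] < alpha
    return out
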