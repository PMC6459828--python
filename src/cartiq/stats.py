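"""Statistical battery for the loading-response analysis.

Log-transformation with omnibus normality checking, one-way repeated-
measures ANOVA across the three displacement positions with Tukey post-hoc
comparisons on the within-subject error term, unpaired two-sample t-tests on
log-transformed values, Spearman rank correlation, and noncentral-t power /
sample-size computation for two-sample designs.

Significance is conventionally stratified as p <= 0.05 (*), <= 0.01 (**),
<= 0.001 (***); no correction is applied across test families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "log_transform_check",
    "rm_anova",
    "rm_anova_tukey",
    "unpaired_t_log",
    "spearman",
    "sample_size_unpaired",
    "significance_marker",
    "longitudinal_block",
    "analyze_cohort_table",
]


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    name: str
    statistic: float
    p_value: float
    effect: dict = field(default_factory=dict)
    posthoc: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p_value) and self.p_value <= 0.05


def significance_marker(p: float) -> str:
    """Star notation: * for p <= 0.05, ** for <= 0.01, *** for <= 0.001."""
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def log_transform_check(values) -> tuple[np.ndarray, float]:
    """Natural-log transform plus an omnibus normality p-value.

    The normality check is the combined skewness/kurtosis (D'Agostino &
    Pearson) omnibus test on the transformed values.  With fewer than eight
    observations the test is unavailable and NaN is returned alongside the
    transform.

    Raises
    ------
    ValueError
        If any value is non-positive.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("log transform requires strictly positive values")
    logged = np.log(x)
    if x.size < 8 or np.allclose(logged, logged[0]):
        return logged, float("nan")
    _, p = sps.normaltest(logged)
    return logged, float(p)


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction factor."""
    k = data.shape[1]
    cov = np.cov(data, rowvar=False)
    mean_diag = np.trace(cov) / k
    mean_all = cov.mean()
    row_means = cov.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (
        np.sum(cov**2) - 2 * k * np.sum(row_means**2) + k**2 * mean_all**2
    )
    if den == 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova(data, gg_correction: bool = False) -> TestResult:
    """One-way within-subject ANOVA on an ``(n_subjects, k_conditions)`` block.

    Decomposes total variation into condition, subject and residual
    (subject x condition) sums of squares; F is the condition mean square
    over the residual mean square.  Complete cases only.

    Degenerate blocks (no condition effect and no residual variance) are
    flagged and reported as F = 0, p = 1.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("data must be (n_subjects, k_conditions) with k >= 2")
    if np.any(~np.isfinite(x)):
        raise ValueError("block contains missing values; complete cases required")
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = x.mean()
    ss_cond = n * float(np.sum((x.mean(axis=0) - grand) ** 2))
    ss_subj = k * float(np.sum((x.mean(axis=1) - grand) ** 2))
    ss_tot = float(np.sum((x - grand) ** 2))
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    flags = []
    if ss_cond == 0.0:
        return TestResult(
            name="rm_anova", statistic=0.0, p_value=1.0,
            effect={"df": (df_cond, df_err), "ss": (ss_cond, ss_subj, ss_err)},
            flags=["no condition effect"],
        )
    if ss_err == 0.0:
        return TestResult(
            name="rm_anova", statistic=float("inf"), p_value=0.0,
            effect={"df": (df_cond, df_err), "ss": (ss_cond, ss_subj, ss_err)},
            flags=["zero residual variance"],
        )
    eps = _gg_epsilon(x) if gg_correction else 1.0
    f = (ss_cond / df_cond) / (ss_err / df_err)
    p = float(sps.f.sf(f, df_cond * eps, df_err * eps))
    if gg_correction:
        flags.append(f"gg_epsilon={eps:.4f}")
    return TestResult(
        name="rm_anova",
        statistic=float(f),
        p_value=p,
        effect={
            "df": (df_cond, df_err),
            "ss": (ss_cond, ss_subj, ss_err),
            "ms_error": ss_err / df_err,
        },
        flags=flags,
    )


def rm_anova_tukey(
    data,
    condition_labels: tuple[str, ...] | None = None,
    gg_correction: bool = False,
) -> TestResult:
    """Repeated-measures ANOVA followed by Tukey pairwise comparisons.

    Pairwise p-values use the studentized range with the within-subject
    residual mean square and its degrees of freedom.
    """
    x = np.asarray(data, dtype=float)
    result = rm_anova(x, gg_correction=gg_correction)
    n, k = x.shape
    labels = condition_labels or tuple(f"c{i}" for i in range(k))
    if len(labels) != k:
        raise ValueError("condition_labels length must equal the number of conditions")
    ms_err = result.effect.get("ms_error")
    df_err = result.effect["df"][1]
    means = x.mean(axis=0)
    posthoc = {}
    for i in range(k):
        for j in range(i + 1, k):
            pair = f"{labels[i]}-{labels[j]}"
            if ms_err is None or ms_err <= 0:
                posthoc[pair] = 1.0 if means[i] == means[j] else 0.0
                continue
            q = abs(means[i] - means[j]) / np.sqrt(ms_err / n)
            posthoc[pair] = float(sps.studentized_range.sf(q, k, df_err))
    result.posthoc = posthoc
    return result


def unpaired_t_log(group_a, group_b) -> TestResult:
    """Two-tailed unpaired t-test on natural-log-transformed values.

    Raises
    ------
    ValueError
        For non-positive values or groups smaller than two.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("log transform requires strictly positive values")
    la, lb = np.log(a), np.log(b)
    if np.var(la) == 0 and np.var(lb) == 0:
        if np.isclose(la.mean(), lb.mean()):
            return TestResult(
                name="unpaired_t_log", statistic=0.0, p_value=1.0,
                flags=["degenerate variance"],
            )
        return TestResult(
            name="unpaired_t_log", statistic=float("inf"), p_value=0.0,
            flags=["degenerate variance"],
        )
    t, p = sps.ttest_ind(la, lb, equal_var=True)
    return TestResult(name="unpaired_t_log", statistic=float(t), p_value=float(p))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with tie-corrected ranks, two-tailed p.

    Constant inputs leave the coefficient undefined (NaN, flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(
            name="spearman", statistic=float("nan"), p_value=float("nan"),
            flags=["constant input"],
        )
    rho, p = sps.spearmanr(x, y)
    return TestResult(name="spearman", statistic=float(rho), p_value=float(p))


def two_sample_t_power(n_per_group: int, effect_size_d: float, alpha: float) -> float:
    """Power of the two-sided two-sample t-test via the noncentral t."""
    df = 2 * n_per_group - 2
    if df < 1:
        return 0.0
    nc = effect_size_d * np.sqrt(n_per_group / 2.0)
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - sps.nct.cdf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc))


def sample_size_unpaired(
    power: float, alpha: float, effect_size_d: float, n_max: int = 1_000_000
) -> int:
    """Smallest per-group n reaching the requested two-sample t-test power.

    Power is evaluated exactly through the noncentral t distribution at the
    given effect size (Cohen's d) and two-sided alpha.

    Raises
    ------
    ValueError
        For parameters outside (0, 1) / non-positive effect size, or if the
        power is unreachable below ``n_max``.
    """
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if effect_size_d <= 0:
        raise ValueError("effect size must be positive")
    n = 2
    while n <= n_max:
        if two_sample_t_power(n, effect_size_d, alpha) >= power:
            return n
        n += 1
    raise ValueError(f"requested power {power} unreachable below n = {n_max}")


_DISPLACEMENTS = ("d0", "d2.5", "d5.0")


def longitudinal_block(
    table: pd.DataFrame, parameter: str, zone: str, group: str | None = None
) -> np.ndarray:
    """Extract an ``(n_samples, 3)`` displacement block from a tidy table.

    Complete cases only: samples missing any displacement mean are dropped.
    ``group=None`` pools both groups.
    """
    sel = (table["parameter"] == parameter) & (table["zone"] == zone)
    if group is not None:
        sel &= table["group"] == group
    wide = (
        table.loc[sel]
        .pivot(index="sample_id", columns="displacement", values="mean")
        .reindex(columns=list(_DISPLACEMENTS))
        .dropna()
    )
    return wide.to_numpy(dtype=float)


def analyze_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Run the full statistical battery over a tidy cohort table.

    Per (group | pooled, parameter, zone): log-transformed repeated-measures
    ANOVA across displacements with Tukey post-tests.  Per (parameter,
    zone): unpaired t-test between groups at each displacement, and Spearman
    correlations of the relative changes against sum score and modulus.
    Returns one tidy row per test.
    """
    rows = []
    params = sorted(table["parameter"].unique())
    zones = [z for z in ("ECS", "sf", "dp") if z in set(table["zone"])]
    for param in params:
        for zone in zones:
            for group in (None, "int", "deg"):
                block = longitudinal_block(table, param, zone, group)
                if block.shape[0] < 3 or np.any(block <= 0):
                    continue
                res = rm_anova_tukey(np.log(block), condition_labels=_DISPLACEMENTS)
                rows.append(
                    {
                        "family": "longitudinal",
                        "test": "rm_anova_tukey",
                        "parameter": param,
                        "zone": zone,
                        "group": group or "all",
                        "displacement": "",
                        "n": block.shape[0],
                        "statistic": res.statistic,
                        "p": res.p_value,
                        "marker": significance_marker(res.p_value),
                        **{f"p_{k}": v for k, v in res.posthoc.items()},
                    }
                )
            for disp in _DISPLACEMENTS:
                sel = (
                    (table["parameter"] == param)
                    & (table["zone"] == zone)
                    & (table["displacement"] == disp)
                )
                a = table.loc[sel & (table["group"] == "int"), "mean"].dropna()
                b = table.loc[sel & (table["group"] == "deg"), "mean"].dropna()
                if len(a) < 2 or len(b) < 2 or (a <= 0).any() or (b <= 0).any():
                    continue
                res = unpaired_t_log(a.to_numpy(), b.to_numpy())
                rows.append(
                    {
                        "family": "group_comparison",
                        "test": "unpaired_t_log",
                        "parameter": param,
                        "zone": zone,
                        "group": "int_vs_deg",
                        "displacement": disp,
                        "n": len(a) + len(b),
                        "statistic": res.statistic,
                        "p": res.p_value,
                        "marker": significance_marker(res.p_value),
                    }
                )
            for disp in ("d2.5", "d5.0"):
                sel = (
                    (table["parameter"] == param)
                    & (table["zone"] == zone)
                    & (table["displacement"] == disp)
                )
                sub = table.loc[sel, ["delta_pct", "mss", "young_modulus"]].dropna()
                for ref in ("mss", "young_modulus"):
                    if len(sub) < 3 or sub[ref].nunique() < 2:
                        continue
                    if sub["delta_pct"].nunique() < 2:
                        continue
                    res = spearman(sub["delta_pct"].to_numpy(), sub[ref].to_numpy())
                    rows.append(
                        {
                            "family": "correlation",
                            "test": f"spearman_delta_vs_{ref}",
                            "parameter": param,
                            "zone": zone,
                            "group": "all",
                            "displacement": disp,
                            "n": len(sub),
                            "statistic": res.statistic,
                            "p": res.p_value,
                            "marker": significance_marker(res.p_value),
                        }
                    )
    return pd.DataFrame(rows)
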