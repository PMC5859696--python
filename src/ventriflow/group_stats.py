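"""Group comparison statistics for per-subject flow results.

The comparison stage mirrors a conventional two-group cardiology
workflow: each parameter is checked for normality per group with a
Kolmogorov-Smirnov test, normally distributed parameters are compared
with an unpaired Student's t test (pooled variance), non-normal ones
with a Mann-Whitney U test, and continuous associations with QRS
duration are assessed by simple linear regression.

Because the original tests ran against a fitted normal, the KS test
here uses the Lilliefors correction for estimated mean and SD (a plain
KS test with estimated parameters would be anti-conservative).  The
pooled t branch can also run directly from printed summary statistics
(mean, SD, n), which are sufficient for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors


class StatsError(ValueError):
    pass


def format_p(p: float) -> str:
    """Three-decimal P value, '<0.001' below that."""
    if not np.isfinite(p):
        return "nan"
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


@dataclass
class NormalityRouting:
    test: str                # "t" or "mwu"
    p_normal_a: float
    p_normal_b: float
    degenerate: bool = False


def _ks_normal_p(x: np.ndarray) -> float:
    return float(lilliefors(x, dist="norm")[1])


def normality_route(a, b, alpha: float = 0.05) -> NormalityRouting:
    """Choose t test vs Mann-Whitney U from per-group normality.

    Both groups must pass the KS (Lilliefors) normality check at the
    given alpha for the t branch.  Constant (zero-variance) samples are
    degenerate for the normality test and are routed to Mann-Whitney
    with a flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise StatsError("normality routing needs at least 3 observations per group")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return NormalityRouting(test="mwu", p_normal_a=np.nan, p_normal_b=np.nan,
                                degenerate=True)
    pa, pb = _ks_normal_p(a), _ks_normal_p(b)
    test = "t" if (pa > alpha and pb > alpha) else "mwu"
    return NormalityRouting(test=test, p_normal_a=pa, p_normal_b=pb)


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
) -> tuple[float, float]:
    """Two-sided pooled-variance t test from sufficient statistics."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def routed_compare(a, b, alpha: float = 0.05, welch: bool = False) -> tuple[float, str, NormalityRouting]:
    """Normality-routed two-group comparison; returns (P, test, routing)."""
    routing = normality_route(a, b, alpha=alpha)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if routing.test == "t":
        res = stats.ttest_ind(a, b, equal_var=not welch)
        return float(res.pvalue), "t", routing
    if np.ptp(np.concatenate([a, b])) == 0.0:
        # identical constants: no evidence of any difference
        return 1.0, "mwu", routing
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue), "mwu", routing


@dataclass
class ComparisonRow:
    parameter: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    test: str
    p_value: float
    p_formatted: str
    normal_a: float
    normal_b: float


def compare_groups(
    table: pd.DataFrame,
    parameters: list[str] | None = None,
    group_col: str = "group",
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-parameter two-group comparison of a tidy subject table.

    ``table`` has one row per subject; ``group_col`` must take exactly
    two values.  Returns one row per parameter with group means +/- SD,
    the routed test and its two-sided P value.
    """
    groups = sorted(table[group_col].dropna().unique().tolist())
    if len(groups) != 2:
        raise StatsError(f"need exactly two groups, found {groups}")
    if parameters is None:
        parameters = [
            c for c in table.columns
            if c != group_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    missing = [p for p in parameters if p not in table.columns]
    if missing:
        raise StatsError(f"parameter column(s) missing from table: {missing}")
    rows = []
    for param in parameters:
        a = table.loc[table[group_col] == groups[0], param].dropna().to_numpy(float)
        b = table.loc[table[group_col] == groups[1], param].dropna().to_numpy(float)
        p, test, routing = routed_compare(a, b, alpha=alpha, welch=welch)
        rows.append(ComparisonRow(
            parameter=param,
            mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=len(a),
            mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=len(b),
            test=test, p_value=p, p_formatted=format_p(p),
            normal_a=routing.p_normal_a, normal_b=routing.p_normal_b,
        ))
    out = pd.DataFrame([r.__dict__ for r in rows])
    out.attrs["groups"] = groups
    return out


@dataclass
class RegressionResult:
    parameter: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def regress_vs_qrs(
    table: pd.DataFrame,
    parameter: str,
    qrs_col: str = "qrs_duration",
) -> RegressionResult:
    """Ordinary least-squares simple regression of a parameter on QRS duration."""
    if parameter not in table.columns:
        raise StatsError(f"parameter column missing: {parameter}")
    if qrs_col not in table.columns:
        raise StatsError(f"QRS column missing: {qrs_col}")
    sub = table[[qrs_col, parameter]].dropna()
    if len(sub) < 3:
        raise StatsError("regression needs at least 3 complete observations")
    x = sub[qrs_col].to_numpy(float)
    y = sub[parameter].to_numpy(float)
    if np.ptp(x) == 0.0:
        raise StatsError("QRS duration has zero variance; regression undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        parameter=parameter,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(sub),
    )


def type_i_error_rate(
    n_per_group: int = 11,
    reps: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> float:
    """Monte-Carlo type-I error of the routed two-group procedure.

    Both groups are drawn from the same standard normal; the fraction of
    repetitions with P < alpha estimates the realized false-positive
    rate, which should sit near alpha for a well-calibrated router.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        a = rng.standard_normal(n_per_group)
        b = rng.standard_normal(n_per_group)
        p, _, _ = routed_compare(a, b, alpha=alpha)
        if p < alpha:
            hits += 1
    return hits / reps
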