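"""Statistical layer: rank tests, contingency tests, survival, overlap.

Thin, contract-checked wrappers around scipy.stats and lifelines so every
cohort comparison in the pipeline states its test, direction and sample
sizes explicitly and is reproducible from the report alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import EmptyGroupError, InputError

#: combined sample size up to which the Mann-Whitney null is enumerated exactly
MW_EXACT_MAX_N = 20
#: default gene universe for the overlap test
OVERLAP_UNIVERSE_DEFAULT = 20_000


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float  # U of the first sample
    p_value: float
    alternative: str
    n_x: int
    n_y: int
    method: str  # "exact" | "asymptotic"


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    dof: int


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    curves: pd.DataFrame  # columns: group, time, survival, at_risk


@dataclass(frozen=True)
class OverlapResult:
    k: int
    n_a: int
    n_b: int
    n_universe: int
    p_value: float  # upper tail P(X >= k); may underflow to 0.0
    log10_p: float  # exact log-space tail, safe below 1e-300


def mann_whitney_one_sided(
    x, y, alternative: str = "greater"
) -> MannWhitneyResult:
    """One-sided Mann-Whitney U test of x against y.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties, otherwise the normal approximation with
    tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("mann_whitney_one_sided: both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise InputError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= MW_EXACT_MAX_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return MannWhitneyResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        n_x=int(x.size),
        n_y=int(y.size),
        method=method,
    )


def _check_counts(table: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(table)
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(np.asarray(arr, dtype=float))
        if not np.allclose(arr, rounded):
            raise InputError(f"{name}: counts must be integers")
        arr = rounded.astype(int)
    if (arr < 0).any():
        raise InputError(f"{name}: counts must be non-negative")
    return arr


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (sum of tables with
    probability at most the observed)."""
    arr = _check_counts(table, "fisher_exact_2x2")
    if arr.shape != (2, 2):
        raise InputError(f"fisher_exact_2x2: expected a 2x2 table, got shape {arr.shape}")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def chi_square_2xk(table, correction: bool = False) -> Chi2Result:
    """Pearson chi-square test on an r x k count table.

    No continuity correction by default. A zero expected count is an error
    (use Fisher's exact test instead).
    """
    arr = _check_counts(table, "chi_square_2xk")
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise InputError("chi_square_2xk: need a table with at least 2 rows and 2 columns")
    total = arr.sum()
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total if total else None
    if total == 0 or (expected == 0).any():
        raise InputError(
            "chi_square_2xk: a zero expected count makes the Pearson statistic "
            "undefined; consider fisher_exact_2x2"
        )
    stat, p, dof, _ = sps.chi2_contingency(arr, correction=correction)
    return Chi2Result(statistic=float(stat), p_value=float(p), dof=int(dof))


def km_curve(time, event) -> pd.DataFrame:
    """Product-limit survival estimate with right-censoring.

    Returns a step table (time, survival, at_risk) including the S(0) = 1
    anchor; survival is non-increasing and steps only at event times.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise EmptyGroupError("km_curve: no records")
    if (time <= 0).any():
        raise InputError("km_curve: all times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"]
    out = pd.DataFrame(
        {
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        }
    )
    out["at_risk"] = at_risk.reindex(sf.index).ffill().to_numpy(dtype=float)
    return out


def km_logrank(records: pd.DataFrame, group_a: str, group_b: str) -> LogrankResult:
    """Kaplan-Meier curves for two groups plus the two-sided log-rank test.

    ``records`` needs columns time (years, > 0), event (bool) and group.
    """
    needed = {"time", "event", "group"}
    if not needed.issubset(records.columns):
        raise InputError(f"km_logrank: records must have columns {sorted(needed)}")
    curves = []
    subsets = {}
    for g in (group_a, group_b):
        sub = records[records["group"] == g]
        if len(sub) == 0:
            raise EmptyGroupError(f"km_logrank: group {g!r} has no records")
        subsets[g] = sub
        c = km_curve(sub["time"], sub["event"])
        c.insert(0, "group", g)
        curves.append(c)
    if not (records["event"].astype(bool)).any():
        raise InputError("km_logrank: need at least one observed event")
    a, b = subsets[group_a], subsets[group_b]
    res = logrank_test(
        a["time"], b["time"],
        event_observed_A=a["event"].astype(bool),
        event_observed_B=b["event"].astype(bool),
    )
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        curves=pd.concat(curves, ignore_index=True),
    )


def hypergeom_overlap(
    k: int, n_a: int, n_b: int, n_universe: int = OVERLAP_UNIVERSE_DEFAULT
) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap between two gene lists.

    P(X >= k) where X is the overlap of a random size-``n_b`` draw from a
    universe of ``n_universe`` genes containing ``n_a`` marked genes. The
    log10 tail is computed in log space so p-values far below 1e-300
    remain usable.
    """
    for name, v in (("k", k), ("n_a", n_a), ("n_b", n_b), ("n_universe", n_universe)):
        if int(v) != v or v < 0:
            raise InputError(f"hypergeom_overlap: {name} must be a non-negative integer")
    k, n_a, n_b, n_universe = int(k), int(n_a), int(n_b), int(n_universe)
    if k > min(n_a, n_b):
        raise InputError(
            f"hypergeom_overlap: overlap k={k} exceeds min(n_a, n_b)={min(n_a, n_b)}"
        )
    if max(n_a, n_b) > n_universe:
        raise InputError("hypergeom_overlap: list sizes exceed the universe")
    dist = sps.hypergeom(M=n_universe, n=n_a, N=n_b)
    p = float(dist.sf(k - 1))
    log_p = float(dist.logsf(k - 1)) / math.log(10.0)
    return OverlapResult(
        k=k, n_a=n_a, n_b=n_b, n_universe=n_universe, p_value=p, log10_p=log_p
    )
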