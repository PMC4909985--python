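"""Cohort-level statistics for mosaic event carriers.

Wilson proportion intervals, exact binomial tests, 2x2 odds ratios with
Woolf intervals, logistic regression by iteratively reweighted least
squares, length-adjusted event rates and the standard event summary
tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

COHORT_COLUMNS = (
    "sample_id", "age", "case_status", "dna_source", "study_id",
    "ancestry_eur", "ancestry_afr", "ancestry_asn",
    "has_x_event", "has_autosomal_event", "x_event_count", "mean_fraction",
)

#: Default age bin edges (years): <50, 5-year bins, >=75 top bin.
DEFAULT_AGE_BINS = (50, 55, 60, 65, 70, 75)


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure x outcome cell counts: a, b / c, d (exposed row first)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against the expected schema."""
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    if (df["age"] <= 0).any():
        raise ValueError("ages must be positive")
    anc = df[["ancestry_eur", "ancestry_afr", "ancestry_asn"]].sum(axis=1)
    if (np.abs(anc - 1.0) > 1e-6).any():
        raise ValueError("ancestry fractions must sum to 1")
    bad = set(df["case_status"].unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown case_status values {sorted(bad)}")
    return df


def wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    z = stats.norm.ppf((1.0 + conf) / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(center - half, 0.0), min(center + half, 1.0))


def two_sided_binomial(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value by doubling the smaller tail."""
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie in (0, 1)")
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def odds_ratio(
    t: TwoByTwo, conf: float = 0.95, continuity: bool = False
) -> tuple[float, float, float]:
    """Odds ratio ad/bc with the Woolf log-scale confidence interval.

    Zero cells raise unless ``continuity`` enables the Haldane-Anscombe
    0.5 correction.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        if not continuity:
            raise ValueError(
                "zero cell in 2x2 table; enable continuity=True for the "
                "Haldane-Anscombe correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    z = stats.norm.ppf((1.0 + conf) / 2.0)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        float(or_),
        float(np.exp(np.log(or_) - z * se)),
        float(np.exp(np.log(or_) + z * se)),
    )


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic regression fit."""

    coef: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    odds_ratios: np.ndarray
    n_iter: int
    converged: bool


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    add_intercept: bool = True,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogisticFit:
    """Fit a logistic regression by iteratively reweighted least squares.

    Convergence when the maximum absolute score falls below ``tol``.
    Raises on rank-deficient designs and on complete separation
    (a coefficient diverging beyond 15).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {p} columns)"
        )
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        info = (X * w[:, None]).T @ X
        beta = beta + np.linalg.solve(info, score)
        if np.max(np.abs(beta)) > 15:
            raise ValueError(
                "complete separation detected (coefficient diverged beyond 15)"
            )
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return LogisticFit(
        coef=beta, se=se, zvalues=z, pvalues=pvals,
        odds_ratios=np.exp(beta), n_iter=it, converged=converged,
    )


def length_adjusted_rate(
    n_events: int, n_individuals: int, territory_mb: float
) -> float:
    """Events per 10,000 Mb of scanned territory.

    rate = n_events / (n_individuals * territory_mb / 1e4).  Note: this
    definition does not reproduce previously published rate values whose
    adjustment was not specified; it is this package's documented choice.
    """
    if n_individuals <= 0 or territory_mb <= 0:
        raise ValueError("n_individuals and territory_mb must be positive")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    return n_events / (n_individuals * territory_mb / 1e4)


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Welch t-test (statistic, two-sided p)."""
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _age_bin_labels(edges: tuple[int, ...]) -> list[str]:
    labels = [f"<{edges[0]}"]
    for lo, hi in zip(edges, edges[1:]):
        labels.append(f"{lo}-{hi - 1}")
    labels.append(f">={edges[-1]}")
    return labels


def summarize_events(
    calls: pd.DataFrame,
    cohort: pd.DataFrame,
    age_bins: tuple[int, ...] = DEFAULT_AGE_BINS,
    conf: float = 0.95,
) -> dict[str, pd.DataFrame]:
    """Standard event summary tables.

    ``calls`` needs columns sample_id, state, location, fraction (one row
    per event; may be empty).  Returns tables keyed ``by_state``,
    ``by_location``, ``prevalence``, ``prevalence_by_age``,
    ``multi_event`` and ``fraction_summary``, all deterministically
    ordered.
    """
    validate_cohort(cohort)
    if len(calls):
        unknown = set(calls["sample_id"]) - set(cohort["sample_id"])
        if unknown:
            raise ValueError(
                f"call sample ids missing from cohort: {sorted(unknown)[:10]}"
            )

    from .event_caller import LOCATIONS, STATES

    n_events = len(calls)
    by_state = pd.DataFrame(
        {
            "state": list(STATES),
            "count": [int((calls["state"] == s).sum()) if n_events else 0
                      for s in STATES],
        }
    )
    by_state["percent"] = (
        100.0 * by_state["count"] / n_events if n_events else 0.0
    )
    by_location = pd.DataFrame(
        {
            "location": list(LOCATIONS),
            "count": [int((calls["location"] == l).sum()) if n_events else 0
                      for l in LOCATIONS],
        }
    )
    by_location["percent"] = (
        100.0 * by_location["count"] / n_events if n_events else 0.0
    )

    carriers = (
        calls.groupby("sample_id").size() if n_events else pd.Series(dtype=int)
    )
    n_carriers = len(carriers)
    n_total = len(cohort)
    lo, hi = wilson_ci(n_carriers, n_total, conf)
    prevalence = pd.DataFrame(
        {
            "n_carriers": [n_carriers],
            "n_total": [n_total],
            "percent": [100.0 * n_carriers / n_total],
            "ci_lower_percent": [100.0 * lo],
            "ci_upper_percent": [100.0 * hi],
        }
    )

    edges = (0,) + tuple(age_bins) + (np.inf,)
    labels = _age_bin_labels(tuple(age_bins))
    carrier_ids = set(carriers.index)
    binned = pd.cut(cohort["age"], bins=edges, labels=labels, right=False)
    rows = []
    for label in labels:
        members = cohort.loc[binned == label, "sample_id"]
        n = len(members)
        k = sum(1 for s in members if s in carrier_ids)
        if n:
            blo, bhi = wilson_ci(k, n, conf)
            rows.append((label, k, n, 100.0 * k / n, 100.0 * blo, 100.0 * bhi))
        else:
            rows.append((label, 0, 0, np.nan, np.nan, np.nan))
    prevalence_by_age = pd.DataFrame(
        rows,
        columns=["age_bin", "n_carriers", "n_total", "percent",
                 "ci_lower_percent", "ci_upper_percent"],
    )

    n_multi = int((carriers > 1).sum()) if n_carriers else 0
    multi_event = pd.DataFrame(
        {
            "n_multi_event_carriers": [n_multi],
            "n_carriers": [n_carriers],
            "percent": [100.0 * n_multi / n_carriers if n_carriers else 0.0],
        }
    )

    if n_events:
        frac = calls.groupby("sample_id")["fraction"].mean()
        fraction_summary = pd.DataFrame(
            {
                "n_carriers": [n_carriers],
                "mean_fraction": [float(frac.mean())],
                "sd_fraction": [float(frac.std(ddof=1)) if n_carriers > 1
                                else np.nan],
            }
        )
    else:
        fraction_summary = pd.DataFrame(
            {"n_carriers": [0], "mean_fraction": [np.nan], "sd_fraction": [np.nan]}
        )

    return {
        "by_state": by_state,
        "by_location": by_location,
        "prevalence": prevalence,
        "prevalence_by_age": prevalence_by_age,
        "multi_event": multi_event,
        "fraction_summary": fraction_summary,
    }
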