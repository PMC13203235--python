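"""Two-sample comparison and exploratory correlation layer.

Sign convention throughout: the first sample is the reference (pre) group and
the second the comparison (post) group; a negative rank-biserial correlation
means the second group is stochastically smaller.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import PatientCovariates
from .errors import InsufficientDataError, RowValidationError
from .metrics import VariabilityProfile, summarize_profiles

DEFAULT_EXACT_LIMIT = 400  # exact Mann-Whitney when n_a * n_b <= this and no ties


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float  # U for the first sample
    p_value: float
    method: str  # "exact" or "asymptotic"
    n_a: int
    n_b: int


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration p-value when the samples are tie-free and
    ``n_a * n_b <= exact_limit``; otherwise the normal approximation with
    tie correction and continuity correction.  The method actually used is
    recorded in the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("Mann-Whitney requires two nonempty samples")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and a.size * b.size <= exact_limit:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "asymptotic"
    return MannWhitneyResult(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def rank_biserial(a: Sequence[float], b: Sequence[float]) -> float:
    """Rank-biserial correlation (Cliff's delta): (#{b > a} - #{a > b}) / (n_a n_b).

    Computed from midranks (ties contribute half-credit to U, i.e. zero to the
    pair difference), so the value lies in [-1, 1] and is negative when the
    second sample is stochastically smaller.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("rank-biserial requires two nonempty samples")
    ranks = sps.rankdata(np.concatenate([a, b]))
    rank_sum_b = ranks[a.size :].sum()
    u_b = rank_sum_b - b.size * (b.size + 1) / 2.0  # counts (b > a), ties as 1/2
    return float(2.0 * u_b / (a.size * b.size) - 1.0)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p-value by the point-probability method.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.
    Deterministic; returns a value in (0, 1].
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise RowValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise RowValidationError("table cells must be nonnegative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if row1 + (c + d) == 0 or col1 + (b + d) == 0 or n_total == 0:
        raise RowValidationError("table must have positive marginals")
    # vary the (0,0) cell over the hypergeometric support at fixed margins
    k_min = max(0, row1 + col1 - n_total)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = sps.hypergeom.pmf(support, n_total, row1, col1)
    p_obs = sps.hypergeom.pmf(a, n_total, row1, col1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class CorrelationResult:
    name: str
    rho: float
    p_value: float
    n_pairs: int
    method: str


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    name: str = "",
    method: str = "t_approx",
) -> CorrelationResult:
    """Spearman rank correlation with pairwise-complete missing handling.

    ``method="t_approx"`` (default) uses the t approximation for the
    two-sided p; ``method="permutation"`` enumerates all permutations
    exactly (only allowed for n <= 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise RowValidationError(
            f"length mismatch: {x.size} vs {y.size}"
        )
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise InsufficientDataError(
            f"Spearman correlation requires >= 3 complete pairs, got {n}"
        )
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise InsufficientDataError(
            "Spearman correlation undefined for constant input"
        )
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "permutation":
        if n > 10:
            raise InsufficientDataError(
                f"exact permutation p only supported for n <= 10, got {n}"
            )
        p = _spearman_permutation_p(rx, ry, rho)
    elif method == "t_approx":
        res = sps.spearmanr(x, y)
        p = float(res.pvalue)
    else:
        raise RowValidationError(f"unknown method {method!r}")
    return CorrelationResult(
        name=name, rho=rho, p_value=min(p, 1.0), n_pairs=n, method=method
    )


def _spearman_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    n = rx.size
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    count = 0
    total = 0
    thresh = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        rho = float(rx_c @ ry_c[list(perm)]) / denom
        if abs(rho) >= thresh:
            count += 1
        total += 1
    return count / total


@dataclass(frozen=True)
class ComparisonResult:
    """One row of the cohort-comparison table."""

    metric: str
    test: str  # "mann_whitney" or "fisher_exact"
    pre_median: float | None
    pre_q1: float | None
    pre_q3: float | None
    post_median: float | None
    post_q1: float | None
    post_q3: float | None
    u_statistic: float | None
    p_value: float
    effect_size_rrb: float | None
    method: str
    pre_counts: tuple[int, int] | None = None  # (stable, total) for fisher rows
    post_counts: tuple[int, int] | None = None


COMPARISON_METRICS = (
    "cv_pct",
    "swing_index",
    "trough_range",
    "mssd",
    "n_zone_changes",
    "mean_trough",
)


def build_comparison_table(
    pre: Iterable[VariabilityProfile],
    post: Iterable[VariabilityProfile],
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> list[ComparisonResult]:
    """Metric-by-metric two-sample comparison plus the stable-patient 2x2 row."""
    pre = list(pre)
    post = list(post)
    if not pre or not post:
        raise InsufficientDataError("both cohorts must be nonempty for comparison")
    pre_summary = summarize_profiles(pre, COMPARISON_METRICS)
    post_summary = summarize_profiles(post, COMPARISON_METRICS)
    rows: list[ComparisonResult] = []
    for metric in COMPARISON_METRICS:
        a = [getattr(p, metric) for p in pre]
        b = [getattr(p, metric) for p in post]
        mw = mann_whitney(a, b, exact_limit=exact_limit)
        rows.append(
            ComparisonResult(
                metric=metric,
                test="mann_whitney",
                pre_median=pre_summary[metric].median,
                pre_q1=pre_summary[metric].q1,
                pre_q3=pre_summary[metric].q3,
                post_median=post_summary[metric].median,
                post_q1=post_summary[metric].q1,
                post_q3=post_summary[metric].q3,
                u_statistic=mw.u_statistic,
                p_value=mw.p_value,
                effect_size_rrb=rank_biserial(a, b),
                method=mw.method,
            )
        )
    n_stable_pre = sum(p.stable for p in pre)
    n_stable_post = sum(p.stable for p in post)
    table = [
        [n_stable_pre, len(pre) - n_stable_pre],
        [n_stable_post, len(post) - n_stable_post],
    ]
    rows.append(
        ComparisonResult(
            metric="stable_patients",
            test="fisher_exact",
            pre_median=None,
            pre_q1=None,
            pre_q3=None,
            post_median=None,
            post_q1=None,
            post_q3=None,
            u_statistic=None,
            p_value=fisher_exact_2x2(table),
            effect_size_rrb=None,
            method="point_probability",
            pre_counts=(n_stable_pre, len(pre)),
            post_counts=(n_stable_post, len(post)),
        )
    )
    return rows


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional output, not part of the
    default report)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        running_max = max(running_max, (m - rank) * p[idx])
        adjusted[idx] = min(running_max, 1.0)
    return adjusted.tolist()


DEFAULT_COVARIATES = (
    "age",
    "egfr",
    "weight",
    "therapy_duration",
    "loading_dose",
    "n_dose_adjustments",
)


def explore_predictors(
    profiles: Iterable[VariabilityProfile],
    covariates: Mapping[str, PatientCovariates],
    covariate_names: Sequence[str] = DEFAULT_COVARIATES,
    method: str = "t_approx",
) -> tuple[list[CorrelationResult], int]:
    """Spearman correlation of each covariate against patient-level CV%.

    Profiles without a matching covariate record are dropped; the number of
    unmatched patients is returned alongside the results.
    """
    profiles = list(profiles)
    matched = [p for p in profiles if p.patient_id in covariates]
    n_unmatched = len(profiles) - len(matched)
    if not matched:
        raise InsufficientDataError("no patients matched between profiles and covariates")
    cv = np.asarray([p.cv_pct for p in matched], dtype=float)
    results = []
    for name in covariate_names:
        vals = np.asarray(
            [
                float(v) if (v := getattr(covariates[p.patient_id], name)) is not None
                else math.nan
                for p in matched
            ],
            dtype=float,
        )
        try:
            results.append(spearman_rho(vals, cv, name=name, method=method))
        except InsufficientDataError:
            continue  # covariate almost entirely missing; skip its row
    return results, n_unmatched


def comparison_to_frame(rows: Iterable[ComparisonResult]) -> pd.DataFrame:
    """Full-precision comparison table for CSV export."""
    records = []
    for r in rows:
        records.append(
            {
                "metric": r.metric,
                "test": r.test,
                "pre_median": r.pre_median,
                "pre_q1": r.pre_q1,
                "pre_q3": r.pre_q3,
                "post_median": r.post_median,
                "post_q1": r.post_q1,
                "post_q3": r.post_q3,
                "u_statistic": r.u_statistic,
                "p_value": r.p_value,
                "effect_size_rrb": r.effect_size_rrb,
                "method": r.method,
                "pre_counts": (
                    f"{r.pre_counts[0]}/{r.pre_counts[1]}" if r.pre_counts else None
                ),
                "post_counts": (
                    f"{r.post_counts[0]}/{r.post_counts[1]}" if r.post_counts else None
                ),
            }
        )
    return pd.DataFrame.from_records(records)


def comparison_to_markdown(rows: Iterable[ComparisonResult]) -> str:
    """Human-readable table: one decimal for metrics, three for p, two for r_rb."""
    lines = [
        "| Metric | Pre (median, IQR) | Post (median, IQR) | p-value | r_rb |",
        "|---|---|---|---|---|",
    ]
    for r in rows:
        if r.test == "fisher_exact":
            sp, np_ = r.pre_counts, r.post_counts
            pre = f"{sp[0]}/{sp[1]} ({100.0 * sp[0] / sp[1]:.1f}%)"
            post = f"{np_[0]}/{np_[1]} ({100.0 * np_[0] / np_[1]:.1f}%)"
            rrb = "—"
        else:
            pre = f"{r.pre_median:.1f} ({r.pre_q1:.1f}–{r.pre_q3:.1f})"
            post = f"{r.post_median:.1f} ({r.post_q1:.1f}–{r.post_q3:.1f})"
            rrb = f"{r.effect_size_rrb:+.2f}"
        lines.append(f"| {r.metric} | {pre} | {post} | {r.p_value:.3f} | {rrb} |")
    return "\n".join(lines) + "\n"
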