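"""Exact nonparametric two-sample statistics and the cohort report.

Group comparisons in small behavioural cohorts (here n = 20 young vs.
10 aged animals, with heavy ties from session-quantised trial counts)
call for the exact, tie-aware Mann-Whitney U test.  The exact null
distribution of the rank sum under ties is computed by a shift
(convolution) dynamic programme over integer-doubled midrank scores,
which enumerates all C(n, n_a) group assignments implicitly; this is
feasible well beyond the cohort sizes used here.  Larger problems fall
back to the normal approximation with the usual tie correction.

Medians and ranges use the standard order-statistic convention
(mean of the two central values at even n).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "mann_whitney_u",
    "median_and_range",
    "spearman_rho",
    "replicate_cohort_report",
]

#: largest n_a * n_b for which the exact null distribution is computed
DEFAULT_EXACT_BOUND = 400


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-group Mann-Whitney comparison."""

    measure: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    range_a: tuple[float, float]
    range_b: tuple[float, float]
    U: float
    p: float
    method: Literal["EXACT", "NORMAL_APPROX"]
    note: str | None = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.U <= self.n_a * self.n_b / 2 + 1e-9
        assert 0.0 <= self.p <= 1.0


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    rho: float
    p: float


def median_and_range(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, min, max); median is the middle order statistic, or the
    mean of the two middle order statistics at even n."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return float(np.median(v)), float(v.min()), float(v.max())


def _u_statistics(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(U1, U2) with ties contributing 1/2 per tied cross-group pair."""
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))  # midranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return u1, n1 * n2 - u1


def _exact_ranksum_p(
    ranks: np.ndarray, n1: int, r1_obs: float
) -> float:
    """Exact two-sided p for the observed rank sum of group 1.

    Shift algorithm: midranks are doubled to integers; the number of
    ways to pick n1 of the pooled scores with each achievable total is
    accumulated by dynamic programming.  The two-sided p doubles the
    smaller exact tail (P(W <= w) vs. P(W >= w)), capped at 1.
    """
    scores = np.rint(2 * ranks).astype(np.int64)
    total = int(scores.sum())
    # dp[k, s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for sc in scores:
        # descending k so each item is used at most once per subset
        for k in range(n1, 0, -1):
            dp[k, sc:] += dp[k - 1, : total + 1 - sc]
    counts = dp[n1]
    n_total = counts.sum()  # = C(n, n1)
    w = int(round(2 * r1_obs))
    lower = counts[: w + 1].sum() / n_total
    upper = counts[w:].sum() / n_total
    return float(min(1.0, 2.0 * min(lower, upper)))


def _normal_approx_p(ranks: np.ndarray, n1: int, u1: float) -> float:
    """Two-sided normal approximation with tie correction and
    continuity correction."""
    n = len(ranks)
    n2 = n - n1
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum()
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    *,
    measure: str = "",
    group_a: str = "a",
    group_b: str = "b",
    exact_bound: int = DEFAULT_EXACT_BOUND,
    note: str | None = None,
) -> ComparisonResult:
    """Tie-aware Mann-Whitney U test with an exact two-sided p-value.

    U1 counts, over all cross-group pairs, wins of ``x`` (1), ties
    (1/2) and losses (0); the reported statistic is U = min(U1, U2).
    The p-value is exact (implicit enumeration of all group
    assignments, respecting ties) whenever n_a * n_b does not exceed
    ``exact_bound``, otherwise the tie-corrected normal approximation
    is used; the ``method`` field records which.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(xa), len(ya)
    u1, u2 = _u_statistics(xa, ya)
    ranks = stats.rankdata(np.concatenate([xa, ya]))
    r1 = ranks[:n1].sum()
    if n1 * n2 <= exact_bound:
        p = _exact_ranksum_p(ranks, n1, r1)
        method: Literal["EXACT", "NORMAL_APPROX"] = "EXACT"
    else:
        p = _normal_approx_p(ranks, n1, u1)
        method = "NORMAL_APPROX"
    med_a, lo_a, hi_a = median_and_range(xa)
    med_b, lo_b, hi_b = median_and_range(ya)
    return ComparisonResult(
        measure=measure, group_a=group_a, group_b=group_b,
        n_a=n1, n_b=n2,
        median_a=med_a, median_b=med_b,
        range_a=(lo_a, hi_a), range_b=(lo_b, hi_b),
        U=float(min(u1, u2)), p=p, method=method, note=note,
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (midranks; p via the t approximation)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("length mismatch")
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    rho, p = stats.spearmanr(xa, ya)
    return CorrelationResult(n=len(xa), rho=float(rho), p=float(p))


# ---------------------------------------------------------------------------
# cohort report

#: measures compared only on animals passing the first-session bias screen
_PD_MEASURES = ("pd_sessions", "pd_trials",
                "pd_response_latency", "pd_reward_latency")
#: measures compared on the full cohort
_ALL_MEASURES = ("training_days", "pdr_sessions", "pdr_trials",
                 "pdr_response_latency", "pdr_reward_latency",
                 "persev_errors_binomial", "persev_errors_50",
                 "trials_to_50")
#: within-group sex contrasts reported for the young cohort
_SEX_MEASURES = ("pd_trials", "pdr_trials",
                 "persev_errors_binomial", "persev_errors_50")


def replicate_cohort_report(summaries, *, exact_bound: int = DEFAULT_EXACT_BOUND):
    """Full young-vs-aged comparison report from a cohort summary table.

    ``summaries`` is a DataFrame with one row per animal (the columns
    of :class:`~touchcog.scoring.AnimalSummary`).  PD acquisition and
    PD latencies are compared on the animals that showed no
    first-session stimulus bias; reversal and perseveration measures
    use the full cohort.  Sex contrasts within the young group are
    included; within the aged group they are computed but flagged
    underpowered (4 vs. 6 animals).  No multiple-testing correction is
    applied; every comparison is reported at face value.

    Returns a JSON-serialisable dict with ``comparisons`` (list of
    :class:`ComparisonResult` dicts), ``correlation`` (PD vs. PDR
    trials-to-criterion over the unbiased animals) and ``exclusions``.
    """
    import pandas as pd  # local: keep module import light

    df = pd.DataFrame(summaries) if not isinstance(summaries, pd.DataFrame) \
        else summaries
    young = df[df.age_group == "YOUNG"]
    aged = df[df.age_group == "AGED"]
    unbiased = df[~df.bias_flag.astype(bool)]
    y_unb = unbiased[unbiased.age_group == "YOUNG"]
    a_unb = unbiased[unbiased.age_group == "AGED"]

    def cmp(measure, ga, gb, la, lb, note=None):
        xa = ga[measure].dropna().to_numpy(dtype=float)
        xb = gb[measure].dropna().to_numpy(dtype=float)
        if xa.size == 0 or xb.size == 0:
            return None
        return asdict(mann_whitney_u(
            xa, xb, measure=measure, group_a=la, group_b=lb,
            exact_bound=exact_bound, note=note))

    comparisons = []
    for m in _PD_MEASURES:
        r = cmp(m, y_unb, a_unb, "young", "aged",
                note="bias-screened animals only")
        if r:
            comparisons.append(r)
    for m in _ALL_MEASURES:
        r = cmp(m, young, aged, "young", "aged")
        if r:
            comparisons.append(r)
    for m in _SEX_MEASURES:
        src = y_unb if m in _PD_MEASURES else young
        r = cmp(m, src[src.sex == "m"], src[src.sex == "f"],
                "young males", "young females")
        if r:
            comparisons.append(r)
        src = a_unb if m in _PD_MEASURES else aged
        r = cmp(m, src[src.sex == "m"], src[src.sex == "f"],
                "aged males", "aged females",
                note="underpowered: small aged sex subgroups")
        if r:
            comparisons.append(r)

    corr_df = unbiased.dropna(subset=["pd_trials", "pdr_trials"])
    correlation = None
    if len(corr_df) >= 3:
        correlation = asdict(spearman_rho(
            corr_df.pd_trials.to_numpy(dtype=float),
            corr_df.pdr_trials.to_numpy(dtype=float)))
    return {
        "comparisons": comparisons,
        "correlation": correlation,
        "exclusions": {
            "bias_flagged_subjects": sorted(
                df.loc[df.bias_flag.astype(bool), "subject_id"]),
            "rule": "first-session stimulus bias excludes an animal from "
                    "PD comparisons only",
        },
        "multiple_testing": "none applied; comparisons reported at face value",
    }


def format_report(report: dict) -> str:
    """Aligned plain-text rendering of :func:`replicate_cohort_report`."""
    lines = []
    hdr = (f"{'measure':<24} {'groups':<28} {'n':>7} "
           f"{'medians':>17} {'U':>7} {'p':>9}  method")
    lines.append(hdr)
    lines.append("-" * len(hdr))
    for c in report["comparisons"]:
        lines.append(
            f"{c['measure']:<24} {c['group_a'] + ' vs ' + c['group_b']:<28} "
            f"{c['n_a']:>3}/{c['n_b']:<3} "
            f"{c['median_a']:>8.6g}/{c['median_b']:<8.6g} "
            f"{c['U']:>7.6g} {c['p']:>9.4g}  {c['method']}"
            + (f"  [{c['note']}]" if c.get("note") else "")
        )
    if report.get("correlation"):
        r = report["correlation"]
        lines.append("")
        lines.append(
            f"Spearman rho (PD vs PDR trials-to-criterion, n={r['n']}): "
            f"rho={r['rho']:.4f}, p={r['p']:.3g}"
        )
    if report.get("exclusions", {}).get("bias_flagged_subjects"):
        lines.append("bias-excluded from PD comparisons: "
                     + ", ".join(report["exclusions"]["bias_flagged_subjects"]))
    return "\n".join(lines)
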