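"""Burden dichotomization, Kaplan–Meier / log-rank survival and rank tests.

The survival core (product-limit estimator with Greenwood variance,
complementary log-log confidence intervals, k-group log-rank statistic) is
implemented here directly so the cutoff scan can run it thousands of times
cheaply; rank-sum comparisons and false-discovery-rate adjustment delegate to
scipy / statsmodels.

Dichotomization rule: the threshold is the empirical q-quantile (the smallest
observed value with at least q·n of the values at or below it) and a sample
is "high" only when its value strictly exceeds the threshold — ties go to the
low group, so on continuous data the high group is always the strict
minority.

The cutoff scan dichotomizes burden on the full analyzed cohort at each grid
quantile, runs a two-arm log-rank test within every subgroup, and selects the
quantile whose split separates survival (p < alpha) in the most subgroups;
ties break by the smallest all-patients p, then the smaller quantile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SUBTYPES = ("HR+HER2-", "HR+HER2+", "HR-HER2+", "TNBC")
INTRINSIC_SUBTYPES = ("LumA", "LumB", "HER2E", "Basal", "Normal")
DEFAULT_GRID = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1))
FIVE_YEARS_MONTHS = 60.0


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's clinical row: subtype labels, event-free survival time
    (months) and event indicator, plus optional numeric covariates."""

    sample_id: str
    subtype: str
    efs_months: float
    efs_event: bool
    intrinsic: str | None = None
    covariates: Mapping[str, float] = field(default_factory=dict)
    pcr: bool | None = None

    def __post_init__(self) -> None:
        if self.efs_months < 0:
            raise ValueError("efs_months must be non-negative")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")


def clinical_to_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": r.sample_id, "subtype": r.subtype, "intrinsic": r.intrinsic,
        "efs_months": r.efs_months, "efs_event": r.efs_event,
        **dict(r.covariates),
    } for r in records])


def read_clinical_table(path) -> pd.DataFrame:
    """Read a clinical CSV with at least sample_id, subtype, efs_months,
    efs_event (0/1 or true/false) columns; extra columns pass through."""
    df = pd.read_csv(path)
    required = {"sample_id", "subtype", "efs_months", "efs_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["efs_event"] = df["efs_event"].map(
        lambda v: str(v).strip().lower() in ("1", "true", "yes"))
    return df


# ---------------------------------------------------------------------------
# Dichotomization
# ---------------------------------------------------------------------------

def quantile_threshold(values: Sequence[float], q: float) -> float:
    """Empirical q-quantile: smallest observed v with >= q*n values <= v."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    ordered = np.sort(np.asarray(list(values), dtype=float))
    k = math.ceil(q * len(ordered))
    return float(ordered[max(k, 1) - 1])


def dichotomize_quantile(values: Mapping[str, float], q: float
                         ) -> tuple[dict[str, str], float]:
    """Split samples into high/low at the empirical q-quantile.

    High means strictly above the threshold; ties go low.  Returns the
    group map and the threshold.  If all values are identical everything is
    low and a warning is issued.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    threshold = quantile_threshold(list(values.values()), q)
    groups = {s: ("high" if v > threshold else "low") for s, v in values.items()}
    if all(g == "low" for g in groups.values()) and len(set(values.values())) == 1:
        warnings.warn("all values identical: every sample assigned to the low group")
    return groups, threshold


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Product-limit step function over distinct event times.

    ``greenwood_var`` is the Greenwood variance of S(t) at each event time.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n_total: int


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan–Meier estimator with Greenwood variance.

    Subjects censored at an event time remain at risk for that time's factor
    (the standard convention).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0 or t.size != e.size:
        raise ValueError("times and events must be equal-length and non-empty")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    uniq = np.unique(t[e])
    n_at_risk = np.array([(t >= u).sum() for u in uniq], dtype=float)
    d = np.array([((t == u) & e).sum() for u in uniq], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / n_at_risk)
        inc = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), 0.0)
        gvar = surv ** 2 * np.cumsum(inc)
    gvar = np.where(surv > 0, gvar, 0.0)
    return SurvivalCurve(event_times=uniq, at_risk=n_at_risk.astype(int),
                         events=d.astype(int), survival=surv,
                         greenwood_var=gvar, n_total=int(t.size))


def survival_at(curve: SurvivalCurve, t_months: float, conf: float = 0.95) -> dict:
    """Survival rate at time t with a complementary log-log CI.

    The rate is S at the last event time <= t.  Before the first event the
    rate is 1 with a degenerate CI; a zero-variance estimate likewise
    collapses to a point interval.
    """
    idx = np.searchsorted(curve.event_times, t_months, side="right") - 1
    if idx < 0:
        return {"rate": 1.0, "ci_low": 1.0, "ci_high": 1.0}
    s = float(curve.survival[idx])
    var = float(curve.greenwood_var[idx])
    if s <= 0.0 or s >= 1.0 or var <= 0.0:
        return {"rate": s, "ci_low": s, "ci_high": s}
    z = stats.norm.ppf(0.5 + conf / 2.0)
    se_cloglog = math.sqrt(var) / (s * abs(math.log(s)))
    lo = s ** math.exp(z * se_cloglog)
    hi = s ** math.exp(-z * se_cloglog)
    return {"rate": s, "ci_low": max(0.0, lo), "ci_high": min(1.0, hi)}


def curve_to_frame(curve: SurvivalCurve) -> pd.DataFrame:
    return pd.DataFrame({
        "time": curve.event_times, "at_risk": curve.at_risk,
        "events": curve.events, "survival": curve.survival,
        "greenwood_var": curve.greenwood_var,
    })


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p: float


def logrank(groups: Sequence[tuple[Sequence[float], Sequence[bool]]]) -> LogRankResult:
    """k-group log-rank test (chi-square, df = k-1, no continuity correction).

    At each distinct pooled event time the observed-minus-expected event
    counts accumulate with the hypergeometric covariance; with no events at
    all the statistic is 0 and p = 1.
    """
    k = len(groups)
    if k < 2 or any(len(t) == 0 for t, _ in groups):
        raise ValueError("need >= 2 non-empty groups")
    t = [np.asarray(ti, dtype=float) for ti, _ in groups]
    e = [np.asarray(ei, dtype=bool) for _, ei in groups]
    pooled_t = np.concatenate(t)
    pooled_e = np.concatenate(e)
    uniq = np.unique(pooled_t[pooled_e])
    if uniq.size == 0:
        return LogRankResult(statistic=0.0, df=k - 1, p=1.0)

    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for u in uniq:
        n_j = np.array([(tj >= u).sum() for tj in t], dtype=float)
        d_j = np.array([((tj == u) & ej).sum() for tj, ej in zip(t, e)], dtype=float)
        n = n_j.sum()
        d = d_j.sum()
        observed += d_j
        expected += d * n_j / n
        if n > 1:
            frac = n_j / n
            cov += d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))

    diff = (observed - expected)[:-1]
    v = cov[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(v, diff, rcond=None)
        stat = float(diff @ sol)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=k - 1))
    return LogRankResult(statistic=stat, df=k - 1, p=p)


def logrank_two(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Convenience wrapper for the common two-arm comparison."""
    return logrank([(times_a, events_a), (times_b, events_b)])


# ---------------------------------------------------------------------------
# Cutoff scan
# ---------------------------------------------------------------------------

@dataclass
class CutoffScanResult:
    table: pd.DataFrame            # quantile, subgroup, n_high, n_low, statistic, p, testable
    thresholds: dict[float, float]
    coverage: dict[float, int]
    selected_quantile: float
    alpha: float


def default_subgroups(clinical: pd.DataFrame, min_size: int = 15) -> dict[str, list[str]]:
    """All patients, IHC subtypes and intrinsic subtypes with >= min_size samples."""
    subgroups: dict[str, list[str]] = {"all": clinical["sample_id"].tolist()}
    for s in SUBTYPES:
        members = clinical.loc[clinical["subtype"] == s, "sample_id"].tolist()
        if len(members) >= min_size:
            subgroups[f"subtype:{s}"] = members
    if "intrinsic" in clinical.columns:
        for s in INTRINSIC_SUBTYPES:
            members = clinical.loc[clinical["intrinsic"] == s, "sample_id"].tolist()
            if len(members) >= min_size:
                subgroups[f"intrinsic:{s}"] = members
    return subgroups


def scan_cutoffs(burden: Mapping[str, float], clinical: pd.DataFrame,
                 subgroups: Mapping[str, Sequence[str]] | None = None,
                 grid: Sequence[float] = DEFAULT_GRID,
                 alpha: float = 0.05) -> CutoffScanResult:
    """Quantile scan: dichotomize burden on the full cohort at each grid
    quantile, log-rank within each subgroup, select the quantile covering the
    most subgroups at p < alpha.

    Cells where a subgroup has an empty high or low arm are untestable and
    excluded from coverage.
    """
    clin = clinical[clinical["sample_id"].isin(burden)].reset_index(drop=True)
    if len(clin) < 2:
        raise ValueError("fewer than 2 samples with both burden and clinical data")
    if subgroups is None:
        subgroups = default_subgroups(clin)
    cohort_burden = {s: burden[s] for s in clin["sample_id"]}
    time_of = dict(zip(clin["sample_id"], clin["efs_months"].astype(float)))
    event_of = dict(zip(clin["sample_id"], clin["efs_event"].astype(bool)))

    rows = []
    thresholds: dict[float, float] = {}
    coverage: dict[float, int] = {}
    for q in grid:
        groups, thr = dichotomize_quantile(cohort_burden, q)
        thresholds[q] = thr
        cov = 0
        for name, members in subgroups.items():
            hi = [s for s in members if groups.get(s) == "high"]
            lo = [s for s in members if groups.get(s) == "low"]
            if not hi or not lo:
                rows.append({"quantile": q, "subgroup": name, "n_high": len(hi),
                             "n_low": len(lo), "statistic": np.nan, "p": np.nan,
                             "testable": False})
                continue
            res = logrank_two([time_of[s] for s in hi], [event_of[s] for s in hi],
                              [time_of[s] for s in lo], [event_of[s] for s in lo])
            if res.p < alpha:
                cov += 1
            rows.append({"quantile": q, "subgroup": name, "n_high": len(hi),
                         "n_low": len(lo), "statistic": res.statistic,
                         "p": res.p, "testable": True})
        coverage[q] = cov

    table = pd.DataFrame(rows)

    def p_all(q: float) -> float:
        sel = table[(table["quantile"] == q) & (table["subgroup"] == "all")]
        if sel.empty or not bool(sel["testable"].iloc[0]):
            return math.inf
        return float(sel["p"].iloc[0])

    selected = min(grid, key=lambda q: (-coverage[q], p_all(q), q))
    return CutoffScanResult(table=table, thresholds=thresholds, coverage=coverage,
                            selected_quantile=float(selected), alpha=alpha)


# ---------------------------------------------------------------------------
# Rank tests and FDR
# ---------------------------------------------------------------------------

def compare_groups(values: Mapping[str, float], labels: Mapping[str, str],
                   test: str = "wilcoxon") -> tuple[float, float]:
    """Rank-based group comparison of a numeric covariate.

    ``wilcoxon`` is the two-sample Wilcoxon rank-sum (Mann–Whitney; exact p
    for small tie-free samples, normal approximation with average ranks
    otherwise), ``kruskal`` the Kruskal–Wallis chi-square test for >= 2
    groups.  Returns (statistic, p).
    """
    by_group: dict[str, list[float]] = {}
    for s, v in values.items():
        if s in labels:
            by_group.setdefault(labels[s], []).append(v)
    if any(len(v) == 0 for v in by_group.values()):
        raise ValueError("empty group")
    samples = [by_group[g] for g in sorted(by_group)]
    if test == "wilcoxon":
        if len(samples) != 2:
            raise ValueError("wilcoxon requires exactly 2 groups")
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
    elif test == "kruskal":
        if len(samples) < 2:
            raise ValueError("kruskal requires >= 2 groups")
        res = stats.kruskal(*samples)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, <= 1, >= raw)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
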