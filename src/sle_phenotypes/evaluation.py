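"""Performance estimation of a cohort against ground truth.

Case status is matched at the person level with no tolerance on dates: a
cohort member is a true positive iff the ground truth marks them a case.
Timing accuracy is reported separately by :func:`index_date_error`.  True
cases whose onset falls after their observation ends (or who have no
observation at all) are excluded from the evaluation denominator — no
database, real or synthetic, can detect them.

Confidence intervals are Wilson score intervals, which stay well-behaved at
the near-1.0 specificities typical of rare-disease phenotypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

METRICS = ("sensitivity", "specificity", "ppv", "npv", "f1")


@dataclass
class PerformanceEstimate:
    """Confusion counts plus sensitivity/specificity/PPV/NPV/F1 with 95% CIs.

    Metrics with a zero denominator are ``None`` (absent), never 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    f1: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    algorithm_id: str | None = None
    database: str | None = None

    def metric(self, name: str) -> float | None:
        return getattr(self, name)


def confusion_counts(cohort: pd.DataFrame, ground_truth: pd.DataFrame,
                     observation_periods: pd.DataFrame) -> tuple[int, int, int, int]:
    """Person-level (tp, fp, tn, fn) for a cohort against ground truth.

    The denominator is every non-case plus every case whose onset is not
    after their observation end; ``tp + fp + tn + fn`` always equals its
    size.  A cohort member missing from the ground truth is fatal.
    """
    members = set(cohort["person_id"])
    known = set(ground_truth["person_id"])
    missing = members - known
    if missing:
        raise ValueError(
            f"cohort persons missing from ground truth: {sorted(missing)[:10]}")

    obs_end = (observation_periods.groupby("person_id")
               ["observation_period_end_date"].max())
    gt = ground_truth.merge(obs_end.rename("obs_end"), on="person_id", how="left")
    undetectable = gt["has_sle"] & (
        gt["obs_end"].isna() | (gt["onset_date"] > gt["obs_end"]))
    gt = gt[~undetectable]

    in_cohort = gt["person_id"].isin(members)
    tp = int((gt["has_sle"] & in_cohort).sum())
    fp = int((~gt["has_sle"] & in_cohort).sum())
    fn = int((gt["has_sle"] & ~in_cohort).sum())
    tn = int((~gt["has_sle"] & ~in_cohort).sum())
    return tp, fp, tn, fn


def f1_score(sensitivity: float | None, ppv: float | None) -> float | None:
    """Harmonic mean of sensitivity and PPV; None when undefined."""
    if sensitivity is None or ppv is None or (sensitivity + ppv) == 0:
        return None
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def _binomial(num: int, den: int) -> tuple[float | None, tuple[float, float] | None]:
    if den == 0:
        return None, None
    lo, hi = proportion_confint(num, den, alpha=0.05, method="wilson")
    return num / den, (float(lo), float(hi))


def performance(counts, algorithm_id: str | None = None,
                database: str | None = None) -> PerformanceEstimate:
    """Full metric set with Wilson 95% CIs from (tp, fp, tn, fn)."""
    tp, fp, tn, fn = (int(c) for c in counts)
    est = PerformanceEstimate(tp=tp, fp=fp, tn=tn, fn=fn,
                              algorithm_id=algorithm_id, database=database)
    for name, num, den in [
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, tn + fp),
        ("ppv", tp, tp + fp),
        ("npv", tn, tn + fn),
    ]:
        value, ci = _binomial(num, den)
        setattr(est, name, value)
        if ci is not None:
            est.ci[name] = ci
    est.f1 = f1_score(est.sensitivity, est.ppv)
    return est


def cross_database_mean(estimates, metric: str) -> float | None:
    """Unweighted arithmetic mean of a metric's point estimates.

    Estimates where the metric is absent are skipped with a warning.
    Accepts :class:`PerformanceEstimate` objects or mappings.
    """
    values = []
    for est in estimates:
        v = est.get(metric) if isinstance(est, dict) else est.metric(metric)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            logger.warning("metric %r absent in one estimate; skipped", metric)
            continue
        values.append(float(v))
    if not values:
        return None
    return sum(values) / len(values)


def to_percent(proportion: float) -> int:
    """Report a proportion as the nearest whole percent (half rounds up)."""
    return int(math.floor(100.0 * proportion + 0.5))


@dataclass
class IndexDateErrorSummary:
    """Signed index-date error (index − onset, days) over true-positive entries."""

    n: int
    mean_days: float | None
    median_days: float | None
    fraction_exact: float | None


def index_date_error(cohort: pd.DataFrame,
                     ground_truth: pd.DataFrame) -> IndexDateErrorSummary:
    """Summarise how far cohort entry dates sit from true onset.

    Only entries for true cases are considered; error is signed
    (positive = entry later than onset).
    """
    cases = ground_truth[ground_truth["has_sle"]]
    joined = cohort.merge(cases[["person_id", "onset_date"]], on="person_id")
    if joined.empty:
        return IndexDateErrorSummary(0, None, None, None)
    err = (joined["index_date"] - joined["onset_date"]).dt.days
    return IndexDateErrorSummary(
        n=int(len(err)),
        mean_days=float(err.mean()),
        median_days=float(err.median()),
        fraction_exact=float((err == 0).mean()),
    )


def published_performance() -> pd.DataFrame:
    """Published multi-database validation estimates for the six algorithms.

    One row per algorithm × database with columns ``algorithm_id, database,
    sensitivity, ppv, specificity, npv`` as reported by the source
    validation study across seven observational databases.
    """
    ref = resources.files("sle_phenotypes.data") / "published_performance.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, dtype={"algorithm_id": str, "database": str})


def published_estimates(algorithm_id: str) -> list[PerformanceEstimate]:
    """Published point estimates for one algorithm as estimate objects.

    Confusion counts are unavailable for published results and are set to
    -1; only the point metrics (and derived F1) are meaningful.
    """
    frame = published_performance()
    frame = frame[frame["algorithm_id"] == algorithm_id]
    if frame.empty:
        raise ValueError(f"no published estimates for {algorithm_id!r}")
    out = []
    for row in frame.itertuples():
        est = PerformanceEstimate(
            tp=-1, fp=-1, tn=-1, fn=-1,
            sensitivity=row.sensitivity, specificity=row.specificity,
            ppv=row.ppv, npv=row.npv,
            algorithm_id=row.algorithm_id, database=row.database)
        est.f1 = f1_score(est.sensitivity, est.ppv)
        out.append(est)
    return out
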