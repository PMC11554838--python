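"""Quantile-union expression stratification and survival comparison.

A cohort is split into *High* and *Low* expression groups by a
percentile-union rule: per gene, the threshold is the q-quantile
(default 0.75, linear interpolation between order statistics) of that
gene's values across samples, and a sample is High when it strictly
exceeds the threshold for at least one gene in the panel. The two
groups are then compared with the Kaplan-Meier product-limit estimator
and the log-rank test; the hazard ratio is the observed/expected ratio
``(O1/E1)/(O0/E0)`` from the log-rank table (the Pike estimator).

Times are in months; ``event=False`` records are right-censored. At
tied times, events are counted before censorings leave the risk set
(the standard convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnalyteMatrix, InvariantError

logger = logging.getLogger("chemoresist")

HIGH = "High"
LOW = "Low"


@dataclass
class StratificationRule:
    """Percentile-union High/Low rule.

    ``combine="any"`` labels a sample High when it exceeds the
    per-gene q-quantile for at least one panel gene (the union rule);
    ``"all"`` requires every gene. The comparator is strictly ``>``.
    """

    genes: list[str]
    q: float = 0.75
    combine: str = "any"

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if not self.genes:
            raise InvariantError("stratification rule needs a non-empty gene panel")
        if not 0 < self.q < 1:
            raise InvariantError(f"q must be in (0,1), got {self.q}")
        if self.combine not in ("any", "all"):
            raise InvariantError(f"combine must be 'any' or 'all', got {self.combine!r}")


@dataclass
class SurvivalCohort:
    """Time-to-event records, optionally with a High/Low group label.

    ``records`` has columns ``sample_id`` (unique), ``time`` (months,
    >= 0) and ``event`` (True = event observed, False = censored).
    """

    records: pd.DataFrame
    group: pd.Series | None = None

    def __post_init__(self) -> None:
        need = {"sample_id", "time", "event"}
        missing = need - set(self.records.columns)
        if missing:
            raise InvariantError(f"survival records missing column(s): {sorted(missing)}")
        ids = self.records["sample_id"]
        if ids.duplicated().any():
            dups = sorted(set(ids[ids.duplicated()]))
            raise InvariantError(f"duplicate sample id(s) in cohort: {dups}")
        if (self.records["time"] < 0).any():
            raise InvariantError("survival times must be >= 0")
        if self.group is not None:
            unknown = set(self.group.index) - set(ids)
            if unknown:
                raise InvariantError(f"group labels for unknown sample(s): {sorted(unknown)}")

    def with_group(self, group: pd.Series) -> "SurvivalCohort":
        return SurvivalCohort(self.records.copy(), group=group)

    @property
    def n(self) -> int:
        return len(self.records)


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve at the observed event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (1 before the first event)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]
    hazard_ratio: float
    groups: tuple[str, str] = field(default=("", ""))


def stratify(m: AnalyteMatrix, rule: StratificationRule) -> pd.Series:
    """Label each sample High/Low by the percentile-union rule.

    Per gene, the threshold is the linear-interpolation q-quantile of
    that gene's values across all samples; a sample is High iff its
    value strictly exceeds the threshold for >= 1 gene (combine="any")
    or for every gene (combine="all").
    """
    absent = [g for g in rule.genes if g not in m.values.index]
    if absent:
        raise InvariantError(f"stratification gene(s) absent from matrix: {absent}")
    n = len(m.values.columns)
    if n < 4:
        raise InvariantError(f"need >= 4 samples to stratify, got {n}")
    exceed = pd.DataFrame(index=rule.genes, columns=m.values.columns, dtype=bool)
    for g in rule.genes:
        x = m.values.loc[g]
        if x.isna().any():
            raise InvariantError(f"gene {g!r} has missing values; stratification needs complete rows")
        thr = float(np.quantile(x.to_numpy(dtype=float), rule.q))
        exceed.loc[g] = x > thr
    high = exceed.any(axis=0) if rule.combine == "any" else exceed.all(axis=0)
    labels = pd.Series(np.where(high, HIGH, LOW), index=m.values.columns, name="group")
    logger.info("stratify: %d/%d samples High (q=%g, combine=%s, genes=%s)",
                int(high.sum()), n, rule.q, rule.combine, rule.genes)
    return labels


def _km_one(times: np.ndarray, events: np.ndarray) -> KMCurve:
    order = np.argsort(times, kind="stable")
    times = times[order]
    events = events[order]
    event_times = np.unique(times[events])
    surv = []
    at_risk = []
    s = 1.0
    for t in event_times:
        n_i = int(np.sum(times >= t))  # censored at t are still at risk for events at t
        d_i = int(np.sum((times == t) & events))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
    return KMCurve(event_times.astype(float), np.asarray(surv, dtype=float),
                   np.asarray(at_risk, dtype=int), n=len(times))


def km_fit(cohort: SurvivalCohort) -> dict[str, KMCurve]:
    """Product-limit curve per group (single key ``"all"`` when ungrouped)."""
    rec = cohort.records
    if cohort.group is None:
        groups = {"all": rec}
    else:
        labels = cohort.group.reindex(rec["sample_id"]).to_numpy()
        groups = {g: rec[labels == g] for g in pd.unique(labels)}
    curves = {}
    for g, sub in groups.items():
        if len(sub) == 0:
            raise InvariantError(f"group {g!r} is empty")
        curves[str(g)] = _km_one(sub["time"].to_numpy(dtype=float),
                                 sub["event"].to_numpy(dtype=bool))
    return curves


def km_median(curve: KMCurve) -> float | None:
    """Smallest event time with S(t) <= 0.5; None when S never reaches 0.5."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if len(below) == 0:
        return None
    return float(curve.event_times[below[0]])


def logrank_test(cohort: SurvivalCohort,
                 group_order: tuple[str, str] | None = None) -> LogRankResult:
    """Two-group log-rank test with O/E hazard ratio.

    Tied event times are handled with the hypergeometric variance.
    ``hazard_ratio`` is group1-vs-group0 in ``group_order`` (sorted
    label order by default); swapping the order inverts it.
    """
    if cohort.group is None:
        raise InvariantError("log-rank needs a grouped cohort")
    rec = cohort.records
    labels = cohort.group.reindex(rec["sample_id"]).astype(str).to_numpy()
    names = sorted(pd.unique(labels)) if group_order is None else [str(g) for g in group_order]
    if len(names) != 2 or set(names) != set(pd.unique(labels)):
        raise InvariantError(f"need exactly two groups matching the labels, got {names} "
                             f"vs {sorted(pd.unique(labels))}")
    g0, g1 = names
    times = rec["time"].to_numpy(dtype=float)
    events = rec["event"].to_numpy(dtype=bool)
    if not events.any():
        raise InvariantError("log-rank undefined with zero events")
    in1 = labels == g1

    ut = np.unique(times[events])
    sorted_all = np.sort(times)
    sorted_1 = np.sort(times[in1])
    n_at = len(times) - np.searchsorted(sorted_all, ut, side="left")
    n1_at = len(sorted_1) - np.searchsorted(sorted_1, ut, side="left")
    # events per distinct event time, overall and in group 1
    d_at = np.array([np.sum((times == t) & events) for t in ut], dtype=float)
    d1_at = np.array([np.sum((times == t) & events & in1) for t in ut], dtype=float)

    frac1 = n1_at / n_at
    e1_at = d_at * frac1
    with np.errstate(invalid="ignore", divide="ignore"):
        v_at = np.where(n_at > 1,
                        d_at * frac1 * (1.0 - frac1) * (n_at - d_at) / (n_at - 1.0),
                        0.0)
    o1 = float(d1_at.sum())
    e1 = float(e1_at.sum())
    o_total = float(d_at.sum())
    o0 = o_total - o1
    e0 = o_total - e1
    v = float(v_at.sum())
    if v <= 0:
        chi2 = 0.0
        p = 1.0
    else:
        chi2 = (o1 - e1) ** 2 / v
        p = float(stats.chi2.sf(chi2, df=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        hr = (o1 / e1) / (o0 / e0) if e1 > 0 and e0 > 0 and o0 > 0 else np.inf
    return LogRankResult(float(chi2), 1, p,
                         observed={g0: o0, g1: o1},
                         expected={g0: e0, g1: e1},
                         hazard_ratio=float(hr), groups=(g0, g1))
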