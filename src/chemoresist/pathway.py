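"""Pathway-activity scoring and paired pre/post-treatment analysis.

The pathway activity score (PAS) of a sample is the sum of the
normalized (log2) levels of a pathway's positive regulators minus the
sum of its negative regulators — a plain signed sum, no averaging. On
paired pre/post-treatment cohorts the per-patient change
``delta = PAS(post) - PAS(pre)`` classifies patients as Up
(``delta > 0``) or Down, and deltas of two pathways can be correlated
across patients (Pearson).

Two-group comparisons follow a normality-gated scheme: Shapiro-Wilk per
group at level alpha; a two-sided Welch t-test when both groups pass,
otherwise a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import LOG2, AnalyteMatrix, InvariantError, SignedGeneSet

logger = logging.getLogger("chemoresist")

WELCH_T = "welch_t"
MANN_WHITNEY = "mann_whitney"

UP = "Up"
DOWN = "Down"


@dataclass
class PASResult:
    """Per-sample pathway activity scores.

    ``members_used`` records the declared regulators actually found in
    the matrix, by sign; scores are in (summed) log2 units.
    """

    pathway: str
    scores: pd.Series
    members_used: dict[str, list[str]]


@dataclass
class DeltaResult:
    """Per-patient post-minus-pre PAS change with Up/Down calls.

    ``direction`` is Up iff ``delta > 0`` (ties classified Down, so Up
    strictly means an increase). Samples present in a matrix but not in
    the pairing are listed in ``excluded_pre`` / ``excluded_post``.
    """

    pathway: str
    delta: pd.Series
    direction: pd.Series
    excluded_pre: list[str]
    excluded_post: list[str]


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    test_used: str
    normality_p: dict[str, float]
    groups: tuple[str, str]


def compute_pas(m: AnalyteMatrix, gene_set: SignedGeneSet,
                missing_policy: str = "error") -> PASResult:
    """Signed-sum pathway activity score per sample.

    ``score(s) = sum(values of positive members present) -
    sum(values of negative members present)``. Requires a normalized
    log2-scale matrix and at least one set member present among its
    rows. ``missing_policy``: ``"error"`` rejects missing member
    readings; ``"skip"`` omits them from the per-sample sum.
    """
    if m.scale != LOG2:
        raise InvariantError("PAS requires a normalized log2-scale matrix")
    if missing_policy not in ("error", "skip"):
        raise InvariantError(f"missing_policy must be 'error' or 'skip', got {missing_policy!r}")
    rows = set(m.values.index)
    pos = [g for g in gene_set.positive if g in rows]
    neg = [g for g in gene_set.negative if g in rows]
    if not pos and not neg:
        raise InvariantError(
            f"no member of set {gene_set.name!r} present in the matrix "
            f"(declared: {gene_set.members})"
        )
    absent = [g for g in gene_set.members if g not in rows]
    if absent:
        logger.info("compute_pas[%s]: %d declared member(s) absent from matrix: %s",
                    gene_set.name, len(absent), absent)
    sub_pos = m.values.loc[pos]
    sub_neg = m.values.loc[neg]
    n_missing = int(sub_pos.isna().sum().sum() + sub_neg.isna().sum().sum())
    if n_missing and missing_policy == "error":
        both = pd.concat([sub_pos, sub_neg])
        rr, cc = np.argwhere(both.isna().to_numpy())[0]
        raise InvariantError(
            f"missing reading for member {both.index[rr]!r} in sample {both.columns[cc]!r} "
            f"(policy=error; use policy='skip' to omit)"
        )
    if n_missing:
        logger.info("compute_pas[%s]: skipped %d missing member reading(s)",
                    gene_set.name, n_missing)
    scores = sub_pos.sum(axis=0, skipna=True) - sub_neg.sum(axis=0, skipna=True)
    scores.name = gene_set.name
    return PASResult(gene_set.name, scores.astype(float),
                     {"positive": pos, "negative": neg})


def delta_pas(pre: AnalyteMatrix, post: AnalyteMatrix,
              pairing: Mapping[str, tuple[str, str]],
              gene_set: SignedGeneSet,
              missing_policy: str = "error") -> DeltaResult:
    """Per-patient PAS(post) - PAS(pre) over a patient→(pre, post) sample map."""
    missing_pairs = [
        p for p, (s_pre, s_post) in pairing.items()
        if s_pre not in pre.values.columns or s_post not in post.values.columns
    ]
    if missing_pairs:
        raise InvariantError(f"pairing references missing sample(s) for patient(s): {sorted(missing_pairs)}")
    pas_pre = compute_pas(pre, gene_set, missing_policy)
    pas_post = compute_pas(post, gene_set, missing_policy)
    if pas_pre.members_used != pas_post.members_used:
        raise InvariantError(
            f"pre/post matrices realise different member sets for {gene_set.name!r}: "
            f"{pas_pre.members_used} vs {pas_post.members_used}"
        )
    patients = list(pairing)
    delta = pd.Series(
        [pas_post.scores[pairing[p][1]] - pas_pre.scores[pairing[p][0]] for p in patients],
        index=patients, name=f"delta_{gene_set.name}", dtype=float,
    )
    direction = pd.Series(np.where(delta > 0, UP, DOWN), index=patients, name="direction")
    used_pre = {pairing[p][0] for p in patients}
    used_post = {pairing[p][1] for p in patients}
    excluded_pre = sorted(set(pre.values.columns) - used_pre)
    excluded_post = sorted(set(post.values.columns) - used_post)
    if excluded_pre or excluded_post:
        logger.info("delta_pas[%s]: unpaired samples excluded — pre: %s, post: %s",
                    gene_set.name, excluded_pre, excluded_post)
    return DeltaResult(gene_set.name, delta, direction, excluded_pre, excluded_post)


def correlate_deltas(a: DeltaResult, b: DeltaResult) -> tuple[float, float, int]:
    """Pearson correlation of two pathways' deltas over shared patients.

    Returns ``(r, two-sided p, n)``; p comes from the t-distribution
    with n-2 degrees of freedom. Requires at least three shared
    patients and non-degenerate variance in both vectors.
    """
    shared = [p for p in a.delta.index if p in set(b.delta.index)]
    n = len(shared)
    if n < 3:
        raise InvariantError(f"need >= 3 shared patients for correlation, got {n}")
    x = a.delta[shared].to_numpy(dtype=float)
    y = b.delta[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvariantError("correlation undefined: zero variance in at least one delta vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def compare_groups(values: pd.Series, labels: pd.Series, alpha: float = 0.05) -> GroupComparison:
    """Normality-gated two-group comparison.

    Shapiro-Wilk is run per group at level ``alpha``; if both groups
    pass, a two-sided Welch t-test (unequal variances) is used,
    otherwise a two-sided Mann-Whitney U test. Requires exactly two
    groups with at least three observations each.
    """
    shared = values.index.intersection(labels.index)
    values = values[shared].astype(float)
    labels = labels[shared].astype(str)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise InvariantError(f"need exactly two groups, got {groups}")
    samples = {g: values[labels == g].to_numpy() for g in groups}
    for g, x in samples.items():
        if len(x) < 3:
            raise InvariantError(f"group {g!r} has n={len(x)} < 3")
    normality_p = {g: float(stats.shapiro(x).pvalue) for g, x in samples.items()}
    g0, g1 = groups
    if all(p >= alpha for p in normality_p.values()):
        res = stats.ttest_ind(samples[g0], samples[g1], equal_var=False)
        test_used = WELCH_T
    else:
        res = stats.mannwhitneyu(samples[g0], samples[g1], alternative="two-sided")
        test_used = MANN_WHITNEY
    return GroupComparison(float(res.statistic), float(res.pvalue), test_used,
                           normality_p, (g0, g1))
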