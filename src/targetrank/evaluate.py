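"""Validation statistics for ranked gene lists.

Implements the evaluation toolkit used to judge a druggability ranking
against external evidence: ROC AUC, the paired DeLong test for comparing two
models' AUCs on the same cases, Fisher's exact 2x2 test with sample odds
ratio, rank-interval enrichment (the ranking cut into B near-equal intervals,
each tested for enrichment of an evidence gene set), the cumulative evidence
distribution over intervals, and a stepwise hypergeometric enrichment curve
with an enriched-region AUC summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import InputError

logger = logging.getLogger("targetrank")

TINY_P = 5e-324  # smallest subnormal double; floors p before log10


def auc_score(scores, labels) -> float:
    """Probability that a random positive outscores a random negative (ties 1/2).

    Computed from the Mann-Whitney U statistic on average ranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise InputError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values (midrank construction) for one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    v10 = (all_r[:m] - pos_r) / n          # per positive
    v01 = 1.0 - (all_r[m:] - neg_r) / m    # per negative
    auc = v10.mean()
    return auc, v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Paired DeLong test: (auc_a, auc_b, two-sided p for the AUC difference).

    Zero variance of the difference (e.g. identical score vectors) gives p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise InputError("paired scores and labels must have identical length")
    n1 = int(labels.sum())
    if n1 == 0 or n1 == len(labels):
        raise InputError("both classes must be present")
    auc_a, v10a, v01a = _placements(scores_a, labels)
    auc_b, v10b, v01b = _placements(scores_b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    if var <= 0:
        return float(auc_a), float(auc_b), 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test on [[a, b], [c, d]].

    Returns the sample odds ratio (Haldane +0.5 correction on all cells iff
    any cell is zero) and the two-sided exact p-value (sum of hypergeometric
    outcomes with probability <= the observed table's).
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise InputError("cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    if a + b == 0 or c + d == 0:
        raise InputError("a row of the 2x2 table is empty")
    if min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def interval_sizes(n: int, B: int) -> list[int]:
    """B near-equal interval sizes summing to n; the remainder genes go to
    the bottom intervals so the top interval holds exactly floor(n/B) genes."""
    base, rem = divmod(n, B)
    return [base] * (B - rem) + [base + 1] * rem


def rank_interval_enrichment(
    ranking: Sequence, evidence, B: int = 20
) -> pd.DataFrame:
    """Cut the ranking into B near-equal intervals and Fisher-test each one.

    Per interval: a 2x2 table of (in interval, has evidence) against the rest
    of the universe. Returns interval bounds in percent, gene and evidence
    counts, odds ratio and p-value.
    """
    ranking = list(ranking)
    n = len(ranking)
    if B > n:
        raise InputError(f"B = {B} exceeds universe size {n}")
    evidence = set(evidence)
    if not evidence <= set(ranking):
        raise InputError("evidence genes must belong to the ranking universe")
    sizes = interval_sizes(n, B)
    rows = []
    start = 0
    n_ev = len(evidence)
    for i, size in enumerate(sizes):
        interval = ranking[start : start + size]
        a = sum(g in evidence for g in interval)
        b = size - a
        c = n_ev - a
        d = n - size - c
        odds, p = fisher_2x2(a, b, c, d)
        rows.append(
            (
                i + 1,
                100.0 * start / n,
                100.0 * (start + size) / n,
                size,
                a,
                odds,
                p,
            )
        )
        start += size
    return pd.DataFrame(
        rows,
        columns=[
            "interval", "lo_pct", "hi_pct", "n_genes",
            "n_with_evidence", "odds_ratio", "p_value",
        ],
    )


def evidence_cdf(ranking: Sequence, evidence, B: int = 20) -> np.ndarray:
    """Cumulative fraction of evidence genes found at or above each interval."""
    evidence = set(evidence)
    if not evidence:
        raise InputError("evidence set is empty")
    table = rank_interval_enrichment(ranking, evidence, B)
    return (table["n_with_evidence"].cumsum() / len(evidence)).to_numpy()


@dataclass
class StepwiseCurve:
    cutoffs: np.ndarray      # gene counts k
    pvalues: np.ndarray      # upper-tail hypergeometric p at each k
    enriched_auc: float      # area of the -log10 p curve where p < alpha
    alpha: float = 0.05


def stepwise_hypergeom(
    ranking: Sequence, reference, step: int = 50, alpha: float = 0.05
) -> StepwiseCurve:
    """Hypergeometric enrichment of a reference set at successive cutoffs.

    At each cutoff k the p-value is the upper-tail probability of drawing at
    least the observed overlap in k draws from the universe. The
    enriched-region AUC sums -log10(p) * (step_width / N) over cutoffs with
    p < alpha (a rectangle-rule area of the enriched part of the curve); it
    is 0 when no cutoff is enriched.
    """
    if step < 1:
        raise InputError("step must be >= 1")
    ranking = list(ranking)
    n = len(ranking)
    reference = set(reference)
    if not reference <= set(ranking):
        raise InputError("reference genes must belong to the ranking universe")
    K = len(reference)
    cutoffs = list(range(step, n + 1, step))
    if not cutoffs or cutoffs[-1] != n:
        cutoffs.append(n)
    in_ref = np.fromiter((g in reference for g in ranking), dtype=int, count=n)
    cum = np.cumsum(in_ref)
    ks = np.array(cutoffs)
    overlaps = cum[ks - 1]
    pvals = stats.hypergeom.sf(overlaps - 1, n, K, ks)
    pvals = np.clip(pvals, TINY_P, 1.0)
    widths = np.diff(np.concatenate([[0], ks])) / n
    mask = pvals < alpha
    auc = float(np.sum(-np.log10(pvals[mask]) * widths[mask]))
    return StepwiseCurve(ks, pvals, auc, alpha)
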