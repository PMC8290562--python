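"""Rank-based comparison of gene-family sizes across taxonomic groups.

The omnibus test is the tie-corrected Kruskal-Wallis statistic

    H = [12 / (N(N+1)) * sum_i R_i^2 / n_i  -  3(N+1)] / C,
    C = 1 - sum_t (t^3 - t) / (N^3 - N)

with mid-ranks for ties and the chi-square upper tail on k-1 degrees of
freedom.  Post-hoc pairwise comparisons follow Conover's rank-means
procedure (the behaviour of the classic agricolae ``kruskal`` routine):
group i and j differ when

    |Rbar_i - Rbar_j| > t_{1-a'/2, N-k} * sqrt(S^2 (N-1-H)/(N-k) (1/n_i + 1/n_j))

where S^2 is the variance of all ranks and a' the per-comparison level
(Bonferroni: alpha / [k(k-1)/2] by default, the unadjusted level
optionally).  Results are summarised as a compact letter display: groups
sharing a letter are not significantly different.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import ABC_FAMILIES
from .pipeline import FamilySizeMatrix

logger = logging.getLogger("abcfam")

LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass
class KWResult:
    """Kruskal-Wallis omnibus result with post-hoc letter groups."""

    H: float
    df: int
    p_value: float
    mean_ranks: dict[str, float]
    letters: dict[str, str] | None = None


def _validate(data: Mapping[str, Sequence[float]]) -> None:
    if len(data) < 2:
        raise ValidationError("need at least 2 groups")
    if any(len(v) < 1 for v in data.values()):
        raise ValidationError("every group needs at least 1 value")
    if sum(len(v) for v in data.values()) < 3:
        raise ValidationError("need at least 3 values in total")


def _ranks(data: Mapping[str, Sequence[float]]):
    labels = list(data)
    values = np.concatenate([np.asarray(data[g], dtype=float) for g in labels])
    ranks = stats.rankdata(values)  # mid-ranks for ties
    group_ranks: dict[str, np.ndarray] = {}
    pos = 0
    for g in labels:
        n = len(data[g])
        group_ranks[g] = ranks[pos : pos + n]
        pos += n
    return labels, values, ranks, group_ranks


def kruskal_wallis(data: Mapping[str, Sequence[float]]) -> KWResult:
    """Tie-corrected Kruskal-Wallis test over the grouped values.

    When every value in the pooled sample is identical the tie correction
    is degenerate; H is defined as 0 with p = 1.
    """
    _validate(data)
    labels, values, ranks, group_ranks = _ranks(data)
    N = len(values)
    k = len(labels)
    raw = (12.0 / (N * (N + 1))) * sum(
        group_ranks[g].sum() ** 2 / len(group_ranks[g]) for g in labels
    ) - 3.0 * (N + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (N**3 - N)
    mean_ranks = {g: float(group_ranks[g].mean()) for g in labels}
    if correction <= 0:  # all values identical
        return KWResult(H=0.0, df=k - 1, p_value=1.0, mean_ranks=mean_ranks)
    H = raw / correction
    H = max(H, 0.0)
    p = float(stats.chi2.sf(H, k - 1))
    return KWResult(H=float(H), df=k - 1, p_value=p, mean_ranks=mean_ranks)


def _pairwise_significant(
    data: Mapping[str, Sequence[float]], alpha: float, adjust: str
) -> tuple[dict[str, float], set[frozenset[str]]]:
    labels, values, ranks, group_ranks = _ranks(data)
    N = len(values)
    k = len(labels)
    if N - k < 1:
        raise ValidationError("need N - k >= 1 residual degrees of freedom")
    H = kruskal_wallis(data).H
    S2 = (np.sum(ranks**2) - N * (N + 1) ** 2 / 4.0) / (N - 1)
    if S2 <= 0:  # all values identical: nothing can differ
        return {g: float(group_ranks[g].mean()) for g in labels}, set()
    factor = max(0.0, (N - 1.0 - H) / (N - k))
    m = k * (k - 1) // 2
    if adjust == "bonferroni":
        alpha_pc = alpha / m
    elif adjust == "none":
        alpha_pc = alpha
    else:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    tcrit = stats.t.ppf(1.0 - alpha_pc / 2.0, N - k)
    mean_ranks = {g: float(group_ranks[g].mean()) for g in labels}
    significant: set[frozenset[str]] = set()
    for i, gi in enumerate(labels):
        for gj in labels[i + 1 :]:
            ni, nj = len(group_ranks[gi]), len(group_ranks[gj])
            msd = tcrit * np.sqrt(S2 * factor * (1.0 / ni + 1.0 / nj))
            if abs(mean_ranks[gi] - mean_ranks[gj]) > msd:
                significant.add(frozenset((gi, gj)))
    return mean_ranks, significant


def _compact_letters(
    mean_ranks: Mapping[str, float], significant: set[frozenset[str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups are processed in descending mean-rank order; the group with the
    highest mean rank carries letter 'a' (the agricolae convention).
    """
    order = sorted(mean_ranks, key=lambda g: (-mean_ranks[g], g))
    sets: list[set[str]] = [set(order)]
    for pair in sorted(significant, key=lambda p: sorted(p)):
        gi, gj = sorted(pair, key=lambda g: order.index(g))
        new_sets: list[set[str]] = []
        for s in sets:
            if gi in s and gj in s:
                new_sets.append(s - {gi})
                new_sets.append(s - {gj})
            else:
                new_sets.append(s)
        # absorb duplicates and subsets
        new_sets.sort(key=len, reverse=True)
        kept: list[set[str]] = []
        for s in new_sets:
            if s and not any(s <= other for other in kept):
                kept.append(s)
        sets = kept
    # order letter sets by the best-ranked group they contain
    sets.sort(key=lambda s: min(order.index(g) for g in s))
    letters = {g: "" for g in order}
    for idx, s in enumerate(sets):
        for g in s:
            letters[g] += LETTERS[idx % len(LETTERS)]
    return {g: "".join(sorted(letters[g])) for g in order}


def posthoc_letters(
    data: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> dict[str, str]:
    """Conover pairwise comparisons summarised as letter groups.

    Groups sharing any letter are not significantly different at the
    (per-comparison, Bonferroni-adjusted by default) level ``alpha``.
    """
    _validate(data)
    mean_ranks, significant = _pairwise_significant(data, alpha, adjust)
    return _compact_letters(mean_ranks, significant)


def family_size_tests(
    matrix: FamilySizeMatrix,
    min_group_n: int = 3,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    adjust_across_families: bool = True,
) -> pd.DataFrame:
    """Kruskal-Wallis + letters for every family column (A..H and total).

    Species are grouped by taxonomic order; orders with fewer than
    ``min_group_n`` species are dropped with a warning.  The omnibus
    p-values are additionally Bonferroni-adjusted across the family-level
    tests.  Returns a tidy frame with one row per (family, group).
    """
    families = list(ABC_FAMILIES) + ["total"]
    if matrix.counts.empty:
        raise ValidationError("empty family size matrix")
    taxon = matrix.meta.loc[matrix.counts.index, "taxon_order"]
    results = []
    n_tests = len(families)
    for family in families:
        grouped: dict[str, list[float]] = {}
        for order, block in matrix.counts.groupby(taxon):
            if len(block) < min_group_n:
                logger.warning(
                    "%s: group %s dropped (%d < %d species)",
                    family, order, len(block), min_group_n,
                )
                continue
            grouped[str(order)] = block[family].tolist()
        if len(grouped) < 2:
            logger.warning("%s: fewer than 2 eligible groups; skipped", family)
            continue
        kw = kruskal_wallis(grouped)
        letters = posthoc_letters(grouped, alpha=alpha, adjust=adjust)
        p_adj = min(1.0, kw.p_value * n_tests) if adjust_across_families else kw.p_value
        for group in sorted(grouped):
            results.append(
                {
                    "family": family,
                    "H": kw.H,
                    "df": kw.df,
                    "p_value": kw.p_value,
                    "p_adjusted": p_adj,
                    "group": group,
                    "n": len(grouped[group]),
                    "mean_rank": kw.mean_ranks[group],
                    "letters": letters[group],
                }
            )
    return pd.DataFrame(results)
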