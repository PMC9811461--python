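"""Group-comparison statistics used by the pipeline.

Kruskal-Wallis with Dunn's pairwise post-hoc test compares drug-affinity
ratios between groups (the distributions are small and non-normal); an
ordinary one-way ANOVA with Tukey multiple comparisons compares colloid
composition ratios between morphologies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    p_adjusted: float


@dataclass
class KruskalDunnResult:
    h_statistic: float
    p_value: float
    pairwise: list[PairwiseResult]


def kruskal_dunn(
    groups: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> KruskalDunnResult:
    """Kruskal-Wallis H test plus Dunn's z-tests on mean ranks.

    Dunn's statistic for groups i, j with pooled (tie-corrected) ranks:

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    where T = sum over tied groups of (t^3 - t).  Two-sided p-values,
    adjusted by Bonferroni ('bonferroni'), Holm ('holm') or left raw
    ('none').
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(len(a) < 3 for a in arrays):
        raise ValueError("each group needs at least three observations")
    h, p = sps.kruskal(*arrays)

    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for name, a in zip(names, arrays):
        mean_ranks[name] = float(ranks[start : start + len(a)].mean())
        sizes[name] = len(a)
        start += len(a)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (12.0 * (n_total - 1))

    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se
        raw.append((a, b, float(z), float(2.0 * sps.norm.sf(abs(z)))))

    m = len(pairs)
    results = []
    if adjust == "bonferroni":
        adjusted = [min(1.0, pv * m) for *_, pv in raw]
    elif adjust == "holm":
        order = np.argsort([pv for *_, pv in raw])
        adjusted = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, raw[idx][3] * (m - rank))
            adjusted[idx] = min(1.0, running)
    elif adjust == "none":
        adjusted = [pv for *_, pv in raw]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    for (a, b, z, pv), pa in zip(raw, adjusted):
        results.append(PairwiseResult(a, b, z, pv, pa))
    return KruskalDunnResult(h_statistic=float(h), p_value=float(p), pairwise=results)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise: list[PairwiseResult]


def oneway_anova_tukey(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Ordinary one-way ANOVA with Tukey HSD multiple comparisons."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    f, p = sps.f_oneway(*arrays)
    tukey = sps.tukey_hsd(*arrays)
    pairwise = []
    for i, j in itertools.combinations(range(len(names)), 2):
        pairwise.append(
            PairwiseResult(
                names[i],
                names[j],
                float(tukey.statistic[i, j]),
                float(tukey.pvalue[i, j]),
                float(tukey.pvalue[i, j]),  # Tukey HSD is already family-wise
            )
        )
    return AnovaResult(f_statistic=float(f), p_value=float(p), pairwise=pairwise)
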