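"""Hypothesis tests and circular statistics used across the pipeline.

Linear two-sample and k-sample tests are thin wrappers around scipy;
Dunn's post-hoc test and the Watson-Williams F-test for circular means
are implemented here (no pre-installed package exposes them).
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np
from scipy import stats as sps


class InputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# linear tests


def mann_whitney(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    res = sps.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def wilcoxon(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    res = sps.wilcoxon(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def kruskal_dunn(*groups, p_adjust: str = "bonferroni"):
    """Kruskal-Wallis H-test plus Dunn's pairwise post-hoc z-tests.

    Returns ``(H, p, pairwise)`` where ``pairwise`` maps group index pairs
    to the (Bonferroni-adjusted by default) two-sided p-value of Dunn's
    rank-mean comparison with tie correction.
    """
    groups = [np.asarray(g, float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise InputError("empty group")
    H, p = sps.kruskal(*groups)
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term for the variance of rank means
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    pairwise = {}
    m = len(list(combinations(range(len(groups)), 2)))
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        pz = 2.0 * sps.norm.sf(abs(z))
        if p_adjust == "bonferroni":
            pz = min(1.0, pz * m)
        pairwise[(i, j)] = float(pz)
    return float(H), float(p), pairwise


# ---------------------------------------------------------------------------
# circular statistics


@dataclasses.dataclass
class CircularSummary:
    """Mean direction and resultant-vector strength of angular data."""

    mean_direction: float  # degrees in (-180, 180]
    r: float  # vector strength in [0, 1]
    n: int


def circular_summary(phases_deg) -> CircularSummary:
    """Mean vector of phase angles (degrees).

    The mean direction is the argument of the resultant of the unit
    vectors; ``r`` is the resultant length divided by n — 1 for perfectly
    clustered angles, 0 for a balanced spread.
    """
    ph = np.asarray(phases_deg, float)
    if ph.size == 0:
        raise InputError("need at least one phase value")
    rad = np.deg2rad(ph)
    C, S = np.cos(rad).sum(), np.sin(rad).sum()
    r = float(np.hypot(C, S) / ph.size)
    mean = float(np.rad2deg(np.arctan2(S, C)))
    if mean <= -180.0:
        mean += 360.0
    return CircularSummary(mean_direction=mean, r=r, n=int(ph.size))


def _vm_kappa(rbar: float) -> float:
    """Maximum-likelihood von Mises concentration from mean resultant length."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def watson_williams(*groups_deg, warn_threshold: float = 0.45) -> tuple[float, float]:
    """Watson-Williams F-test for a common circular mean across groups.

    Uses the standard one-way decomposition of resultant lengths with the
    ``1 + 3/(8 kappa)`` correction factor. Requires at least two groups of
    n >= 2; the test assumes reasonably concentrated von Mises samples
    (a RuntimeWarning is raised below ``warn_threshold`` mean resultant
    length).
    """
    import warnings

    groups = [np.deg2rad(np.asarray(g, float)) for g in groups_deg]
    if len(groups) < 2:
        raise InputError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise InputError("each group needs n >= 2")
    k = len(groups)
    n = sum(g.size for g in groups)
    Rs = [np.hypot(np.cos(g).sum(), np.sin(g).sum()) for g in groups]
    C, S = (sum(np.cos(g).sum() for g in groups), sum(np.sin(g).sum() for g in groups))
    R = np.hypot(C, S)
    rbar = sum(Rs) / n
    if rbar < warn_threshold:
        warnings.warn(
            f"mean resultant length {rbar:.2f} below {warn_threshold}; "
            "the Watson-Williams approximation may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    kappa = _vm_kappa(rbar)
    correction = 1.0 + 3.0 / (8.0 * kappa)
    num = (sum(Rs) - R) / (k - 1)
    den = (n - sum(Rs)) / (n - k)
    if den <= 0:
        return float("inf"), 0.0
    F = correction * num / den
    p = float(sps.f.sf(F, k - 1, n - k))
    return float(F), p
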