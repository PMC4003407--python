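"""Pattern statistics: what the listener is meant to hear, quantified.

Three analyses back the auditory impressions the sonification produces:

* summary morphometry (count, linear density, mean length and volume),
  mirroring the per-segment summaries used to compare dendrites;
* an angular periodicity test that discriminates a helical arrangement of
  insertion angles from a random one.  The statistic is the maximum, over
  candidate helix periods P, of the mean resultant length of the phase
  residuals (theta_i - 360 s_i / P); a perfect helix gives 1, uniform
  angles give ~1/sqrt(n).  Significance comes from permuting theta against
  s, re-maximizing over periods for every permutation so the search over P
  cannot inflate significance;
* a clustering test for a timbre/category class along the axis (e.g. "do
  the trumpets sound together?"): the statistic is the mean nearest-
  neighbour distance in s among the target-category spines, with a label-
  permutation null; small distances mean clustering.

Monte-Carlo p-values use the add-one rule
``p = (1 + #extreme) / (1 + n_permutations)`` with "extreme" oriented
toward the one-sided alternative (large resultant length; small
nearest-neighbour distance).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .morphology import SpineRecord
from .unroll import UnrolledSpine

__all__ = [
    "SummaryStats",
    "PatternTestResult",
    "summary_stats",
    "angular_periodicity_test",
    "category_clustering_test",
]

logger = logging.getLogger(__name__)

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class SummaryStats:
    n_spines: int
    density: float  # spines/μm
    mean_length: float  # μm
    mean_volume: float  # μm³


@dataclass(frozen=True)
class PatternTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    period: float | None = None  # best-fitting helix period (periodicity test)


def summary_stats(spines: Sequence[SpineRecord], axis_length: float) -> SummaryStats:
    """Count, density and mark means for a spine table on a segment."""
    if axis_length <= 0:
        raise ValueError("axis_length must be > 0")
    n = len(spines)
    if n == 0:
        logger.warning("empty spine table: morphometric means are undefined")
        return SummaryStats(0, 0.0, float("nan"), float("nan"))
    return SummaryStats(
        n_spines=n,
        density=n / axis_length,
        mean_length=float(np.mean([s.length_um for s in spines])),
        mean_volume=float(np.mean([s.volume_um3 for s in spines])),
    )


def _resultant_at(f: np.ndarray, s: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Mean resultant length at per-row frequencies f for phase rows w."""
    phases = np.exp(-2j * np.pi * f[:, None] * s[None, :])
    return np.abs(np.sum(phases * w, axis=1)) / s.size


def _max_resultant(
    s: np.ndarray, w: np.ndarray, f_grid: np.ndarray, n_iter: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Maximize the resultant length over frequency for each row of w.

    Coarse search on ``f_grid`` followed by golden-section refinement in
    the bracket around the grid argmax.  Returns (max value, argmax
    frequency) per row.
    """
    m = w.shape[0]
    E = np.exp(-2j * np.pi * np.outer(f_grid, s))  # (K, n)
    R = np.abs(E @ w.T) / s.size  # (K, m)
    j = np.argmax(R, axis=0)
    best = R[j, np.arange(m)]
    best_f = f_grid[j]
    a = f_grid[np.maximum(j - 1, 0)]
    b = f_grid[np.minimum(j + 1, len(f_grid) - 1)]
    for _ in range(n_iter):
        c = b - _INVPHI * (b - a)
        d = a + _INVPHI * (b - a)
        fc = _resultant_at(c, s, w)
        fd = _resultant_at(d, s, w)
        go_left = fc > fd
        b = np.where(go_left, d, b)
        a = np.where(go_left, a, c)
    f_ref = 0.5 * (a + b)
    r_ref = _resultant_at(f_ref, s, w)
    improved = r_ref > best
    return np.where(improved, r_ref, best), np.where(improved, f_ref, best_f)


def angular_periodicity_test(
    unrolled: Sequence[UnrolledSpine],
    n_permutations: int = 999,
    seed: int = 0,
    axis_length: float | None = None,
) -> PatternTestResult:
    """Helical-vs-random test on the (s, theta) point pattern.

    Candidate periods run from twice the mean inter-spine spacing up to the
    axis length, searched on a frequency grid of spacing 1/(2L) (fine
    enough to resolve the resultant-length main lobe, whose width is ~1/L)
    and refined by golden section.  The identical maximization is applied
    to each permutation of theta against s.
    """
    n = len(unrolled)
    if n < 10:
        raise ValueError("insufficient markers: need >= 10 spines")
    s = np.array([u.s for u in unrolled])
    theta = np.array([u.theta for u in unrolled])
    L = float(axis_length) if axis_length is not None else float(s.max())
    # frequencies 1/P from 1/L (period = L) to n/(2L) (period = 2 mean spacing)
    f_grid = np.arange(2, n + 1) / (2.0 * L)
    w = np.exp(2j * np.pi * theta / 360.0)

    stat, f_best = _max_resultant(s, w[None, :], f_grid)
    stat, f_best = float(stat[0]), float(f_best[0])

    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    perm_stats, _ = _max_resultant(s, w[perm_idx], f_grid)
    p = (1 + int(np.sum(perm_stats >= stat))) / (1 + n_permutations)
    return PatternTestResult(
        statistic=stat,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        period=1.0 / f_best,
    )


def _mean_nearest_neighbor(sorted_s: np.ndarray) -> np.ndarray:
    """Mean nearest-neighbour gap per row of sorted positions."""
    gaps = np.diff(sorted_s, axis=1)
    m = sorted_s.shape[1]
    nn = np.empty_like(sorted_s)
    nn[:, 0] = gaps[:, 0]
    nn[:, -1] = gaps[:, -1]
    if m > 2:
        nn[:, 1:-1] = np.minimum(gaps[:, :-1], gaps[:, 1:])
    return nn.mean(axis=1)


def category_clustering_test(
    unrolled: Sequence[UnrolledSpine],
    category_of: Callable[[UnrolledSpine], object],
    target: object,
    n_permutations: int = 999,
    seed: int = 0,
) -> PatternTestResult:
    """Are the target-category spines clustered along the axis?

    Statistic: mean nearest-neighbour distance in s among spines whose
    category equals ``target``; the null permutes category labels over
    spines.  One-sided: small distances are evidence of clustering.
    """
    s = np.array([u.s for u in unrolled])
    is_target = np.array([category_of(u) == target for u in unrolled])
    m = int(is_target.sum())
    if m < 2:
        raise ValueError(f"need >= 2 spines in target category, found {m}")
    obs = float(_mean_nearest_neighbor(np.sort(s[is_target])[None, :])[0])
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_permutations, s.size)), axis=1)[:, :m]
    perm_stats = _mean_nearest_neighbor(np.sort(s[idx], axis=1))
    p = (1 + int(np.sum(perm_stats <= obs))) / (1 + n_permutations)
    return PatternTestResult(statistic=obs, p_value=p, n_permutations=n_permutations, seed=seed)
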