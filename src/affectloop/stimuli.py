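"""Stimulus selection: maximal-span sampling of the valence-arousal plane,
extreme-valence polar subsets with iterative arousal matching, and
randomized assignment to trial types."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from affectloop.synthetic import StimulusCatalog

__all__ = [
    "PolarSubsets",
    "InfeasibleCatalogError",
    "maxspan_sample",
    "polar_subsets",
    "assign_trials",
    "VALENCE_POSITIVE_MIN",
    "VALENCE_NEGATIVE_MAX",
]

#: Valence bounds defining the polar subsets: v >= 7 (positive), v <= 2.6 (negative).
VALENCE_POSITIVE_MIN = 7.0
VALENCE_NEGATIVE_MAX = 2.6


class InfeasibleCatalogError(ValueError):
    """Raised when the catalog cannot supply the requested subsets."""


@dataclass
class PolarSubsets:
    positive: list
    negative: list
    arousal_window: tuple[float, float]
    equivalence_p: float


def maxspan_sample(catalog: StimulusCatalog, n: int, seed: int = 0) -> list:
    """Greedy farthest-point selection over the valence-arousal plane.

    Scores are min-max normalized to the unit square.  The first pick is the
    point nearest the square's centroid; each subsequent pick maximizes the
    minimum distance to the points already picked.  Exact ties are broken by
    a seeded shuffle, making the result deterministic given the seed and
    invariant to input row order.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    if n > len(catalog):
        raise ValueError(f"cannot sample {n} from catalog of {len(catalog)}")
    frame = catalog.frame
    pts = frame[["valence", "arousal"]].to_numpy(dtype=float)
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    span[span == 0] = 1.0
    pts = (pts - lo) / span

    # canonical, order-independent processing sequence with seeded tie order
    ids = frame["stim_id"].to_numpy()
    canon = np.lexsort((ids,))
    pts = pts[canon]
    ids = ids[canon]
    rng = np.random.default_rng(seed)
    tie_order = rng.permutation(len(ids))

    centroid = np.array([0.5, 0.5])
    d0 = np.linalg.norm(pts - centroid, axis=1)
    first = _argbest(-d0, tie_order)
    picked = [first]
    min_dist = np.linalg.norm(pts - pts[first], axis=1)
    min_dist[first] = -np.inf
    for _ in range(1, n):
        nxt = _argbest(min_dist, tie_order)
        picked.append(nxt)
        d = np.linalg.norm(pts - pts[nxt], axis=1)
        min_dist = np.minimum(min_dist, d)
        min_dist[nxt] = -np.inf
    return [ids[i] for i in picked]


def _argbest(values: np.ndarray, tie_order: np.ndarray) -> int:
    """Index of the maximum value; exact ties resolved by ``tie_order``."""
    best = np.max(values)
    cand = np.flatnonzero(values == best)
    if cand.size == 1:
        return int(cand[0])
    return int(cand[np.argmin(tie_order[cand])])


def polar_subsets(
    catalog: StimulusCatalog,
    n_per_side: int = 30,
    alpha: float = 0.05,
    seed: int = 0,
    step: float = 0.1,
) -> PolarSubsets:
    """Extreme-valence subsets with iteratively arousal-matched membership.

    Starting from the full arousal range, a two-sided rank-sum test compares
    the arousal of the positive (v >= 7) and negative (v <= 2.6) tails; while
    p <= alpha the window shrinks symmetrically inward by ``step`` toward the
    pooled arousal median, dropping excluded items.  After equivalence is
    reached, ``n_per_side`` items are drawn uniformly at random per side.
    """
    frame = catalog.frame
    pos = frame[frame["valence"] >= VALENCE_POSITIVE_MIN]
    neg = frame[frame["valence"] <= VALENCE_NEGATIVE_MAX]
    if len(pos) < n_per_side or len(neg) < n_per_side:
        raise InfeasibleCatalogError(
            f"valence tails too small: {len(pos)} positive / {len(neg)} negative, "
            f"need {n_per_side} each"
        )
    arousal_all = np.concatenate([pos["arousal"], neg["arousal"]])
    pooled_median = float(np.median(arousal_all))
    window = (float(arousal_all.min()), float(arousal_all.max()))

    def rank_sum_p(p_frame, n_frame) -> float:
        # Wilcoxon rank-sum with midrank tie correction
        return float(
            stats.mannwhitneyu(
                p_frame["arousal"], n_frame["arousal"], alternative="two-sided"
            ).pvalue
        )

    p_value = rank_sum_p(pos, neg)
    while p_value <= alpha:
        lo = min(window[0] + step, pooled_median)
        hi = max(window[1] - step, pooled_median)
        if (lo, hi) == window:
            raise InfeasibleCatalogError("arousal window collapsed before equivalence")
        window = (lo, hi)
        pos = pos[(pos["arousal"] >= window[0]) & (pos["arousal"] <= window[1])]
        neg = neg[(neg["arousal"] >= window[0]) & (neg["arousal"] <= window[1])]
        if len(pos) < n_per_side or len(neg) < n_per_side:
            raise InfeasibleCatalogError(
                f"arousal window {window} leaves too few items "
                f"({len(pos)} positive / {len(neg)} negative)"
            )
        p_value = rank_sum_p(pos, neg)

    rng = np.random.default_rng(seed)
    pos_ids = list(rng.choice(pos["stim_id"].to_numpy(), n_per_side, replace=False))
    neg_ids = list(rng.choice(neg["stim_id"].to_numpy(), n_per_side, replace=False))
    return PolarSubsets(
        positive=pos_ids, negative=neg_ids, arousal_window=window, equivalence_p=p_value
    )


def assign_trials(
    subsets: PolarSubsets, n_ps: int = 40, n_fs: int = 20, seed: int = 0
) -> dict:
    """Uniform random split of the polar subsets into Mod-PS / Mod-FS trials,
    balanced positive/negative within each trial type."""
    if n_ps % 2 or n_fs % 2:
        raise ValueError("n_ps and n_fs must be even for a balanced split")
    half_ps, half_fs = n_ps // 2, n_fs // 2
    if half_ps + half_fs > min(len(subsets.positive), len(subsets.negative)):
        raise ValueError("not enough stimuli per side for the requested split")
    rng = np.random.default_rng(seed)
    assignment = {}
    for side in (subsets.positive, subsets.negative):
        order = list(rng.permutation(np.asarray(side, dtype=object)))
        for sid in order[:half_ps]:
            assignment[sid] = "Mod-PS"
        for sid in order[half_ps : half_ps + half_fs]:
            assignment[sid] = "Mod-FS"
    return assignment
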