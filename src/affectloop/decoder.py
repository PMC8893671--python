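"""Valence/arousal decoding: labels, linear max-margin models, Platt scaling,
beta-series extraction, and accuracy/reliability diagnostics."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from affectloop.synthetic import (
    MID_SCORE,
    StimulusCatalog,
    VolumeSeries,
    hrf_kernel,
    validate_schedule,
)

__all__ = [
    "LabeledVolumeSet",
    "DecoderModel",
    "BetaSeries",
    "build_class_regressor",
    "label_volumes",
    "train_linear_classifier",
    "hyperplane_distance",
    "fit_platt",
    "platt_probability",
    "extract_beta_series",
    "decode",
    "within_subject_accuracy",
    "reliable_stimulus_set",
]


@dataclass
class LabeledVolumeSet:
    """Volumes with per-volume class labels in {-1, 0, +1}; 0 = unlabeled."""

    features: np.ndarray  # samples x voxels
    labels: np.ndarray  # per-sample label
    source: str = ""

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels must align")
        if not set(np.unique(self.labels)) <= {-1, 0, 1}:
            raise ValueError("labels must come from {-1, 0, +1}")

    def labeled(self) -> tuple[np.ndarray, np.ndarray]:
        mask = self.labels != 0
        return self.features[mask], self.labels[mask].astype(int)


@dataclass
class DecoderModel:
    """Linear hyperplane plus Platt calibration and accuracy diagnostics.

    ``weights`` and ``offset`` act on raw feature space (training
    standardization is folded in), so h(x) = weights @ x + offset.
    """

    weights: np.ndarray
    offset: float
    dimension: str = "valence"
    platt_a: float | None = None
    platt_b: float | None = None
    accuracy_full: float | None = None
    accuracy_reliable: float | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.platt_a is not None and self.platt_a >= 0:
            raise ValueError("platt_a must be negative (probability increasing in h)")

    @property
    def calibrated(self) -> bool:
        return self.platt_a is not None and self.platt_b is not None


@dataclass
class BetaSeries:
    """Per-trial-event regression coefficient maps."""

    tags: list = field(default_factory=list)
    maps: np.ndarray = None  # events x voxels

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] != len(self.tags):
            raise ValueError("one beta map per event tag required")


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------


def _convolve_impulses(onsets, amplitudes, tr, n_vols) -> np.ndarray:
    kernel = hrf_kernel(tr)
    out = np.zeros(n_vols)
    for onset, amp in zip(np.asarray(onsets, dtype=float), np.asarray(amplitudes, dtype=float)):
        k = int(round(onset / tr))
        if k >= n_vols:
            continue
        upper = min(n_vols, k + kernel.size)
        out[k:upper] += amp * kernel[: upper - k]
    return out


def build_class_regressor(onsets, scores, tr: float, n_vols: int) -> np.ndarray:
    """HRF-convolved impulse train with signed amplitudes (score - 5).

    Amplitude = sign(score - 5) * |score - 5|; a middle-Likert score of
    exactly 5 contributes nothing.
    """
    onsets = np.asarray(onsets, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if onsets.shape != scores.shape:
        raise ValueError("onsets and scores must align")
    if np.any(onsets < 0) or np.any(onsets >= n_vols * tr):
        raise ValueError("onsets must fall within the scan")
    if np.any(scores < 1) or np.any(scores > 9):
        raise ValueError("scores must lie in [1, 9]")
    grid_err = np.abs(onsets - np.round(onsets / tr) * tr)
    if np.any(grid_err > tr / 2):
        raise ValueError("onset misaligned to the volume grid by more than tr/2")
    amplitudes = scores - MID_SCORE
    return _convolve_impulses(onsets, amplitudes, tr, n_vols)


def label_volumes(regressor: np.ndarray, theta: float = 0.2) -> np.ndarray:
    """Threshold a signed regressor into {-1, 0, +1} volume labels.

    +1 where regressor >= theta * max|regressor|, -1 at the mirrored
    condition, 0 (unlabeled) otherwise.  An all-zero regressor labels nothing.
    """
    if not 0 < theta < 1:
        raise ValueError("theta must lie in (0, 1)")
    regressor = np.asarray(regressor, dtype=float)
    peak = np.max(np.abs(regressor))
    labels = np.zeros(regressor.size, dtype=int)
    if peak == 0:
        return labels
    labels[regressor >= theta * peak] = 1
    labels[regressor <= -theta * peak] = -1
    return labels


# ---------------------------------------------------------------------------
# Linear max-margin model
# ---------------------------------------------------------------------------


def train_linear_classifier(
    data: LabeledVolumeSet,
    C: float = 1.0,
    dimension: str = "valence",
    scale: bool = False,
) -> DecoderModel:
    """Fit a soft-margin linear SVM to the labeled volumes.

    Features are mean-centered per voxel with training statistics (variance
    scaling is optional: synthetic voxels share one noise scale, and
    per-voxel rescaling distorts pattern recovery when noise vanishes); the
    normalization is folded back into (weights, offset) so the model acts on
    raw feature space.
    """
    X, y = data.labeled()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    mu = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
    else:
        sd = np.ones(X.shape[1])
    Xs = (X - mu) / sd
    svm = SVC(kernel="linear", C=C)
    svm.fit(Xs, y)
    w_std = svm.coef_.ravel()
    b_std = float(svm.intercept_[0])
    weights = w_std / sd
    offset = b_std - float(weights @ mu)
    return DecoderModel(weights=weights, offset=offset, dimension=dimension)


def rescale_to_feedback_range(
    model: DecoderModel,
    features: np.ndarray,
    bound: float = 1.25,
    q: float = 0.95,
) -> DecoderModel:
    """Rescale (weights, offset) so |h| on reference volumes spans the feedback range.

    The streaming loop interprets h on the base range [-1.25, 1.25]; a
    max-margin fit carries no such scale, so the q-th percentile of |h| over
    the (labeled training) reference volumes is mapped to ``bound``.
    Calibration must be (re)fit after rescaling.
    """
    h = np.abs(np.atleast_1d(hyperplane_distance(model, features)))
    ref = float(np.quantile(h, q))
    if ref <= 0:
        raise ValueError("reference decision values are degenerate")
    factor = bound / ref
    return DecoderModel(
        weights=model.weights * factor,
        offset=model.offset * factor,
        dimension=model.dimension,
    )


def hyperplane_distance(model: DecoderModel, x: np.ndarray) -> np.ndarray | float:
    """Signed decision value h = weights @ x + offset (1-D or samples x voxels)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.weights.size:
        raise ValueError(
            f"dimension mismatch: model has {model.weights.size} voxels, input {x.shape[-1]}"
        )
    h = x @ model.weights + model.offset
    return float(h) if np.ndim(h) == 0 else h


# ---------------------------------------------------------------------------
# Platt scaling
# ---------------------------------------------------------------------------


def fit_platt(h, y, max_iter: int = 100, tol: float = 1e-10) -> tuple[float, float]:
    """Platt's regularized maximum-likelihood sigmoid fit.

    Returns (a, b) of Pr(+1 | h) = 1 / (1 + exp(a*h + b)) with smoothed
    targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2), using the Lin-Weng
    Newton iteration.  ``a`` is negative (probability increasing in h).
    """
    h = np.asarray(h, dtype=float)
    y = np.asarray(y)
    if np.ptp(h) == 0:
        raise ValueError("decision values are degenerate (constant)")
    pos = y > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for calibration")
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    a, b = 0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))
    sigma = 1e-12
    for _ in range(max_iter):
        fApB = a * h + b
        p = np.where(fApB >= 0, np.exp(-fApB) / (1 + np.exp(-fApB)), 1 / (1 + np.exp(fApB)))
        q = 1 - p
        d1 = t - p  # dF/d(fApB) for F = sum of t*f + log(1 + exp(-f))
        g1 = float(h @ d1)
        g2 = float(d1.sum())
        if abs(g1) < 1e-7 and abs(g2) < 1e-7:
            break
        d2 = p * q
        h11 = float(h @ (d2 * h)) + sigma
        h22 = float(d2.sum()) + sigma
        h21 = float(h @ d2)
        det = h11 * h22 - h21 * h21
        da = -(h22 * g1 - h21 * g2) / det
        db = -(-h21 * g1 + h11 * g2) / det
        # backtracking line search on the cross-entropy objective
        def objective(aa, bb):
            f = aa * h + bb
            return float(np.sum(np.where(f >= 0, t * f + np.log1p(np.exp(-f)),
                                         (t - 1) * f + np.log1p(np.exp(f)))))
        base = objective(a, b)
        step = 1.0
        while step > 1e-10:
            if objective(a + step * da, b + step * db) < base + 1e-4 * step * (g1 * da + g2 * db):
                a, b = a + step * da, b + step * db
                break
            step /= 2
        else:
            break
        if max(abs(step * da), abs(step * db)) < tol:
            break
    if a >= 0:
        raise ValueError("calibration produced a non-increasing probability map")
    return float(a), float(b)


def platt_probability(a: float, b: float, h) -> np.ndarray | float:
    f = a * np.asarray(h, dtype=float) + b
    p = np.where(f >= 0, np.exp(-f) / (1 + np.exp(-f)), 1 / (1 + np.exp(f)))
    return float(p) if np.ndim(p) == 0 else p


def decode(model: DecoderModel, x) -> np.ndarray | float:
    """Platt-scaled probability of the positive class for volume(s) x."""
    if not model.calibrated:
        raise ValueError("model is not calibrated; fit Platt coefficients first")
    h = hyperplane_distance(model, x)
    return platt_probability(model.platt_a, model.platt_b, h)


# ---------------------------------------------------------------------------
# Beta-series extraction
# ---------------------------------------------------------------------------


def extract_beta_series(
    series: VolumeSeries,
    events: pd.DataFrame,
) -> BetaSeries:
    """Least-squares-all beta-series: one HRF regressor per event.

    ``events`` needs columns ``onset`` (seconds) and ``tag``.  The design
    adds a linear drift and an intercept; returned betas are the per-event
    coefficients.  A rank-deficient design raises an error naming the
    collinear events.
    """
    tr = series.tr
    n_vols = series.n_volumes
    onsets = events["onset"].to_numpy(dtype=float)
    tags = list(events["tag"])
    if np.any(onsets < 0) or np.any(onsets >= n_vols * tr):
        raise ValueError("event onsets must fall within the scan")
    n_ev = len(tags)
    design = np.zeros((n_vols, n_ev + 2))
    for j, onset in enumerate(onsets):
        design[:, j] = _convolve_impulses([onset], [1.0], tr, n_vols)
    design[:, n_ev] = np.linspace(-1, 1, n_vols)  # drift
    design[:, n_ev + 1] = 1.0  # intercept

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(design[:, :n_ev].T)
        bad = [
            (tags[i], tags[j])
            for i, j in itertools.combinations(range(n_ev), 2)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient beta-series design; collinear events: {bad}")

    coef, *_ = np.linalg.lstsq(design, series.data.T, rcond=None)
    return BetaSeries(tags=tags, maps=coef[:n_ev])


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def within_subject_accuracy(model: DecoderModel, features, labels) -> tuple[float, float]:
    """Held-out accuracy and exact one-sided binomial p against chance 0.5."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    mask = labels != 0
    features, labels = features[mask], labels[mask]
    if labels.size == 0:
        raise ValueError("held-out set is empty")
    h = hyperplane_distance(model, features)
    pred = np.where(np.asarray(h) >= 0, 1, -1)
    n_correct = int(np.sum(pred == labels))
    accuracy = n_correct / labels.size
    p = stats.binomtest(n_correct, labels.size, 0.5, alternative="greater").pvalue
    return accuracy, float(p)


def reliable_stimulus_set(
    beta_by_subject: dict[str, BetaSeries], fraction: float = 0.5
) -> list:
    """Proxy reliable-set selection by inter-subject beta-map agreement.

    For each stimulus tag present in every subject's beta series, reliability
    is the mean pairwise inter-subject Pearson correlation of its maps; the
    top ``fraction`` of stimuli by reliability is returned.
    """
    if len(beta_by_subject) < 2:
        raise ValueError("reliability requires at least two subjects")
    tag_sets = [set(bs.tags) for bs in beta_by_subject.values()]
    common = sorted(set.intersection(*tag_sets))
    scores = {}
    for tag in common:
        maps = [bs.maps[bs.tags.index(tag)] for bs in beta_by_subject.values()]
        rs = [
            stats.pearsonr(m1, m2).statistic
            for m1, m2 in itertools.combinations(maps, 2)
        ]
        scores[tag] = float(np.mean(rs))
    n_keep = int(round(fraction * len(common)))
    ranked = sorted(common, key=lambda t: scores[t], reverse=True)
    return ranked[:n_keep]
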