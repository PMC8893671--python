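"""Neuroanatomical encoding maps: Haufe transform of decoder weights,
group-level averaging, label-permutation nulls, and cross-map comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from affectloop.decoder import LabeledVolumeSet, train_linear_classifier

__all__ = [
    "EncodingMap",
    "haufe_transform",
    "group_mean_encoding",
    "permutation_null",
    "mask_by_permutation",
    "shared_variance",
]


@dataclass
class EncodingMap:
    values: np.ndarray
    mask: np.ndarray
    p_values: np.ndarray
    dimension: str = "valence"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if not (self.values.shape == self.mask.shape == self.p_values.shape):
            raise ValueError("values, mask and p_values must share a voxel space")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("encoding values must be finite")


def haufe_transform(weights: np.ndarray, features: np.ndarray) -> np.ndarray:
    """Forward-model encoding pattern: Cov(X) w / Var(X w).

    The inverse-variance scaling of the decision values makes the transform
    self-consistent under feature whitening (whitened features give back the
    weights up to positive scale).
    """
    weights = np.asarray(weights, dtype=float)
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 2:
        raise ValueError("need at least two samples to estimate covariance")
    centered = features - features.mean(axis=0)
    decision = centered @ weights
    var_dec = float(decision @ decision) / (features.shape[0] - 1)
    if var_dec <= 0:
        raise ValueError("decision values have zero variance")
    cov_times_w = centered.T @ decision / (features.shape[0] - 1)
    return cov_times_w / var_dec


def group_mean_encoding(per_subject: list[np.ndarray]) -> np.ndarray:
    """Voxelwise arithmetic mean of per-subject encoding maps."""
    if len(per_subject) < 2:
        raise ValueError("group mean needs at least two subjects")
    maps = [np.asarray(m, dtype=float) for m in per_subject]
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("encoding maps must share a voxel space")
    return np.mean(maps, axis=0)


def observed_group_encoding(data_by_subject: dict) -> np.ndarray:
    """Group mean Haufe encoding from per-subject (features, labels) pairs."""
    encodings = []
    for features, labels in data_by_subject.values():
        model = train_linear_classifier(LabeledVolumeSet(features, labels))
        encodings.append(haufe_transform(model.weights, np.asarray(features, dtype=float)))
    return group_mean_encoding(encodings)


def permutation_null(
    data_by_subject: dict,
    n_perm: int = 1000,
    seed: int = 0,
    max_retries: int = 20,
) -> np.ndarray:
    """Null distribution of group mean encodings under label permutation.

    For each permutation, labels are shuffled within subject, the classifier
    refit, Haufe-transformed, and group-averaged.  Returns an array of shape
    (n_perm, n_voxels).  A shuffle that leaves a single class is redrawn
    (bounded retries).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if len(data_by_subject) < 2:
        raise ValueError("permutation null needs at least two subjects")
    rng = np.random.default_rng(seed)
    subjects = list(data_by_subject)
    null = None
    for p in range(n_perm):
        encodings = []
        for sid in subjects:
            features, labels = data_by_subject[sid]
            features = np.asarray(features, dtype=float)
            labels = np.asarray(labels)
            for attempt in range(max_retries):
                perm = rng.permutation(labels)
                active = perm[perm != 0]
                if np.unique(active).size >= 2:
                    break
            else:
                raise RuntimeError(f"could not find a two-class shuffle for {sid}")
            model = train_linear_classifier(LabeledVolumeSet(features, perm))
            encodings.append(haufe_transform(model.weights, features))
        gm = group_mean_encoding(encodings)
        if null is None:
            null = np.empty((n_perm, gm.size))
        null[p] = gm
    return null


def mask_by_permutation(
    observed: np.ndarray,
    null: np.ndarray,
    alpha: float = 0.05,
    dimension: str = "valence",
    pooled: bool = False,
) -> EncodingMap:
    """Two-sided permutation p-values with add-one correction, masked at alpha.

    Per-voxel exceedance by default; ``pooled=True`` compares each voxel
    against the null values pooled across all voxels.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    n_perm = null.shape[0]
    if pooled:
        flat = np.sort(np.abs(null).ravel())
        exceed = flat.size - np.searchsorted(flat, np.abs(observed), side="left")
        p = (exceed + 1.0) / (flat.size + 1.0)
    else:
        exceed = np.sum(np.abs(null) >= np.abs(observed)[None, :], axis=0)
        p = (exceed + 1.0) / (n_perm + 1.0)
    return EncodingMap(values=observed, mask=p < alpha, p_values=p, dimension=dimension)


def shared_variance(map1: EncodingMap, map2: EncodingMap, restrict_to_mask: bool = False) -> float:
    """Squared Pearson correlation of voxelwise encoding values.

    With ``restrict_to_mask`` the comparison covers only voxels surviving
    permutation masking in both maps.
    """
    if map1.values.shape != map2.values.shape:
        raise ValueError("encoding maps must share a voxel space")
    sel = (map1.mask & map2.mask) if restrict_to_mask else np.ones(map1.values.shape, bool)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 joint voxels for comparison")
    r = stats.pearsonr(map1.values[sel], map2.values[sel]).statistic
    return float(r**2)
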