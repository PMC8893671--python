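"""Synthetic data generation: stimulus catalogs, subjects, volume series.

Everything the downstream pipeline consumes is generated here with known
ground truth so that decoding, triggering, and statistical analyses can be
validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusCatalog",
    "SubjectProfile",
    "VolumeSeries",
    "PhysioTrialSeries",
    "hrf",
    "hrf_kernel",
    "generate_stimulus_catalog",
    "make_subject",
    "simulate_selfinduction",
    "simulate_volume_series",
    "simulate_physio",
    "make_identification_schedule",
    "validate_schedule",
    "score_amplitude",
]

#: Likert midpoint separating positive from negative affect scores.
MID_SCORE = 5.0

#: Trial types understood by the schedule machinery.
TRIAL_TYPES = ("Id-PS", "Id-CR-cue", "Id-CR-recall", "Mod-PS", "Mod-FS")

# HRF shape constants: response peak delay, undershoot delay (seconds) and
# peak:undershoot amplitude ratio of the canonical double-gamma form.
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_RATIO = 6.0
HRF_LENGTH = 32.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class StimulusCatalog:
    """Table of stimuli with normative valence/arousal scores (Likert 1-9).

    Wraps a :class:`pandas.DataFrame` with columns ``stim_id``, ``valence``,
    ``arousal``.  Scores must lie in [1, 9] and ids must be unique.
    """

    COLUMNS = ("stim_id", "valence", "arousal")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        if frame["stim_id"].duplicated().any():
            raise ValueError("catalog stim_ids must be unique")
        for col in ("valence", "arousal"):
            vals = frame[col].to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)) or vals.min() < 1.0 or vals.max() > 9.0:
                raise ValueError(f"{col} scores must be finite and within [1, 9]")
        self.frame = frame.reset_index(drop=True)[list(self.COLUMNS)].copy()

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, StimulusCatalog) and self.frame.equals(other.frame)

    def scores(self, stim_id: str) -> tuple[float, float]:
        row = self.frame.loc[self.frame["stim_id"] == stim_id]
        if row.empty:
            raise KeyError(f"unknown stimulus {stim_id!r}")
        return float(row["valence"].iloc[0]), float(row["arousal"].iloc[0])

    def subset(self, stim_ids) -> "StimulusCatalog":
        ids = list(stim_ids)
        sub = self.frame.set_index("stim_id").loc[ids].reset_index()
        return StimulusCatalog(sub)


@dataclass
class SubjectProfile:
    """A synthetic subject: planted encodings plus individual differences.

    ``controllability`` is the dimensionless gain in [0, 1] governing how far
    the subject can volitionally push the latent valence state during
    feedback ("BCI illiteracy" lives at the low end).
    """

    subject_id: str
    pattern_valence: np.ndarray
    pattern_arousal: np.ndarray
    noise_sd: float = 1.0
    controllability: float = 0.5
    physio_gain_cemg: float = 0.11
    physio_gain_scr: float = 0.07
    age: float = 38.8
    sex: int = 0  # 0 = male, 1 = female

    def __post_init__(self):
        self.pattern_valence = np.asarray(self.pattern_valence, dtype=float)
        self.pattern_arousal = np.asarray(self.pattern_arousal, dtype=float)
        for name, vec in (("pattern_valence", self.pattern_valence),
                          ("pattern_arousal", self.pattern_arousal)):
            norm = np.linalg.norm(vec)
            if not np.isclose(norm, 1.0, atol=1e-6):
                raise ValueError(f"{name} must have unit Euclidean norm (got {norm:.4f})")
        cosine = float(self.pattern_valence @ self.pattern_arousal)
        if abs(cosine) >= 0.95:
            raise ValueError(f"patterns must be non-collinear (|cos| = {abs(cosine):.3f})")
        if not 0.0 <= self.controllability <= 1.0:
            raise ValueError("controllability must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_voxels(self) -> int:
        return self.pattern_valence.size


@dataclass
class VolumeSeries:
    """Voxel x time matrix in percent-signal-change units."""

    data: np.ndarray
    tr: float = 2.0
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (voxels x time)")
        if np.any(~np.isfinite(self.data)):
            raise ValueError("data must not contain missing values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def volume(self, index: int) -> np.ndarray:
        return self.data[:, index]

    def times(self) -> np.ndarray:
        return self.t0 + self.tr * np.arange(self.n_volumes)


@dataclass
class PhysioTrialSeries:
    """Per-trial psychophysiological response scalars."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["stim_id", "cemg", "scr"]))


# ---------------------------------------------------------------------------
# Hemodynamic response
# ---------------------------------------------------------------------------


def hrf(t):
    """Canonical double-gamma hemodynamic response, unit peak amplitude.

    Response peak at ~6 s, undershoot trough at ~16 s, peak:undershoot
    amplitude ratio ~6:1; ``hrf(0) == 0`` and the response decays toward 0
    by 32 s.  Accepts a scalar or array of non-negative times (seconds).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("hrf is undefined for negative times")
    with np.errstate(divide="ignore", invalid="ignore"):
        peak = np.where(
            t > 0, (t / HRF_PEAK_DELAY) ** HRF_PEAK_DELAY * np.exp(HRF_PEAK_DELAY - t), 0.0
        )
        under = np.where(
            t > 0,
            (t / HRF_UNDERSHOOT_DELAY) ** HRF_UNDERSHOOT_DELAY
            * np.exp(HRF_UNDERSHOOT_DELAY - t),
            0.0,
        )
    out = peak - under / HRF_RATIO
    # normalize so the peak value is exactly 1
    norm = 1.0 - (HRF_PEAK_DELAY / HRF_UNDERSHOOT_DELAY) ** HRF_UNDERSHOOT_DELAY * np.exp(
        HRF_UNDERSHOOT_DELAY - HRF_PEAK_DELAY
    ) / HRF_RATIO
    out = out / norm
    return float(out) if out.ndim == 0 else out


def hrf_kernel(tr: float, length: float = HRF_LENGTH) -> np.ndarray:
    """HRF sampled on the TR grid, for discrete convolution."""
    return hrf(np.arange(0.0, length + tr / 2, tr))


def score_amplitude(score) -> np.ndarray:
    """Map a Likert score to a signed neural amplitude: (score - 5) / 4.

    Likert extremes 1 and 9 map to -1 and +1; the midpoint contributes 0.
    """
    return (np.asarray(score, dtype=float) - MID_SCORE) / 4.0


# ---------------------------------------------------------------------------
# Stimulus catalog
# ---------------------------------------------------------------------------

# arousal window within which the guaranteed tail items are planted; strictly
# inside the (4.6, 6.8) interval required for downstream polar sampling
_GUARANTEE_AROUSAL = (4.8, 6.6)
_N_GUARANTEE = 30


def generate_stimulus_catalog(n: int, seed: int) -> StimulusCatalog:
    """Draw a synthetic normative-score pool emulating an affective picture set.

    Valence is bimodal over [1, 9]; arousal is conditionally correlated with
    ``|valence - 5|`` (the classic "boomerang").  By construction at least 30
    items satisfy v >= 7 and at least 30 satisfy v <= 2.6, each with arousal
    inside (4.6, 6.8), so polar sampling downstream is always feasible.
    """
    if n < 2 * _N_GUARANTEE:
        raise ValueError(f"catalog needs n >= {2 * _N_GUARANTEE} (got {n})")
    rng = np.random.default_rng(seed)

    lo, hi = _GUARANTEE_AROUSAL
    v_pos = rng.uniform(7.0, 8.8, _N_GUARANTEE)
    a_pos = rng.uniform(lo, hi, _N_GUARANTEE)
    v_neg = rng.uniform(1.2, 2.6, _N_GUARANTEE)
    a_neg = rng.uniform(lo, hi, _N_GUARANTEE)

    n_rest = n - 2 * _N_GUARANTEE
    comp = rng.random(n_rest) < 0.5
    v_rest = np.where(
        comp,
        rng.normal(3.0, 1.3, n_rest),
        rng.normal(7.0, 1.3, n_rest),
    )
    v_rest = np.clip(v_rest, 1.0, 9.0)
    a_rest = np.clip(2.9 + 0.8 * np.abs(v_rest - MID_SCORE) + rng.normal(0, 0.9, n_rest), 1.0, 9.0)

    valence = np.concatenate([v_pos, v_neg, v_rest])
    arousal = np.concatenate([a_pos, a_neg, a_rest])
    order = rng.permutation(n)
    frame = pd.DataFrame(
        {
            "stim_id": [f"im{i:04d}" for i in range(n)],
            "valence": np.round(valence[order], 2),
            "arousal": np.round(arousal[order], 2),
        }
    )
    return StimulusCatalog(frame)


def make_subject(
    subject_id: str,
    n_voxels: int = 2000,
    noise_sd: float = 1.0,
    controllability: float = 0.5,
    seed: int = 0,
    **kwargs,
) -> SubjectProfile:
    """Draw a subject with random unit-norm, near-orthogonal planted patterns."""
    rng = np.random.default_rng(seed)
    pv = rng.normal(size=n_voxels)
    pa = rng.normal(size=n_voxels)
    pa -= (pa @ pv) / (pv @ pv) * pv * 0.5  # soften collinearity without full orthogonality
    pv /= np.linalg.norm(pv)
    pa /= np.linalg.norm(pa)
    return SubjectProfile(
        subject_id=subject_id,
        pattern_valence=pv,
        pattern_arousal=pa,
        noise_sd=noise_sd,
        controllability=controllability,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Trial schedules
# ---------------------------------------------------------------------------


def validate_schedule(schedule: pd.DataFrame, tr: float = 2.0) -> None:
    required = {"onset", "duration", "trial_type", "stim_id"}
    missing = required - set(schedule.columns)
    if missing:
        raise ValueError(f"schedule missing columns: {sorted(missing)}")
    onsets = schedule["onset"].to_numpy(dtype=float)
    durations = schedule["duration"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("schedule onsets must be strictly increasing")
    if np.any(durations <= 0):
        raise ValueError("schedule durations must be positive")
    if np.any(np.abs(onsets / tr - np.round(onsets / tr)) > 1e-9):
        raise ValueError("schedule onsets must align to the TR grid")
    bad = set(schedule["trial_type"]) - set(TRIAL_TYPES)
    if bad:
        raise ValueError(f"unknown trial types: {sorted(bad)}")


def make_identification_schedule(
    ps_stim_ids,
    cr_stim_ids,
    tr: float = 2.0,
    iti_range: tuple[float, float] = (2.0, 6.0),
    seed: int = 0,
    n_candidates: int = 20,
) -> pd.DataFrame:
    """Build a pseudo-random Identification schedule (Id-PS + Id-CR trials).

    Id-PS: 2 s cue then ITI.  Id-CR: 2 s cue, 2 s cue-response, 8 s recall,
    then ITI.  Among ``n_candidates`` seeded random orderings, the one
    minimizing the absolute correlation between the HRF-convolved PS and CR
    cue regressors is kept (the fixed orders used in-scanner are not public).
    """
    rng = np.random.default_rng(seed)
    ps = list(ps_stim_ids)
    cr = list(cr_stim_ids)

    def build(order_rng):
        kinds = ["ps"] * len(ps) + ["cr"] * len(cr)
        order_rng.shuffle(kinds)
        ps_iter = iter(order_rng.permutation(ps))
        cr_iter = iter(order_rng.permutation(cr))
        rows = []
        t = 0.0
        for kind in kinds:
            iti = order_rng.uniform(*iti_range)
            if kind == "ps":
                rows.append((t, 2.0, "Id-PS", next(ps_iter)))
                t += 2.0
            else:
                sid = next(cr_iter)
                rows.append((t, 2.0, "Id-CR-cue", sid))
                rows.append((t + 4.0, 8.0, "Id-CR-recall", sid))
                t += 12.0
            t += tr * round(iti / tr)  # keep onsets on the TR grid
        return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "stim_id"])

    from affectloop.decoder import _convolve_impulses  # local import avoids a cycle

    best, best_score = None, np.inf
    for _ in range(n_candidates):
        cand = build(rng)
        n_vols = int(np.ceil((cand["onset"].iloc[-1] + 16.0) / tr))
        ps_rows = cand[cand["trial_type"] == "Id-PS"]
        cr_rows = cand[cand["trial_type"] == "Id-CR-cue"]
        r_ps = _convolve_impulses(ps_rows["onset"].to_numpy(), np.ones(len(ps_rows)), tr, n_vols)
        r_cr = _convolve_impulses(cr_rows["onset"].to_numpy(), np.ones(len(cr_rows)), tr, n_vols)
        score = abs(np.corrcoef(r_ps, r_cr)[0, 1])
        if score < best_score:
            best, best_score = cand, score
    validate_schedule(best, tr)
    return best


# ---------------------------------------------------------------------------
# Latent self-induction
# ---------------------------------------------------------------------------

FEEDBACK_BOUND = 1.25


def simulate_selfinduction(
    subject: SubjectProfile,
    duration: float,
    tr: float = 2.0,
    seed: int = 0,
    rate: float = 0.25,
    innovation_sd: float = 0.15,
) -> np.ndarray:
    """Latent valence trajectory during volitional self-induction.

    Mean-reverting walk from 0 toward an asymptote of
    ``1.25 * controllability``, clipped to [-1.25, 1.25].  One sample per TR.
    """
    if duration < tr:
        raise ValueError("duration must be at least one TR")
    rng = np.random.default_rng(seed)
    n = int(round(duration / tr))
    target = FEEDBACK_BOUND * subject.controllability
    x = 0.0
    out = np.empty(n)
    for k in range(n):
        x = x + rate * (target - x) + rng.normal(0.0, innovation_sd)
        x = float(np.clip(x, -FEEDBACK_BOUND, FEEDBACK_BOUND))
        out[k] = x
    return out


# ---------------------------------------------------------------------------
# Volume series
# ---------------------------------------------------------------------------


def _impulse_times(onset: float, duration: float, tr: float) -> np.ndarray:
    """TR-grid impulse times covering [onset, onset + duration)."""
    n = max(1, int(round(duration / tr)))
    return onset + tr * np.arange(n)


def simulate_volume_series(
    schedule: pd.DataFrame,
    subject: SubjectProfile,
    catalog: StimulusCatalog | None,
    seed: int = 0,
    tr: float = 2.0,
    n_volumes: int | None = None,
    drift_slope_sd: float = 0.002,
    selfinduction_kwargs: dict | None = None,
) -> VolumeSeries:
    """Synthesize a voxel x time series for a trial schedule.

    data(t) = s_v(t) * pattern_valence + s_a(t) * pattern_arousal
              + drift(t) + noise, where s_v / s_a are HRF-convolved impulse
    trains with amplitudes (score - 5)/4 per stimulus event.  ``Mod-FS`` rows
    are self-induce periods: their impulse train is the latent trajectory from
    :func:`simulate_selfinduction`, scaled so the convolved steady state
    matches the latent level.
    """
    validate_schedule(schedule, tr)
    if n_volumes is None:
        end = schedule["onset"].iloc[-1] + schedule["duration"].iloc[-1]
        n_volumes = int(np.ceil((end + 16.0) / tr))
    end_needed = schedule["onset"].iloc[-1] + schedule["duration"].iloc[-1]
    if end_needed > n_volumes * tr + 1e-9:
        raise ValueError("schedule extends past scan length")

    rng = np.random.default_rng(seed)
    kernel = hrf_kernel(tr)
    gain = kernel.sum()  # steady-state gain of sustained unit input

    sv = np.zeros(n_volumes)
    sa = np.zeros(n_volumes)
    for i, row in enumerate(schedule.itertuples(index=False)):
        if row.trial_type == "Mod-FS":
            traj = simulate_selfinduction(
                subject,
                row.duration,
                tr,
                seed=np.random.default_rng([seed, 7919, i]).integers(2**31),
                **(selfinduction_kwargs or {}),
            )
            times = _impulse_times(row.onset, row.duration, tr)
            idx = np.round(times / tr).astype(int)
            for j, k in enumerate(idx):
                if k < n_volumes:
                    upper = min(n_volumes, k + kernel.size)
                    sv[k:upper] += (traj[j] / gain) * kernel[: upper - k]
        else:
            v, a = catalog.scores(row.stim_id)
            amp_v = float(score_amplitude(v))
            amp_a = float(score_amplitude(a))
            for t in _impulse_times(row.onset, row.duration, tr):
                k = int(round(t / tr))
                if k >= n_volumes:
                    continue
                upper = min(n_volumes, k + kernel.size)
                sv[k:upper] += amp_v * kernel[: upper - k]
                sa[k:upper] += amp_a * kernel[: upper - k]

    slopes = rng.normal(0.0, drift_slope_sd, subject.n_voxels)
    drift = np.outer(slopes, np.arange(n_volumes))
    noise = rng.normal(0.0, subject.noise_sd, (subject.n_voxels, n_volumes)) \
        if subject.noise_sd > 0 else 0.0
    data = (
        np.outer(subject.pattern_valence, sv)
        + np.outer(subject.pattern_arousal, sa)
        + drift
        + noise
    )
    return VolumeSeries(data=data, tr=tr, t0=0.0)


def simulate_rest_series(
    subject: SubjectProfile,
    n_volumes: int,
    seed: int = 0,
    tr: float = 2.0,
    drift_slope_sd: float = 0.002,
) -> VolumeSeries:
    """Resting-state series: drift + noise only, no planted affect signal."""
    rng = np.random.default_rng(seed)
    slopes = rng.normal(0.0, drift_slope_sd, subject.n_voxels)
    data = np.outer(slopes, np.arange(n_volumes))
    if subject.noise_sd > 0:
        data = data + rng.normal(0.0, subject.noise_sd, (subject.n_voxels, n_volumes))
    return VolumeSeries(data=data, tr=tr, t0=0.0)


# ---------------------------------------------------------------------------
# Psychophysiology
# ---------------------------------------------------------------------------


def simulate_physio(
    catalog_row,
    subject: SubjectProfile,
    seed: int = 0,
    noise_sd_cemg: float = 0.25,
    noise_sd_scr: float = 0.25,
) -> dict:
    """Trial-level corrugator EMG and skin-conductance responses.

    cemg responds linearly to valence, scr to arousal, each with the
    subject's gain plus independent Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    v = float(catalog_row["valence"])
    a = float(catalog_row["arousal"])
    cemg = subject.physio_gain_cemg * float(score_amplitude(v))
    scr = subject.physio_gain_scr * float(score_amplitude(a))
    if noise_sd_cemg > 0:
        cemg += rng.normal(0.0, noise_sd_cemg)
    if noise_sd_scr > 0:
        scr += rng.normal(0.0, noise_sd_scr)
    return {"stim_id": catalog_row["stim_id"], "cemg": cemg, "scr": scr}
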