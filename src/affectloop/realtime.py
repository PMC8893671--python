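"""Closed-loop feedback machinery: per-volume streaming decode, online
detrending, feedback transparency, and the consecutive-criterion trigger
with threshold decay and emergency default."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from affectloop.decoder import DecoderModel, hyperplane_distance
from affectloop.synthetic import (
    FEEDBACK_BOUND,
    StimulusCatalog,
    SubjectProfile,
    VolumeSeries,
    hrf_kernel,
    score_amplitude,
    simulate_selfinduction,
    simulate_volume_series,
)

__all__ = [
    "TriggerPolicy",
    "FeedbackTrace",
    "TrialRecord",
    "detrend_online",
    "feedback_alpha",
    "threshold_at",
    "step_trigger",
    "run_modfs_trial",
]


@dataclass
class TriggerPolicy:
    """Parameters of the feedback/trigger state machine.

    The criterion is a detrended hyperplane distance at or above the current
    threshold for ``n_consecutive`` volumes; the threshold holds at
    ``threshold0`` for ``hold`` seconds, then decays linearly to 0 over
    ``decay`` seconds, at which point the stimulus triggers by default.
    """

    threshold0: float = 0.8
    n_consecutive: int = 4
    hold: float = 20.0
    decay: float = 18.0
    feedback_range: tuple[float, float] = (-FEEDBACK_BOUND, FEEDBACK_BOUND)
    detrend_start_index: int = 40
    trial_length: float = 44.0
    min_iti: float = 4.0
    cue_duration: float = 2.0
    tr: float = 2.0

    def __post_init__(self):
        if not 0 < self.threshold0 < self.feedback_range[1]:
            raise ValueError("threshold0 must lie in (0, feedback max)")
        if self.hold <= 0 or self.decay <= 0:
            raise ValueError("hold and decay must be positive")
        if self.n_consecutive < 1:
            raise ValueError("n_consecutive must be at least 1")


@dataclass
class FeedbackTrace:
    """Per-volume log of the streaming loop (1-based volume indices)."""

    rows: list = field(default_factory=list)

    def append(self, **row):
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=[
                "index",
                "h_raw",
                "h_detrended",
                "alpha",
                "threshold_now",
                "consec_count",
                "event",
            ],
        )


@dataclass
class TrialRecord:
    trial_id: str
    trigger_time: float
    trigger_type: str  # "criterion" | "emergency"
    feedback_at_trigger: float
    stimulus: str
    congruence: str  # "congruent" | "incongruent"
    iti: float


# ---------------------------------------------------------------------------
# Streaming primitives
# ---------------------------------------------------------------------------


def detrend_online(history, h_i: float, i: int, policy: TriggerPolicy) -> float:
    """Remove the OLS linear trend of h_1..h_{i-1} from h_i.

    Below ``detrend_start_index`` (1-based volume count from scan start) the
    raw value passes through unchanged.
    """
    history = np.asarray(history, dtype=float)
    if history.size != i - 1:
        raise ValueError("history must contain exactly i-1 values")
    if i < policy.detrend_start_index:
        return float(h_i)
    k = np.arange(1, i, dtype=float)
    slope, intercept = np.polyfit(k, history, 1)
    return float(h_i - (slope * i + intercept))


def feedback_alpha(h: float, policy: TriggerPolicy) -> float:
    """Map a hyperplane distance to text transparency in [0, 1].

    Affine map of the feedback range [-1.25, 1.25] onto [0, 1], clipped;
    recomputed once per volume.
    """
    lo, hi = policy.feedback_range
    return float(np.clip((h - lo) / (hi - lo), 0.0, 1.0))


def threshold_at(t: float, policy: TriggerPolicy) -> float:
    """Trigger threshold at ``t`` seconds since feedback onset."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if t <= policy.hold:
        return policy.threshold0
    if t < policy.hold + policy.decay:
        return policy.threshold0 * (1.0 - (t - policy.hold) / policy.decay)
    return 0.0


@dataclass
class TriggerState:
    consec_count: int = 0
    event: str | None = None  # "trigger" | "emergency" once fired


def step_trigger(state: TriggerState, h_detrended: float, t: float, policy: TriggerPolicy) -> TriggerState:
    """Advance the trigger state machine by one volume.

    The consecutive counter increments while the detrended distance meets the
    time-varying threshold and resets otherwise; the criterion event fires at
    ``n_consecutive`` hits, and the emergency event fires unconditionally at
    the first volume with t >= hold + decay if nothing fired before.
    """
    if state.event is not None:
        raise RuntimeError("step_trigger called after the trial already triggered")
    thr = threshold_at(t, policy)
    if h_detrended >= thr:
        state.consec_count += 1
    else:
        state.consec_count = 0
    if state.consec_count >= policy.n_consecutive:
        state.event = "trigger"
    elif t >= policy.hold + policy.decay:
        state.event = "emergency"
    return state


# ---------------------------------------------------------------------------
# Full Mod-FS trial
# ---------------------------------------------------------------------------


def run_modfs_trial(
    subject: SubjectProfile,
    model: DecoderModel,
    policy: TriggerPolicy,
    stimulus: str,
    congruence: str,
    catalog: StimulusCatalog,
    seed: int = 0,
    h_history=None,
    trial_id: str = "modfs",
    selfinduction_kwargs: dict | None = None,
) -> tuple[TrialRecord, FeedbackTrace, VolumeSeries]:
    """Simulate one closed-loop feedback-triggered stimulus trial.

    Volumes are synthesized from the subject's latent self-induction
    trajectory, decoded one at a time, detrended online, mapped to feedback
    transparency, and stepped through the trigger machine.  At trigger the
    pre-assigned stimulus is "presented" (its HRF response is added to the
    remaining volumes) and the ITI absorbs the slack so trial length is fixed.

    ``h_history`` carries raw hyperplane distances from earlier volumes of
    the same run, so the online detrender sees the acquisition stream.
    """
    tr = policy.tr
    history = [float(v) for v in (h_history if h_history is not None else [])]
    n_history = len(history)

    max_fb = policy.hold + policy.decay
    # 16 s padding past the fixed trial length so the triggered stimulus
    # response is fully observable even on emergency trials
    n_pad = int(round(16.0 / tr))
    n_trial_vols = int(round(policy.trial_length / tr))
    # latent self-induce signal spans the whole feedback window
    fb_schedule = pd.DataFrame(
        [(0.0, max_fb, "Mod-FS", stimulus)],
        columns=["onset", "duration", "trial_type", "stim_id"],
    )
    base = simulate_volume_series(
        fb_schedule,
        subject,
        catalog,
        seed=seed,
        tr=tr,
        n_volumes=n_trial_vols + n_pad,
        selfinduction_kwargs=selfinduction_kwargs,
    )

    trace = FeedbackTrace()
    state = TriggerState()
    trigger_volume = None
    for k in range(n_trial_vols):
        t = k * tr
        h_raw = hyperplane_distance(model, base.volume(k))
        i = n_history + k + 1
        h_det = detrend_online(history, h_raw, i, policy)
        history.append(h_raw)
        state = step_trigger(state, h_det, t, policy)
        trace.append(
            index=i,
            h_raw=h_raw,
            h_detrended=h_det,
            alpha=feedback_alpha(h_det, policy),
            threshold_now=threshold_at(t, policy),
            consec_count=state.consec_count,
            event=state.event or "none",
        )
        if state.event is not None:
            trigger_volume = k
            break

    if trigger_volume is None:
        raise ValueError("trial_length too short: no volume at/after hold + decay")
    trigger_time = trigger_volume * tr
    trigger_type = "criterion" if state.event == "trigger" else "emergency"
    feedback_at_trigger = trace.rows[-1]["h_detrended"]

    # stimulus response added from the trigger volume onward
    v, a = catalog.scores(stimulus)
    kernel = hrf_kernel(tr)
    n_after = n_trial_vols + n_pad - trigger_volume
    stim_sv = float(score_amplitude(v)) * kernel[:n_after]
    stim_sa = float(score_amplitude(a)) * kernel[:n_after]
    data = base.data.copy()
    data[:, trigger_volume:trigger_volume + stim_sv.size] += (
        np.outer(subject.pattern_valence, stim_sv)
        + np.outer(subject.pattern_arousal, stim_sa)
    )
    series = VolumeSeries(data=data, tr=tr, t0=0.0)

    iti = policy.trial_length - (trigger_time + policy.cue_duration)
    iti = max(iti, policy.min_iti)

    record = TrialRecord(
        trial_id=trial_id,
        trigger_time=trigger_time,
        trigger_type=trigger_type,
        feedback_at_trigger=feedback_at_trigger,
        stimulus=stimulus,
        congruence=congruence,
        iti=iti,
    )
    return record, trace, series
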