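"""Surrogate cued-recall trials sampled from resting-state decodings,
used as within-subject null controls for the regulation analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from affectloop.decoder import DecoderModel, decode
from affectloop.synthetic import VolumeSeries

__all__ = ["SurrogateTrialSet", "decode_resting", "sample_surrogate_trials"]

# Id-CR trial footprint (seconds): cue 2, cue response 2, recall 8
CUE_DURATION = 2.0
CUE_RESPONSE_DURATION = 2.0
RECALL_DURATION = 8.0
RECALL_OFFSET = CUE_DURATION + CUE_RESPONSE_DURATION  # recall starts 4 s after cue
FOOTPRINT = CUE_DURATION + CUE_RESPONSE_DURATION + RECALL_DURATION
N_RECALL_VOLUMES = 4


@dataclass
class SurrogateTrialSet:
    frame: pd.DataFrame  # onset, cue_value, recall_1..recall_4

    def __len__(self) -> int:
        return len(self.frame)


def decode_resting(series: VolumeSeries, model: DecoderModel) -> np.ndarray:
    """Decoded probability for every resting volume."""
    return np.atleast_1d(decode(model, series.data.T))


def sample_surrogate_trials(
    decoded: np.ndarray,
    n: int = 30,
    tr: float = 2.0,
    seed: int = 0,
    allow_overlap: bool = False,
) -> SurrogateTrialSet:
    """Uniform random surrogate cue/recall onsets over a decoded rest series.

    Onsets are TR-aligned and drawn without replacement; by default trial
    footprints (cue + cue response + recall = 12 s) may not overlap.
    cue_value is the decoded value at the cue volume; recall values are the
    4 recall-window volumes starting 4 s after the cue.
    """
    decoded = np.asarray(decoded, dtype=float)
    footprint_vols = int(round(FOOTPRINT / tr))
    recall_start = int(round(RECALL_OFFSET / tr))
    max_onset_vol = decoded.size - footprint_vols
    if max_onset_vol < 0:
        raise ValueError("series too short for a single surrogate trial")
    rng = np.random.default_rng(seed)
    candidates = np.arange(max_onset_vol + 1)
    if allow_overlap:
        if candidates.size < n:
            raise ValueError("series too short for the requested trial count")
        chosen = rng.choice(candidates, n, replace=False)
    else:
        chosen = []
        occupied = np.zeros(decoded.size, dtype=bool)
        for vol in rng.permutation(candidates):
            if occupied[vol : vol + footprint_vols].any():
                continue
            occupied[vol : vol + footprint_vols] = True
            chosen.append(vol)
            if len(chosen) == n:
                break
        if len(chosen) < n:
            raise ValueError(
                f"series too short for {n} non-overlapping surrogate trials"
            )
        chosen = np.asarray(chosen)
    chosen = np.sort(chosen)
    rows = []
    for vol in chosen:
        recall = decoded[vol + recall_start : vol + recall_start + N_RECALL_VOLUMES]
        rows.append(
            {
                "onset": vol * tr,
                "cue_value": decoded[vol],
                **{f"recall_{k + 1}": recall[k] for k in range(N_RECALL_VOLUMES)},
            }
        )
    return SurrogateTrialSet(pd.DataFrame(rows))
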