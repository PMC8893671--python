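"""End-to-end experiment on a synthetic cohort.

Wires the modules together: catalog generation and stimulus selection,
identification-task simulation and decoder training, the closed modulation
loop, surrogate resting trials, table assembly, and the full battery of
mixed-effects analyses.  Backs both the CLI and the smoke tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from affectloop import io as alio
from affectloop.bias import (
    induction_predictor_test,
    novel_stimulus_validation,
    physio_validation,
    primary_bias_test,
    regulation_test,
    trigger_validation,
)
from affectloop.decoder import (
    BetaSeries,
    LabeledVolumeSet,
    build_class_regressor,
    decode,
    extract_beta_series,
    fit_platt,
    hyperplane_distance,
    label_volumes,
    reliable_stimulus_set,
    rescale_to_feedback_range,
    train_linear_classifier,
    within_subject_accuracy,
)
from affectloop.encoding import (
    group_mean_encoding,
    haufe_transform,
    mask_by_permutation,
    permutation_null,
)
from affectloop.realtime import TriggerPolicy, run_modfs_trial
from affectloop.stimuli import assign_trials, maxspan_sample, polar_subsets
from affectloop.surrogate import decode_resting, sample_surrogate_trials
from affectloop.synthetic import (
    MID_SCORE,
    generate_stimulus_catalog,
    make_identification_schedule,
    make_subject,
    simulate_physio,
    simulate_rest_series,
    simulate_volume_series,
)

__all__ = ["PipelineConfig", "run_experiment", "train_subject_decoders"]


@dataclass
class PipelineConfig:
    """Cohort and task sizes; defaults are smoke-test scale."""

    n_subjects: int = 8
    n_voxels: int = 300
    catalog_size: int = 400
    n_id_ps: int = 60
    n_id_cr: int = 20
    n_id_runs: int = 2
    n_mod_ps: int = 40
    n_mod_fs: int = 20
    n_mod_runs: int = 2
    noise_sd: float = 0.15
    controllability_range: tuple[float, float] = (0.4, 1.0)
    rest_volumes: int = 360  # long enough for 30 non-overlapping surrogate footprints
    surrogate_n: int = 30
    label_theta: float = 0.2
    n_perm: int = 100
    tr: float = 2.0
    policy: TriggerPolicy = field(default_factory=TriggerPolicy)


def _labeled_volumes(series, schedule, catalog, dimension, theta):
    ps = schedule[schedule["trial_type"] == "Id-PS"]
    scores = [catalog.scores(s)[0 if dimension == "valence" else 1] for s in ps["stim_id"]]
    regressor = build_class_regressor(
        ps["onset"].to_numpy(), scores, series.tr, series.n_volumes
    )
    labels = label_volumes(regressor, theta)
    return LabeledVolumeSet(series.data.T, labels, source=dimension)


def _beta_labels(tags, catalog, dimension):
    idx = 0 if dimension == "valence" else 1
    labels = []
    for tag in tags:
        score = catalog.scores(tag)[idx]
        labels.append(0 if score == MID_SCORE else (1 if score > MID_SCORE else -1))
    return np.asarray(labels)


def train_subject_decoders(subject, schedules, catalog, config, seed):
    """Train volume-level and beta-level decoders for one subject.

    Run 1 trains, run 2 calibrates (Platt) and scores held-out accuracy.
    Returns (volume models, beta models, beta series per run, accuracy dict).
    """
    rng = np.random.default_rng(seed)
    series = [
        simulate_volume_series(
            sched, subject, catalog, seed=int(rng.integers(2**31)), tr=config.tr
        )
        for sched in schedules
    ]
    betas = []
    for sched, ser in zip(schedules, series):
        ps = sched[sched["trial_type"] == "Id-PS"]
        events = pd.DataFrame({"onset": ps["onset"], "tag": ps["stim_id"]})
        betas.append(extract_beta_series(ser, events))

    vol_models, beta_models, accuracy = {}, {}, {}
    for dim in ("valence", "arousal"):
        train_set = _labeled_volumes(series[0], schedules[0], catalog, dim, config.label_theta)
        vmodel = train_linear_classifier(train_set, dimension=dim)
        vmodel = rescale_to_feedback_range(vmodel, train_set.labeled()[0])
        held = _labeled_volumes(series[1], schedules[1], catalog, dim, config.label_theta)
        h_held = hyperplane_distance(vmodel, held.labeled()[0])
        vmodel.platt_a, vmodel.platt_b = fit_platt(h_held, held.labeled()[1])
        vol_models[dim] = vmodel

        y_train = _beta_labels(betas[0].tags, catalog, dim)
        bmodel = train_linear_classifier(
            LabeledVolumeSet(betas[0].maps, y_train), dimension=dim
        )
        y_held = _beta_labels(betas[1].tags, catalog, dim)
        mask = y_held != 0
        h_beta = hyperplane_distance(bmodel, betas[1].maps[mask])
        bmodel.platt_a, bmodel.platt_b = fit_platt(h_beta, y_held[mask])
        acc, p = within_subject_accuracy(bmodel, betas[1].maps, y_held)
        bmodel.accuracy_full = acc
        accuracy[dim] = {"accuracy": acc, "p": p}
        beta_models[dim] = bmodel
    return vol_models, beta_models, betas, accuracy


#: hemodynamic lag (volumes) applied when reading out a stimulus response
HRF_LAG_VOLUMES = 3


def run_experiment(config: PipelineConfig | None = None, seed: int = 0, outdir=None) -> dict:
    """Simulate the full cohort experiment and run every analysis.

    Returns a dict of tables and fit results; if ``outdir`` is given, writes
    TSV/JSON (and HDF5 decoder/encoding) artifacts there.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    policy = config.policy
    tr = config.tr

    # --- stimulus machinery (shared across the cohort, as in the design) ---
    catalog = generate_stimulus_catalog(config.catalog_size, seed=int(rng.integers(2**31)))
    id_ps_ids = maxspan_sample(catalog, config.n_id_ps, seed=int(rng.integers(2**31)))
    rest_ids = [s for s in catalog.frame["stim_id"] if s not in set(id_ps_ids)]
    id_cr_ids = maxspan_sample(
        catalog.subset(rest_ids), config.n_id_cr, seed=int(rng.integers(2**31))
    )
    polar = polar_subsets(catalog, n_per_side=30, seed=int(rng.integers(2**31)))
    assignment = assign_trials(
        polar, n_ps=config.n_mod_ps, n_fs=config.n_mod_fs, seed=int(rng.integers(2**31))
    )
    mod_ps_ids = [s for s, kind in assignment.items() if kind == "Mod-PS"]
    mod_fs_ids = [s for s, kind in assignment.items() if kind == "Mod-FS"]

    # fixed pseudo-random identification schedules shared by all subjects
    per_run_ps = np.array_split(np.asarray(id_ps_ids, dtype=object), config.n_id_runs)
    per_run_cr = np.array_split(np.asarray(id_cr_ids, dtype=object), config.n_id_runs)
    id_schedules = [
        make_identification_schedule(
            list(per_run_ps[r]), list(per_run_cr[r]), tr=tr, seed=int(rng.integers(2**31))
        )
        for r in range(config.n_id_runs)
    ]

    mod_rows, idps_rows, idcr_rows, reg_rows, records = [], [], [], [], []
    beta_by_subject, encoding_data = {}, {"valence": {}, "arousal": {}}
    subjects = []
    c_lo, c_hi = config.controllability_range
    for j in range(config.n_subjects):
        subject = make_subject(
            f"s{j:03d}",
            n_voxels=config.n_voxels,
            noise_sd=config.noise_sd,
            controllability=float(rng.uniform(c_lo, c_hi)),
            seed=int(rng.integers(2**31)),
            age=float(np.clip(rng.normal(38.8, 13.3), 20, 65)),
            sex=int(j % 2),  # balanced so sex never aliases the intercept
        )
        subjects.append(subject)
        vol_models, beta_models, betas, accuracy = train_subject_decoders(
            subject, id_schedules, catalog, config, seed=int(rng.integers(2**31))
        )
        acc_val = accuracy["valence"]["accuracy"]
        all_beta = BetaSeries(
            tags=betas[0].tags + betas[1].tags,
            maps=np.vstack([betas[0].maps, betas[1].maps]),
        )
        beta_by_subject[subject.subject_id] = all_beta
        for dim in ("valence", "arousal"):
            encoding_data[dim][subject.subject_id] = (
                all_beta.maps,
                _beta_labels(all_beta.tags, catalog, dim),
            )

        base = {
            "subject_id": subject.subject_id,
            "age": subject.age,
            "sex": subject.sex,
            "decoder_accuracy": acc_val,
        }

        # --- identification rows: physiology + cued recall -----------------
        for sid in id_ps_ids:
            v, a = catalog.scores(sid)
            physio = simulate_physio(
                {"stim_id": sid, "valence": v, "arousal": a},
                subject,
                seed=int(rng.integers(2**31)),
            )
            idps_rows.append(
                {**base, "trial_type": "Id-PS", "stim_id": sid, "norm_valence": v,
                 "norm_arousal": a, "cemg": physio["cemg"], "scr": physio["scr"]}
            )

        # Id-CR cue betas and recall-volume decodings from the Id runs
        for sched_idx, sched in enumerate(id_schedules):
            ser = simulate_volume_series(
                sched, subject, catalog, seed=int(rng.integers(2**31)), tr=tr
            )
            cues = sched[sched["trial_type"] == "Id-CR-cue"]
            events = pd.DataFrame({"onset": cues["onset"], "tag": cues["stim_id"]})
            cue_betas = extract_beta_series(ser, events)
            dec_rest_v = decode(vol_models["valence"], ser.data.T)
            dec_rest_a = decode(vol_models["arousal"], ser.data.T)
            for k, row in enumerate(cues.itertuples(index=False)):
                v, a = catalog.scores(row.stim_id)
                cue_v = float(decode(beta_models["valence"], cue_betas.maps[k]))
                cue_a = float(decode(beta_models["arousal"], cue_betas.maps[k]))
                idcr_rows.append(
                    {**base, "trial_type": "Id-CR", "stim_id": row.stim_id,
                     "norm_valence": v, "norm_arousal": a,
                     "decoded_valence": cue_v, "decoded_arousal": cue_a}
                )
                recall_start = int(round((row.onset + 4.0 + 4.0) / tr))  # + HRF lag
                for lag in range(1, 5):
                    idx = min(recall_start + lag - 1, ser.n_volumes - 1)
                    for dim, cue_val, dec in (
                        ("valence", cue_v, dec_rest_v),
                        ("arousal", cue_a, dec_rest_a),
                    ):
                        reg_rows.append(
                            {**base, "trial_type": "Id-CR", "dimension": dim,
                             "cue": cue_val, "recall": float(dec[idx]),
                             "recall_lag": lag}
                        )

        # --- modulation runs ------------------------------------------------
        ps_seq = list(rng.permutation(np.asarray(mod_ps_ids, dtype=object)))
        fs_seq = list(rng.permutation(np.asarray(mod_fs_ids, dtype=object)))
        kinds = ["Mod-PS"] * len(ps_seq) + ["Mod-FS"] * len(fs_seq)
        rng.shuffle(kinds)
        h_history: list[float] = []
        for t_idx, kind in enumerate(kinds):
            if kind == "Mod-PS":
                sid = ps_seq.pop()
                cue_onset = 8.0
                seg_sched = pd.DataFrame(
                    [(cue_onset, 2.0, "Mod-PS", sid)],
                    columns=["onset", "duration", "trial_type", "stim_id"],
                )
                seg = simulate_volume_series(
                    seg_sched, subject, catalog, seed=int(rng.integers(2**31)),
                    tr=tr, n_volumes=12,
                )
                feedback_at_trigger, trigger_type = np.nan, ""
            else:
                sid = fs_seq.pop()
                v_stim, _ = catalog.scores(sid)
                congruence = "congruent" if v_stim > MID_SCORE else "incongruent"
                record, trace, seg = run_modfs_trial(
                    subject, vol_models["valence"], policy, sid, congruence,
                    catalog, seed=int(rng.integers(2**31)), h_history=h_history,
                    trial_id=f"{subject.subject_id}-t{t_idx:02d}",
                )
                records.append({**asdict(record), "subject_id": subject.subject_id})
                cue_onset = record.trigger_time
                feedback_at_trigger = record.feedback_at_trigger
                trigger_type = record.trigger_type
            h_history.extend(
                np.atleast_1d(hyperplane_distance(vol_models["valence"], seg.data.T)).tolist()
            )
            # per-volume decodings: the volume before the cue (trigger volume
            # on Mod-FS trials) and the stimulus response one HRF lag later
            cue_vol = int(round(cue_onset / tr))
            resp_vol = min(cue_vol + HRF_LAG_VOLUMES, seg.n_volumes - 1)
            prev_vol = max(cue_vol - 1, 0) if kind == "Mod-PS" else cue_vol
            v, a = catalog.scores(sid)
            physio = simulate_physio(
                {"stim_id": sid, "valence": v, "arousal": a}, subject,
                seed=int(rng.integers(2**31)),
            )
            mod_rows.append(
                {**base, "trial_type": kind, "stim_id": sid,
                 "norm_valence": v, "norm_arousal": a,
                 "decoded_valence": float(decode(vol_models["valence"], seg.volume(resp_vol))),
                 "decoded_arousal": float(decode(vol_models["arousal"], seg.volume(resp_vol))),
                 "prev_decoded_valence": float(decode(vol_models["valence"], seg.volume(prev_vol))),
                 "cemg": physio["cemg"], "scr": physio["scr"],
                 "feedback_at_trigger": feedback_at_trigger,
                 "trigger_type": trigger_type}
            )

        # --- surrogate resting trials --------------------------------------
        rest = simulate_rest_series(
            subject, config.rest_volumes, seed=int(rng.integers(2**31)), tr=tr
        )
        for dim in ("valence", "arousal"):
            decoded = decode_resting(rest, vol_models[dim])
            surr = sample_surrogate_trials(
                decoded, n=config.surrogate_n, tr=tr, seed=int(rng.integers(2**31))
            )
            for row in surr.frame.itertuples(index=False):
                for lag in range(1, 5):
                    reg_rows.append(
                        {**base, "trial_type": "surrogate", "dimension": dim,
                         "cue": float(row.cue_value),
                         "recall": float(getattr(row, f"recall_{lag}")),
                         "recall_lag": lag}
                    )

    # --- cohort-level diagnostics and analyses -----------------------------
    reliable = reliable_stimulus_set(beta_by_subject, fraction=0.5)

    table = pd.DataFrame(mod_rows)
    idps = pd.DataFrame(idps_rows)
    idcr = pd.DataFrame(idcr_rows)
    reg = pd.DataFrame(reg_rows)

    analyses = {
        "physio_validation": physio_validation(idps),
        "novel_stimulus_validation": novel_stimulus_validation(pd.concat([idcr, table])),
        "primary_bias": primary_bias_test(table),
        "primary_bias_scr": primary_bias_test(table, outcome="scr"),
        "primary_bias_cemg": primary_bias_test(table, outcome="cemg"),
    }
    wil, boot = trigger_validation(table, seed=int(rng.integers(2**31)))
    analyses["trigger_validation"] = {
        "median_feedback": float(np.nanmedian(table["feedback_at_trigger"])),
        "signed_rank_p": float(wil.pvalue),
        "bootstrap_mean": boot.mean,
        "bootstrap_p": boot.p,
    }
    reg_val = reg[reg["dimension"] == "valence"]
    reg_aro = reg[reg["dimension"] == "arousal"]
    regulation = regulation_test(reg_val, reg_aro)
    analyses["regulation"] = {
        dim: {
            "cue_slope": regulation[dim]["fit"]["cue_c"].estimate,
            "comparison_p": regulation[dim]["comparison_p"],
            "lrt_p": regulation[dim]["fit"].lrt_p,
        }
        for dim in regulation
    }
    params = pd.DataFrame(
        {
            "subject_id": sorted(regulation["valence"]["subject_slopes"]),
            "val_slope": [regulation["valence"]["subject_slopes"][s]
                          for s in sorted(regulation["valence"]["subject_slopes"])],
            "val_intercept": [regulation["valence"]["subject_intercepts"][s]
                              for s in sorted(regulation["valence"]["subject_intercepts"])],
            "aro_slope": [regulation["arousal"]["subject_slopes"][s]
                          for s in sorted(regulation["arousal"]["subject_slopes"])],
            "aro_intercept": [regulation["arousal"]["subject_intercepts"][s]
                              for s in sorted(regulation["arousal"]["subject_intercepts"])],
        }
    )
    try:
        analyses["induction_predictor"] = induction_predictor_test(
            table, params, minimal=config.n_subjects < 25
        )
    except ValueError as exc:  # tiny cohorts cannot support subject-level designs
        analyses["induction_predictor"] = {"error": str(exc)}

    encodings = {}
    if config.n_perm >= 100:
        for dim in ("valence", "arousal"):
            data = encoding_data[dim]
            observed = group_mean_encoding(
                [
                    haufe_transform(
                        train_linear_classifier(LabeledVolumeSet(X, y)).weights, X
                    )
                    for X, y in data.values()
                ]
            )
            null = permutation_null(
                data, n_perm=config.n_perm, seed=int(rng.integers(2**31))
            )
            encodings[dim] = mask_by_permutation(observed, null, dimension=dim)

    result = {
        "catalog": catalog,
        "polar": polar,
        "assignment": assignment,
        "subjects": subjects,
        "trial_table": table,
        "idps_table": idps,
        "idcr_table": idcr,
        "regulation_table": reg,
        "regulation_params": params,
        "records": pd.DataFrame(records),
        "reliable_stimuli": reliable,
        "analyses": analyses,
        "encodings": encodings,
        "regulation_fits": regulation,
    }
    if outdir is not None:
        _write_artifacts(result, outdir)
    return result


def _write_artifacts(result: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alio.write_catalog(result["catalog"], outdir / "catalog.tsv")
    alio.write_table(result["trial_table"], outdir / "trial_table.tsv")
    alio.write_table(result["idps_table"], outdir / "idps_table.tsv")
    alio.write_table(result["idcr_table"], outdir / "idcr_table.tsv")
    alio.write_table(result["regulation_table"], outdir / "regulation_table.tsv")
    alio.write_table(result["regulation_params"], outdir / "regulation_params.tsv")
    alio.write_table(result["records"], outdir / "trigger_records.tsv")
    pd.DataFrame({"stim_id": result["reliable_stimuli"]}).to_csv(
        outdir / "reliable_stimuli.tsv", sep="\t", index=False
    )
    alio.write_fit_results(result["analyses"], outdir / "analyses.json")
    for dim, emap in result["encodings"].items():
        alio.write_encoding_map(emap, outdir / f"encoding_{dim}.h5")
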