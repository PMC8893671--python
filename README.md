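# affectloop

Closed-loop affect decoding on synthetic data: a tested re-implementation of
a real-time fMRI neurofeedback experiment in which subjects self-induce a
positive-valence brain state, decoded volume by volume, and stimulus
delivery is triggered the moment the decoded state satisfies a criterion.
Everything runs on synthetic volumetric time series with planted ground
truth, so decoding, triggering, and all downstream statistics can be
validated by parameter recovery.

## What's inside

| module | contents |
| --- | --- |
| `affectloop.synthetic` | stimulus catalogs (bimodal valence, "boomerang" arousal), subjects with planted voxel patterns, double-gamma HRF, trial schedules, volume-series simulation, latent self-induction process, trial-level psychophysiology |
| `affectloop.stimuli` | greedy farthest-point (max-span) sampling of the valence-arousal plane, extreme-valence polar subsets with iterative arousal matching, randomized Mod-PS/Mod-FS assignment |
| `affectloop.decoder` | HRF-derived volume labels, linear max-margin decoders, hyperplane distances, Platt scaling (implemented in-package), least-squares-all beta series, binomial accuracy tests, inter-subject reliability proxy |
| `affectloop.realtime` | online detrending, feedback transparency mapping, threshold hold/decay, consecutive-criterion trigger state machine with emergency default, full closed-loop Mod-FS trials |
| `affectloop.encoding` | Haufe-transform encoding maps, group means, within-subject label-permutation nulls, two-sided permutation masking, cross-map shared variance |
| `affectloop.surrogate` | volume-wise resting-state decoding and surrogate cued-recall trials (within-subject null controls) |
| `affectloop.bias` | mixed-effects battery (psychophysiology validation, novel-stimulus validation, trigger validation with bootstrap, primary carry-over bias model, regulation model + surrogate comparison, induction-predictor model) and planted-truth table generators for calibration/recovery studies |
| `affectloop.pipeline` | end-to-end cohort experiment wiring all of the above |

## CLI

```bash
# full synthetic experiment -> TSV/JSON artifacts
affectloop simulate --config config.yaml --seed 1 --out out/

# arousal-matched polar stimulus subsets from a catalog TSV
affectloop select-stimuli --catalog out/catalog.tsv --alpha 0.05 --seed 1

# train and serialize a decoder for one synthetic subject
affectloop train-decoder --dimension valence --seed 1 --out decoder.h5

# one closed-loop feedback-triggered trial with a stored decoder
affectloop run-loop --decoder decoder.h5 --seed 1 --out loop/

# refit any model family on previously written tables
affectloop analyze --tables out/ --model primary
```

`config.yaml` keys mirror `affectloop.pipeline.PipelineConfig`
(`n_subjects`, `n_voxels`, `noise_sd`, trial counts, `policy:` for the
trigger parameters, ...); all are optional.

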