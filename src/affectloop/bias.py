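"""Mixed-effects bias analyses and their simulation harnesses.

Implements the full battery of validation and hypothesis tests run on the
trial tables: psychophysiology validation, novel-stimulus decoding
validation, trigger-state validation (signed-rank + bootstrap), the primary
carry-over bias model, the cued-recall regulation model with its surrogate
comparison, and the induction-predictor model.  Companion ``simulate_*``
generators produce tables with known planted effects for parameter-recovery
and type-I calibration studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "FixedEffect",
    "FitResult",
    "BootstrapResult",
    "fit_mixed",
    "physio_validation",
    "novel_stimulus_validation",
    "trigger_validation",
    "primary_bias_test",
    "fit_regulation",
    "regulation_test",
    "induction_predictor_test",
    "simulate_bias_table",
    "simulate_physio_table",
    "simulate_regulation_table",
    "simulate_predictor_table",
]


@dataclass
class FixedEffect:
    estimate: float
    se: float
    t: float
    p: float

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.estimate - z * self.se, self.estimate + z * self.se


@dataclass
class FitResult:
    fixed_effects: dict[str, FixedEffect]
    random_effect_variances: dict[str, float]
    r2_adj: float
    loglik: float
    lrt_p: float | None = None
    n_obs: int = 0
    singular: bool = False
    diagnostic: str = ""
    extras: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> FixedEffect:
        return self.fixed_effects[name]

    def to_dict(self) -> dict:
        return {
            "fixed_effects": {
                k: {"estimate": fe.estimate, "se": fe.se, "t": fe.t, "p": fe.p}
                for k, fe in self.fixed_effects.items()
            },
            "random_effect_variances": self.random_effect_variances,
            "r2_adj": self.r2_adj,
            "loglik": self.loglik,
            "lrt_p": self.lrt_p,
            "n_obs": self.n_obs,
            "singular": self.singular,
            "diagnostic": self.diagnostic,
        }


@dataclass
class BootstrapResult:
    mean: float
    p: float
    n_boot: int
    n_subjects: int


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=0)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _center(x: pd.Series) -> pd.Series:
    return x - x.mean()


def _code_sex(x: pd.Series) -> pd.Series:
    # binary {0,1} (or already centered) -> +/- 0.5
    vals = x.astype(float)
    if set(np.unique(vals)) <= {0.0, 1.0}:
        return vals - 0.5
    return vals


def fit_mixed(
    formula: str,
    data: pd.DataFrame,
    groups: str,
    re_formula: str | None = None,
) -> FitResult:
    """Linear mixed model by maximum likelihood.

    Reports Wald t-tests (residual-df approximation) per fixed effect, a
    marginal adjusted R^2 computed from fixed-effect predictions, and a
    likelihood-ratio test of the random effects against a fixed-effects-only
    OLS fit.  A near-zero random-effect variance is flagged as singular
    rather than dropped.
    """
    if data[groups].nunique() < 2:
        raise ValueError("grouping variable must have at least 2 levels")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data[groups], re_formula=re_formula)
        if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
            raise ValueError(_rank_message(model.exog, list(model.exog_names)))
        try:
            res = model.fit(reml=False, maxiter=200)
        except Exception:
            res = model.fit(reml=False, method="powell", maxiter=500)
        if not res.converged or not np.isfinite(res.llf):
            # degenerate (often zero-variance) fits can crash some optimizers;
            # keep the first result if the retry fails
            try:
                retry = model.fit(reml=False, method="powell", maxiter=1000)
                if retry.converged and np.isfinite(retry.llf):
                    res = retry
            except np.linalg.LinAlgError:
                pass

        ols = smf.ols(formula, data).fit()
        try:
            bse_fe = res.bse_fe
        except np.linalg.LinAlgError:
            bse_fe = pd.Series(np.nan, index=res.fe_params.index)

    fe = {}
    n = len(res.model.endog)
    p_fixed = len(res.fe_params)
    df_resid = max(n - p_fixed, 1)
    for name, est in res.fe_params.items():
        se = float(bse_fe[name])
        if np.isfinite(se) and se > 0:
            t = est / se
            p = 2 * stats.t.sf(abs(t), df_resid)
        else:
            t, p = np.nan, np.nan
        fe[name] = FixedEffect(estimate=float(est), se=se, t=float(t), p=float(p))

    yhat = res.model.exog @ res.fe_params.to_numpy()
    y = res.model.endog
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2_adj = 1 - (1 - r2) * (n - 1) / max(n - p_fixed - 1, 1)

    ranef_var = {
        name: float(res.cov_re.loc[name, name]) for name in res.cov_re.index
    }
    singular = any(v < 1e-8 for v in ranef_var.values())

    k_var = res.cov_re.shape[0] * (res.cov_re.shape[0] + 1) // 2
    if k_var > 0 and np.isfinite(res.llf):
        lr = 2 * (res.llf - ols.llf)
        lrt_p = float(stats.chi2.sf(max(lr, 0.0), k_var))
    else:
        lrt_p = None

    return FitResult(
        fixed_effects=fe,
        random_effect_variances=ranef_var,
        r2_adj=float(r2_adj),
        loglik=float(res.llf),
        lrt_p=lrt_p,
        n_obs=n,
        singular=singular,
        diagnostic="singular random-effect covariance (variance ~ 0)" if singular else "",
        extras={"result": res},
    )


def _rank_message(exog: np.ndarray, names: list[str]) -> str:
    # identify aliased columns via pivoted QR
    _, r = np.linalg.qr(exog)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(exog.shape) * np.finfo(float).eps
    aliased = [names[i] for i in range(len(diag)) if diag[i] < tol]
    return f"design is rank deficient; aliased terms: {aliased or names}"


# ---------------------------------------------------------------------------
# Validation models
# ---------------------------------------------------------------------------


def _prep_covariates(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["age_z"] = _zscore(out["age"])
    out["sex_c"] = _code_sex(out["sex"])
    return out


def physio_validation(table: pd.DataFrame) -> dict[str, FitResult]:
    """GLMMs linking normative scores to psychophysiological responses.

    Id-PS rows only.  Matched models: normative valence ~ cEMG and normative
    arousal ~ SCR; crossed (selectivity) models swap the outcome.  All
    control age and sex, with subject-wise random slope and intercept.
    """
    idps = table[table["trial_type"] == "Id-PS"]
    if idps.empty:
        raise ValueError("no Id-PS rows with physiology present")
    rows = _prep_covariates(idps)
    rows["norm_valence_z"] = _zscore(rows["norm_valence"])
    rows["norm_arousal_z"] = _zscore(rows["norm_arousal"])
    rows["cemg_z"] = _zscore(rows["cemg"])
    rows["scr_z"] = _zscore(rows["scr"])
    out = {}
    specs = {
        "valence_cemg": ("norm_valence_z ~ cemg_z + age_z + sex_c", "~cemg_z"),
        "arousal_scr": ("norm_arousal_z ~ scr_z + age_z + sex_c", "~scr_z"),
        "arousal_cemg": ("norm_arousal_z ~ cemg_z + age_z + sex_c", "~cemg_z"),
        "valence_scr": ("norm_valence_z ~ scr_z + age_z + sex_c", "~scr_z"),
    }
    for name, (formula, re_formula) in specs.items():
        out[name] = fit_mixed(formula, rows, "subject_id", re_formula)
    return out


def novel_stimulus_validation(table: pd.DataFrame) -> dict[str, FitResult]:
    """Generalization of the decoders to novel stimuli (Id-CR, Mod-PS).

    Id-CR: normative score ~ same-dimension decoded affect; Mod-PS: adds the
    complementary-dimension decoding as a control.  Age and sex controlled,
    random effects subject-wise.
    """
    out = {}
    idcr = _prep_covariates(table[table["trial_type"] == "Id-CR"])
    if not idcr.empty:
        idcr["norm_valence_z"] = _zscore(idcr["norm_valence"])
        idcr["norm_arousal_z"] = _zscore(idcr["norm_arousal"])
        idcr["dv_z"] = _zscore(idcr["decoded_valence"])
        idcr["da_z"] = _zscore(idcr["decoded_arousal"])
        out["idcr_valence"] = fit_mixed(
            "norm_valence_z ~ dv_z + age_z + sex_c", idcr, "subject_id", "~dv_z"
        )
        out["idcr_arousal"] = fit_mixed(
            "norm_arousal_z ~ da_z + age_z + sex_c", idcr, "subject_id", "~da_z"
        )
    modps = _prep_covariates(table[table["trial_type"] == "Mod-PS"])
    if not modps.empty:
        modps["norm_valence_z"] = _zscore(modps["norm_valence"])
        modps["norm_arousal_z"] = _zscore(modps["norm_arousal"])
        modps["dv_z"] = _zscore(modps["decoded_valence"])
        modps["da_z"] = _zscore(modps["decoded_arousal"])
        out["modps_valence"] = fit_mixed(
            "norm_valence_z ~ dv_z + da_z + age_z + sex_c", modps, "subject_id", "~dv_z"
        )
        out["modps_arousal"] = fit_mixed(
            "norm_arousal_z ~ da_z + dv_z + age_z + sex_c", modps, "subject_id", "~da_z"
        )
    if not out:
        raise ValueError("no Id-CR or Mod-PS rows present")
    return out


def trigger_validation(
    table: pd.DataFrame,
    feedback_at_trigger: pd.Series | None = None,
    n_eval: int = 90,
    alpha: float = 0.05,
    n_boot: int = 10000,
    seed: int = 0,
):
    """Trigger-state validation.

    (a) signed-rank test that the median feedback at trigger exceeds 0;
    (b) one-sided bootstrap (within-subject resampling before pooling) of
    the trigger-volume decoded valence, restricted to subjects whose
    decoding accuracy is significantly above chance, testing mean > 0.5.
    """
    fs = table[table["trial_type"] == "Mod-FS"]
    if fs.empty:
        raise ValueError("no Mod-FS rows present")
    if feedback_at_trigger is None:
        feedback_at_trigger = fs["feedback_at_trigger"]
    wil = stats.wilcoxon(np.asarray(feedback_at_trigger, dtype=float), alternative="greater")

    qualifying = []
    for sid, grp in fs.groupby("subject_id"):
        acc = float(grp["decoder_accuracy"].iloc[0])
        k = int(round(acc * n_eval))
        if stats.binomtest(k, n_eval, 0.5, alternative="greater").pvalue < alpha:
            qualifying.append(sid)
    if not qualifying:
        raise ValueError("no subjects with significant within-subject decoding")

    rng = np.random.default_rng(seed)
    by_subject = [
        fs.loc[fs["subject_id"] == sid, "prev_decoded_valence"].to_numpy(dtype=float)
        for sid in qualifying
    ]
    boot_means = np.empty(n_boot)
    for b in range(n_boot):
        pooled = np.concatenate(
            [vals[rng.integers(0, vals.size, vals.size)] for vals in by_subject]
        )
        boot_means[b] = pooled.mean()
    observed = float(np.concatenate(by_subject).mean())
    p = float(np.mean(boot_means <= 0.5))
    return wil, BootstrapResult(mean=observed, p=p, n_boot=n_boot, n_subjects=len(qualifying))


# ---------------------------------------------------------------------------
# Primary bias model
# ---------------------------------------------------------------------------


def primary_bias_test(table: pd.DataFrame, outcome: str = "decoded_valence") -> FitResult:
    """Carry-over bias of self-induced positive valence on subsequent stimuli.

    outcome ~ trial_type (Mod-FS = 1) + normative valence + decoded arousal
    + age + sex + decoder accuracy + previous-volume decoded valence +
    trial_type x normative valence + trial_type x previous decoded valence,
    subject-wise random intercepts.  Continuous covariates are z-scored; the
    previous-volume decoding is grand-mean centered (outcome scale) so the
    trial-type coefficient reads as the average treatment effect.  The same
    structure is reusable with ``scr``/``cemg`` outcomes.
    """
    rows = table[table["trial_type"].isin(["Mod-FS", "Mod-PS"])].copy()
    if rows["trial_type"].nunique() < 2:
        raise ValueError("both Mod-FS and Mod-PS rows are required")
    rows = _prep_covariates(rows)
    rows["induce"] = (rows["trial_type"] == "Mod-FS").astype(float)
    rows["nv_z"] = _zscore(rows["norm_valence"])
    rows["da_z"] = _zscore(rows["decoded_arousal"])
    rows["acc_z"] = _zscore(rows["decoder_accuracy"])
    rows["prev_c"] = _center(rows["prev_decoded_valence"])
    rows["y"] = rows[outcome]
    formula = (
        "y ~ induce + nv_z + da_z + age_z + sex_c + acc_z + prev_c"
        " + induce:nv_z + induce:prev_c"
    )
    return fit_mixed(formula, rows, "subject_id", re_formula=None)


# ---------------------------------------------------------------------------
# Regulation model and surrogate comparison
# ---------------------------------------------------------------------------


def fit_regulation(table: pd.DataFrame, trial_type: str = "Id-CR"):
    """Recall decoding ~ cue decoding for one trial type and one dimension.

    ``table`` is long over recall volumes with columns subject_id,
    trial_type, cue, recall, recall_lag, age, sex.  Random slope and
    intercept subject-wise; returns the fit plus per-subject slopes
    (fixed + BLUP).
    """
    rows = _prep_covariates(table[table["trial_type"] == trial_type]).copy()
    if rows.empty:
        raise ValueError(f"no {trial_type} rows present")
    rows["cue_c"] = _center(rows["cue"])
    rows["lag_c"] = rows["recall_lag"] - rows["recall_lag"].mean()
    fit = fit_mixed(
        "recall ~ cue_c + lag_c + age_z + sex_c", rows, "subject_id", re_formula="~cue_c"
    )
    res = fit.extras["result"]
    base = fit["cue_c"].estimate
    slopes = {}
    intercepts = {}
    for sid, re_vals in res.random_effects.items():
        slopes[sid] = base + float(re_vals.get("cue_c", 0.0))
        intercepts[sid] = fit["Intercept"].estimate + float(
            re_vals.get("Group", re_vals.iloc[0])
        )
    return fit, slopes, intercepts


def regulation_test(valence_table: pd.DataFrame, arousal_table: pd.DataFrame) -> dict:
    """Cued-recall regulation models with surrogate (resting) comparison.

    For each affect dimension: fit the recall ~ cue model on Id-CR rows and
    on surrogate rows, then compare per-subject slopes with a paired
    one-sided signed-rank test (regulation > surrogate).
    """
    out = {}
    for dim, table in (("valence", valence_table), ("arousal", arousal_table)):
        fit_task, slopes_task, icepts_task = fit_regulation(table, "Id-CR")
        fit_surr, slopes_surr, _ = fit_regulation(table, "surrogate")
        common = sorted(set(slopes_task) & set(slopes_surr))
        diffs = np.array([slopes_task[s] - slopes_surr[s] for s in common])
        if np.allclose(diffs, 0):
            comparison_p = 1.0
        else:
            comparison_p = float(stats.wilcoxon(diffs, alternative="greater").pvalue)
        out[dim] = {
            "fit": fit_task,
            "surrogate_fit": fit_surr,
            "subject_slopes": slopes_task,
            "subject_intercepts": icepts_task,
            "surrogate_slopes": slopes_surr,
            "comparison_p": comparison_p,
        }
    return out


# ---------------------------------------------------------------------------
# Induction predictor model
# ---------------------------------------------------------------------------


def induction_predictor_test(
    table: pd.DataFrame, regulation_params: pd.DataFrame, minimal: bool = False
) -> FitResult:
    """Does unguided regulation ability predict guided self-induction?

    Outcome: decoded valence of the final self-induce volume of Mod-FS
    trials.  Predictors: per-subject regulation slopes/intercepts for both
    affect dimensions, age, sex, decoding accuracy; all slope x intercept
    2-way interactions plus valence slope/intercept x {age, sex, accuracy}.
    Subject-wise random intercepts.  Rank deficiency raises an error naming
    the aliased terms.  ``minimal=True`` keeps only the regulation main
    effects plus accuracy (for cohorts too small to support all
    interactions, whose subject-level design would otherwise be singular).
    """
    fs = table[table["trial_type"] == "Mod-FS"].copy()
    if fs.empty:
        raise ValueError("no Mod-FS rows present")
    rows = fs.merge(regulation_params, on="subject_id", how="inner")
    if rows.empty:
        raise ValueError("no subjects with regulation parameters")
    rows = _prep_covariates(rows)
    for col in ("val_slope", "val_intercept", "aro_slope", "aro_intercept"):
        rows[col + "_z"] = _zscore(rows[col])
    rows["acc_z"] = _zscore(rows["decoder_accuracy"])
    rows["y"] = rows["prev_decoded_valence"]
    main = ["val_slope_z", "val_intercept_z", "aro_slope_z", "aro_intercept_z"]
    if minimal:
        formula = "y ~ " + " + ".join(main + ["acc_z"])
        return fit_mixed(formula, rows, "subject_id", re_formula=None)
    pairs = [
        f"{a}:{b}"
        for i, a in enumerate(main)
        for b in main[i + 1 :]
    ]
    val_x = [
        f"{term}:{cov}"
        for term in ("val_slope_z", "val_intercept_z")
        for cov in ("age_z", "sex_c", "acc_z")
    ]
    formula = "y ~ " + " + ".join(main + ["age_z", "sex_c", "acc_z"] + pairs + val_x)
    return fit_mixed(formula, rows, "subject_id", re_formula=None)


# ---------------------------------------------------------------------------
# Simulation harnesses (planted-truth generators)
# ---------------------------------------------------------------------------


def _subject_frame(n_subjects: int, rng: np.random.Generator) -> pd.DataFrame:
    sex = rng.permutation(np.arange(n_subjects) % 2)  # balanced by construction
    return pd.DataFrame(
        {
            "subject_id": [f"s{j:03d}" for j in range(n_subjects)],
            "age": rng.normal(38.8, 13.3, n_subjects).clip(20, 65),
            "sex": sex,
        }
    )


def simulate_bias_table(
    n_subjects: int = 40,
    n_ps: int = 40,
    n_fs: int = 20,
    delta: float = 0.033,
    beta_norm_valence: float = 0.031,
    beta_prev: float = 0.803,
    residual_sd: float = 0.08,
    intercept_sd: float = 0.02,
    prev_sd: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Modulation-task trial table with a planted carry-over bias ``delta``.

    The self-induced state elevates the previous-volume decoded valence and
    adds ``delta`` to the decoded valence of the next stimulus.  Variance
    components default to values giving fits on the R^2_adj ~ 0.68 scale.
    """
    rng = np.random.default_rng(seed)
    subjects = _subject_frame(n_subjects, rng)
    rows = []
    for _, subj in subjects.iterrows():
        u = rng.normal(0, intercept_sd)
        accuracy = float(np.clip(rng.normal(0.79, 0.08), 0.5, 0.99))
        kinds = ["Mod-PS"] * n_ps + ["Mod-FS"] * n_fs
        rng.shuffle(kinds)
        for kind in kinds:
            positive = rng.random() < 0.5
            nv = rng.normal(7.4, 0.3) if positive else rng.normal(2.05, 0.4)
            na = rng.normal(5.7, 0.55)
            induce = 1.0 if kind == "Mod-FS" else 0.0
            prev = np.clip(
                rng.normal(0.65 if induce else 0.50, prev_sd), 0.01, 0.99
            )
            nv_z = (nv - 4.7) / 2.7  # approximate population standardization
            dv = (
                0.5
                + delta * induce
                + beta_norm_valence * nv_z
                + beta_prev * (prev - 0.575)
                + u
                + rng.normal(0, residual_sd)
            )
            rows.append(
                {
                    "subject_id": subj["subject_id"],
                    "trial_type": kind,
                    "decoded_valence": float(np.clip(dv, 0.0, 1.0)),
                    "decoded_arousal": float(np.clip(rng.normal(0.5, 0.1), 0, 1)),
                    "prev_decoded_valence": float(prev),
                    "norm_valence": float(nv),
                    "norm_arousal": float(na),
                    "cemg": rng.normal(0, 1),
                    "scr": rng.normal(0, 1),
                    "age": subj["age"],
                    "sex": subj["sex"],
                    "decoder_accuracy": accuracy,
                }
            )
    return pd.DataFrame(rows)


def simulate_physio_table(
    n_subjects: int = 40,
    n_trials: int = 90,
    beta_cemg: float = 0.11,
    beta_scr: float = 0.07,
    slope_sd: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Id-PS physiology table with planted standardized effects.

    Responses are built so that the standardized GLMM slope of normative
    score on the physiological measure equals the planted beta: the measure
    carries the z-scored score at correlation ``beta`` with unit total
    variance.
    """
    rng = np.random.default_rng(seed)
    subjects = _subject_frame(n_subjects, rng)
    rows = []
    for _, subj in subjects.iterrows():
        b_c = beta_cemg + rng.normal(0, slope_sd)
        b_s = beta_scr + rng.normal(0, slope_sd)
        v = np.clip(
            np.where(
                rng.random(n_trials) < 0.5,
                rng.normal(3.0, 1.3, n_trials),
                rng.normal(7.0, 1.3, n_trials),
            ),
            1,
            9,
        )
        a = np.clip(2.9 + 0.8 * np.abs(v - 5) + rng.normal(0, 0.9, n_trials), 1, 9)
        v_z = (v - v.mean()) / v.std()
        a_z = (a - a.mean()) / a.std()
        cemg = b_c * v_z + np.sqrt(max(1 - b_c**2, 0.1)) * rng.normal(size=n_trials)
        scr = b_s * a_z + np.sqrt(max(1 - b_s**2, 0.1)) * rng.normal(size=n_trials)
        for i in range(n_trials):
            rows.append(
                {
                    "subject_id": subj["subject_id"],
                    "trial_type": "Id-PS",
                    "norm_valence": float(v[i]),
                    "norm_arousal": float(a[i]),
                    "cemg": float(cemg[i]),
                    "scr": float(scr[i]),
                    "age": subj["age"],
                    "sex": subj["sex"],
                }
            )
    return pd.DataFrame(rows)


def simulate_regulation_table(
    n_subjects: int = 40,
    n_trials: int = 30,
    transfer: float = 0.33,
    surrogate_transfer: float = 0.0,
    lag_effect: float = 0.01,
    slope_sd: float = 0.10,
    residual_sd: float = 0.12,
    cue_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format recall table (Id-CR + surrogate rows, 4 lags per trial)."""
    rng = np.random.default_rng(seed)
    subjects = _subject_frame(n_subjects, rng)
    rows = []
    for _, subj in subjects.iterrows():
        for kind, base in (("Id-CR", transfer), ("surrogate", surrogate_transfer)):
            slope_j = base + rng.normal(0, slope_sd)
            icept_j = 0.5 + rng.normal(0, 0.03)
            for _trial in range(n_trials):
                cue = float(np.clip(rng.normal(0.5, cue_sd), 0.01, 0.99))
                for lag in range(1, 5):
                    recall = (
                        icept_j
                        + slope_j * (cue - 0.5)
                        + lag_effect * lag
                        + rng.normal(0, residual_sd)
                    )
                    rows.append(
                        {
                            "subject_id": subj["subject_id"],
                            "trial_type": kind,
                            "cue": cue,
                            "recall": float(np.clip(recall, 0.0, 1.0)),
                            "recall_lag": lag,
                            "age": subj["age"],
                            "sex": subj["sex"],
                        }
                    )
    return pd.DataFrame(rows)


def simulate_predictor_table(
    n_subjects: int = 40,
    n_fs: int = 20,
    coupling: float = 0.85,
    residual_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mod-FS table + regulation parameters with an arousal-slope coupling.

    The subject's (standardized) arousal regulation slope drives the decoded
    valence reached at the end of self-induction with weight ``coupling``.
    """
    rng = np.random.default_rng(seed)
    subjects = _subject_frame(n_subjects, rng)
    params, rows = [], []
    for _, subj in subjects.iterrows():
        vs, vi = rng.normal(0.33, 0.1), rng.normal(0.5, 0.05)
        a_slope_z = rng.normal(0, 1)
        as_, ai = 0.33 + 0.1 * a_slope_z, rng.normal(0.5, 0.05)
        accuracy = float(np.clip(rng.normal(0.79, 0.08), 0.5, 0.99))
        params.append(
            {
                "subject_id": subj["subject_id"],
                "val_slope": vs,
                "val_intercept": vi,
                "aro_slope": as_,
                "aro_intercept": ai,
            }
        )
        level = 0.5 + coupling * 0.1 * a_slope_z
        for _t in range(n_fs):
            rows.append(
                {
                    "subject_id": subj["subject_id"],
                    "trial_type": "Mod-FS",
                    "prev_decoded_valence": float(
                        np.clip(level + rng.normal(0, residual_sd), 0, 1)
                    ),
                    "decoded_valence": 0.5,
                    "decoded_arousal": 0.5,
                    "norm_valence": 5.0,
                    "norm_arousal": 5.0,
                    "age": subj["age"],
                    "sex": subj["sex"],
                    "decoder_accuracy": accuracy,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(params)
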