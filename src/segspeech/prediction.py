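"""Linking neonatal ERP features to 18-month expressive vocabulary.

Features per subject: L_flat and L_melody (block 2 − block 1 learning
dynamics, 200–500 ms, averaged over all scalp channels) and TW1_melody /
TW2_melody (illegal − legal mismatch amplitudes in the 300–400 and 800–900 ms
windows of the melodic test phase, all-channel mean). The outcome is the raw
MCDI expressive-vocabulary count (BSID-III language score carried alongside).

The evaluation layer implements leave-two-subjects-out cross-validation
(every unordered subject pair held out once: C(n,2) folds, n(n−1)
predictions) and a permutation test that reruns the entire cross-validation
on outcome-shuffled data, which respects the non-independence of the
predicted scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _sps

from .stats import fdr_bh

FEATURES = ("L_flat", "L_melody", "TW1_melody", "TW2_melody")
FINAL_MODEL_FEATURES = ("L_melody", "TW2_melody")

LEARNING_WINDOW = (200.0, 500.0)
TW1_WINDOW = (300.0, 400.0)
TW2_WINDOW = (800.0, 900.0)


class PredictionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_features(learning_amplitudes: pd.DataFrame,
                     test_amplitudes: pd.DataFrame,
                     outcomes: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per subject with the four ERP predictors (all-channel means).

    `learning_amplitudes`: tidy table with cells "1"/"2" (blocks) per
    condition; `test_amplitudes`: cells "legal"/"illegal" per condition and
    window. `outcomes` (subject, mcdi, bsid_lang) is merged when given.
    """
    ldf = learning_amplitudes.copy()
    ldf["cell"] = ldf["cell"].astype(str)
    lmeans = (ldf.groupby(["subject", "condition", "cell"], sort=False)
              ["amplitude_uv"].mean().unstack("cell"))
    if not {"1", "2"}.issubset(lmeans.columns):
        raise PredictionError("learning table must contain blocks 1 and 2")
    ldyn = (lmeans["2"] - lmeans["1"]).unstack("condition")
    for cond in ("flat", "melodic"):
        if cond not in ldyn.columns:
            raise PredictionError(f"missing learning condition {cond!r}")

    tdf = test_amplitudes
    tdf = tdf.loc[tdf["condition"] == "melodic"]
    tmeans = (tdf.groupby(["subject", "win_lo_ms", "cell"], sort=False)
              ["amplitude_uv"].mean().unstack("cell"))
    if not {"legal", "illegal"}.issubset(tmeans.columns):
        raise PredictionError("test table must contain legal and illegal cells")
    diff = (tmeans["illegal"] - tmeans["legal"]).unstack("win_lo_ms")
    for w in (TW1_WINDOW[0], TW2_WINDOW[0]):
        if w not in diff.columns:
            raise PredictionError(f"missing test window starting at {w} ms")

    feats = pd.DataFrame({
        "L_flat": ldyn["flat"], "L_melody": ldyn["melodic"],
        "TW1_melody": diff[TW1_WINDOW[0]], "TW2_melody": diff[TW2_WINDOW[0]],
    })
    if feats.isna().any().any():
        missing = feats[feats.isna().any(axis=1)].index.tolist()
        raise PredictionError(f"subjects missing a phase: {missing}")
    feats = feats.reset_index()
    if outcomes is not None:
        feats = feats.merge(outcomes, on="subject", how="left")
    return feats


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def correlate(features: pd.DataFrame, outcome: str = "mcdi",
              predictors: Sequence[str] = FEATURES) -> pd.DataFrame:
    """Pearson correlation of each predictor with the outcome, BH-FDR over the
    family; the fixed per-test threshold α/n (0.0125 at n=4) is also reported
    since both conventions appear in the field."""
    y = features[outcome].to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise PredictionError("need at least 3 subjects")
    rows = []
    for f in predictors:
        x = features[f].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise PredictionError(f"zero variance in {f!r} or {outcome!r}")
        r, p = _sps.pearsonr(x, y)
        rows.append({"predictor": f, "outcome": outcome, "r": float(r),
                     "df": n - 2, "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_bh(out["p"].to_numpy())
    out["bonferroni_threshold"] = 0.05 / len(predictors)
    return out


# ---------------------------------------------------------------------------
# Backward multiple regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    predictors: tuple[str, ...]
    coef: pd.DataFrame  # term, B, SE, beta, t, p
    r_squared: float
    f: float
    df_num: int
    df_den: int
    p_model: float


def _fit_ols(features: pd.DataFrame, outcome: str,
             predictors: Sequence[str]) -> RegressionFit:
    y = features[outcome].to_numpy(dtype=float)
    x = features[list(predictors)].to_numpy(dtype=float)
    design = sm.add_constant(x) if len(predictors) else np.ones((len(y), 1))
    if np.linalg.cond(design) > 1e8:
        raise PredictionError("collinear predictors (ill-conditioned design)")
    fit = sm.OLS(y, design).fit()
    sy = y.std(ddof=1)
    rows = [{"term": "(Constant)", "B": fit.params[0], "SE": fit.bse[0],
             "beta": np.nan, "t": fit.tvalues[0], "p": fit.pvalues[0]}]
    for j, name in enumerate(predictors, start=1):
        sx = features[name].std(ddof=1)
        rows.append({"term": name, "B": fit.params[j], "SE": fit.bse[j],
                     "beta": fit.params[j] * sx / sy,
                     "t": fit.tvalues[j], "p": fit.pvalues[j]})
    k = len(predictors)
    return RegressionFit(
        predictors=tuple(predictors), coef=pd.DataFrame(rows),
        r_squared=float(fit.rsquared) if k else 0.0,
        f=float(fit.fvalue) if k else np.nan,
        df_num=k, df_den=len(y) - k - 1,
        p_model=float(fit.f_pvalue) if k else np.nan)


def backward_regression(features: pd.DataFrame, outcome: str = "mcdi",
                        predictors: Sequence[str] = FEATURES,
                        p_out: float = 0.10) -> list[RegressionFit]:
    """Backward elimination: start from the full model and iteratively drop
    the predictor with the largest p ≥ `p_out`, refitting each time. Returns
    every intermediate fit; the last entry is the final model."""
    current = list(predictors)
    if len(features) <= len(current) + 1:
        raise PredictionError("too few subjects for the full model")
    fits = [_fit_ols(features, outcome, current)]
    while current:
        coef = fits[-1].coef
        terms = coef.loc[coef["term"] != "(Constant)"]
        worst = terms.loc[terms["p"].idxmax()]
        if worst["p"] < p_out:
            break
        current.remove(worst["term"])
        fits.append(_fit_ols(features, outcome, current))
    return fits


# ---------------------------------------------------------------------------
# Leave-two-subjects-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVEvaluation:
    predictions: pd.DataFrame  # fold, subject, y_true, y_pred
    r_squared: float
    mae: float
    n_folds: int
    p_r2: float | None = None
    p_mae: float | None = None
    n_permutations: int = 0
    null_r2: np.ndarray | None = None
    null_mae: np.ndarray | None = None


def _fold_designs(x: np.ndarray):
    """Precompute, per unordered pair of subjects, the training pseudo-inverse
    and the held-out design rows (with intercept)."""
    n = x.shape[0]
    design = np.column_stack([np.ones(n), x])
    folds = list(itertools.combinations(range(n), 2))
    pinvs, tests, train_idx = [], [], []
    for pair in folds:
        tr = np.array([i for i in range(n) if i not in pair])
        xtr = design[tr]
        if np.linalg.matrix_rank(xtr) < design.shape[1]:
            raise PredictionError(f"degenerate design matrix in fold {pair}")
        pinvs.append(np.linalg.pinv(xtr))
        tests.append(design[list(pair)])
        train_idx.append(tr)
    return folds, np.array(pinvs), np.array(tests), np.array(train_idx)


def ltso_cv(features: pd.DataFrame, outcome: str = "mcdi",
            predictor_subset: Sequence[str] = FINAL_MODEL_FEATURES
            ) -> CVEvaluation:
    """Leave-two-subjects-out CV with a fixed predictor subset.

    Every unordered pair of subjects is held out once; an OLS model is fitted
    on the remaining n−2 and predicts both held-out subjects: C(n,2) folds and
    n(n−1) predictions in total.
    """
    n = len(features)
    if n < 4:
        raise PredictionError("need at least 4 subjects")
    x = features[list(predictor_subset)].to_numpy(dtype=float)
    y = features[outcome].to_numpy(dtype=float)
    subjects = features["subject"].to_numpy() if "subject" in features else \
        np.arange(n).astype(str)
    folds, pinvs, tests, train_idx = _fold_designs(x)
    rows = []
    for f, (pair, pinv, xt, tr) in enumerate(zip(folds, pinvs, tests, train_idx)):
        coef = pinv @ y[tr]
        pred = xt @ coef
        for subj_i, yhat in zip(pair, pred):
            rows.append({"fold": f, "subject": subjects[subj_i],
                         "y_true": y[subj_i], "y_pred": float(yhat)})
    preds = pd.DataFrame(rows)
    r2, mae = evaluate_predictions(preds["y_pred"].to_numpy(),
                                   preds["y_true"].to_numpy())
    return CVEvaluation(predictions=preds, r_squared=r2, mae=mae,
                        n_folds=len(folds))


def evaluate_predictions(predictions: np.ndarray, truth: np.ndarray
                         ) -> tuple[float, float]:
    """Similarity of out-of-sample predictions to the true scores: R² of the
    linear regression of truth on predictions, and mean absolute error."""
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.shape != truth.shape:
        raise PredictionError("prediction/truth length mismatch")
    mae = float(np.mean(np.abs(predictions - truth)))
    if np.std(predictions) == 0 or np.std(truth) == 0:
        return 0.0, mae  # constant predictions: regression undefined
    r, _ = _sps.pearsonr(predictions, truth)
    return float(r ** 2), mae


def permutation_test(features: pd.DataFrame, outcome: str = "mcdi",
                     predictor_subset: Sequence[str] = FINAL_MODEL_FEATURES,
                     n_permutations: int = 5000,
                     seed: int | None = 0) -> CVEvaluation:
    """Permutation-null significance of the cross-validated evaluation.

    Each permutation shuffles the outcome vector across subjects and reruns
    the full leave-two-out CV. Empirical p-values use the +1 correction:
    p = (1 + #{null ≥ observed}) / (n_permutations + 1) for R² and the ≤
    analogue for MAE.
    """
    if n_permutations < 100:
        raise PredictionError("use at least 100 permutations")
    base = ltso_cv(features, outcome, predictor_subset)
    x = features[list(predictor_subset)].to_numpy(dtype=float)
    y = features[outcome].to_numpy(dtype=float)
    folds, pinvs, tests, train_idx = _fold_designs(x)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(len(y)) for _ in range(n_permutations)])
    yp = y[perms]  # n_perm × n
    # Gather training outcomes per fold: (n_perm, n_folds, n-2).
    ytr = yp[:, train_idx]
    coefs = np.einsum("fkm,pfm->pfk", pinvs, ytr)
    preds = np.einsum("fjk,pfk->pfj", tests, coefs)  # n_perm × folds × 2
    pair_idx = np.array(folds)  # folds × 2
    truth = yp[:, pair_idx]  # n_perm × folds × 2
    flat_pred = preds.reshape(n_permutations, -1)
    flat_true = truth.reshape(n_permutations, -1)
    null_mae = np.abs(flat_pred - flat_true).mean(axis=1)
    pc = flat_pred - flat_pred.mean(axis=1, keepdims=True)
    tc = flat_true - flat_true.mean(axis=1, keepdims=True)
    denom = np.sqrt((pc ** 2).sum(axis=1) * (tc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        null_r2 = np.where(denom > 0, ((pc * tc).sum(axis=1) / denom) ** 2, 0.0)
    p_r2 = (1 + int((null_r2 >= base.r_squared).sum())) / (n_permutations + 1)
    p_mae = (1 + int((null_mae <= base.mae).sum())) / (n_permutations + 1)
    base.p_r2, base.p_mae = float(p_r2), float(p_mae)
    base.n_permutations = n_permutations
    base.null_r2, base.null_mae = null_r2, null_mae
    return base
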