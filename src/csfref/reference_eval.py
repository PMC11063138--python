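"""Biomarker models, reference adjustment, AUC machinery and selection.

Three logistic models carry the evaluation: P-tau181 predicting tau-PET
positivity, Abeta42 predicting amyloid-PET positivity (the two search
models), and P-tau181 predicting conversion to AD dementia (validation
only).  A reference enters as a covariate:

    outcome ~ main_predictor + reference + age + sex

Performance is the ROC AUC under 10-fold cross-validation, a train/test
holdout, or out-of-bag bootstrap resampling; AUCs are compared with a
one-sided bootstrap ROC test and Benjamini-Hochberg adjusted within a grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold
from statsmodels.stats.multitest import multipletests

from csfref._logistic import fit_logistic, predict_proba
from csfref.cohort_io import CohortTable

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """One biomarker model: predictor, outcome, covariates, reference."""

    name: str
    main_predictor: str
    outcome: str
    covariates: tuple[str, ...] = ("age", "sex")
    reference: str = "none"  # none | mean_level | protein:<id> | svd:<id,...>

    def with_reference(self, reference: str) -> "ModelSpec":
        return replace(self, reference=reference)


#: The two reference-search models and the validation-only model.
SEARCH_MODELS = (
    ModelSpec("ptau_taupet", "ptau181", "tau_pet_pos"),
    ModelSpec("abeta_abpet", "abeta42", "abeta_pet_pos"),
)
VALIDATION_MODEL = ModelSpec("ptau_addconv", "ptau181", "add_conversion")


@dataclass
class ReferenceEvalResult:
    """Grid of (model x reference) AUCs with comparison p-values."""

    table: pd.DataFrame
    scheme: str


# ---------------------------------------------------------------------------
# AUC


def auc(scores, labels) -> float:
    """ROC AUC via the rank (Mann-Whitney) formulation; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    r = rankdata(scores)
    u = r[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _auc_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise AUC for matrices of resampled scores/labels (NaN if a row
    lacks a class)."""
    r = rankdata(scores, axis=1)
    pos = labels == 1
    n_pos = pos.sum(axis=1)
    n_neg = labels.shape[1] - n_pos
    u = (r * pos).sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = u / (n_pos * n_neg)
    out[(n_pos == 0) | (n_neg == 0)] = np.nan
    return out


# ---------------------------------------------------------------------------
# Design assembly


def _zscore_cols(train: np.ndarray, other: np.ndarray | None = None):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    if other is None:
        return (train - mu) / sd
    return (train - mu) / sd, (other - mu) / sd


def _model_frame(
    spec: ModelSpec,
    cohort: CohortTable,
    reference_values: pd.Series | None,
) -> pd.DataFrame:
    """Listwise-complete frame of outcome, predictor, reference, covariates."""
    cols = {
        "outcome": cohort.df[spec.outcome],
        "predictor": cohort.df[spec.main_predictor],
    }
    if reference_values is not None:
        cols["reference"] = reference_values.reindex(cohort.participant_ids)
    for c in spec.covariates:
        cols[c] = cohort.df[c]
    df = pd.DataFrame(cols).dropna()
    dropped = len(cohort.df) - len(df)
    if dropped:
        logger.info("%s: %d incomplete cases dropped", spec.name, dropped)
    return df


def resolve_reference(
    reference: str,
    zmatrix: pd.DataFrame,
    level_y: pd.Series | None = None,
) -> pd.Series | None:
    """Map a reference descriptor to per-participant values.

    Descriptors: ``"none"``, ``"mean_level"``, ``"protein:<id>"``,
    ``"svd:<id1,id2,...>"`` (first right-singular composite of the named
    standardized columns).
    """
    if reference == "none":
        return None
    if reference == "mean_level":
        if level_y is None:
            raise ValueError("mean_level reference requires the level vector")
        return level_y
    if reference.startswith("protein:"):
        pid = reference.split(":", 1)[1]
        if pid not in zmatrix.columns:
            raise KeyError(f"unknown reference protein {pid!r}")
        return zmatrix[pid]
    if reference.startswith("svd:"):
        ids = reference.split(":", 1)[1].split(",")
        return svd_composite(zmatrix[ids])
    raise ValueError(f"unrecognized reference descriptor {reference!r}")


# ---------------------------------------------------------------------------
# Evaluation schemes


def _fit_score(
    train_df: pd.DataFrame, eval_df: pd.DataFrame
) -> np.ndarray:
    """Fit the logistic model on train rows, return probabilities on eval.

    Continuous predictors are standardized with training statistics before
    fitting (unpenalized maximum likelihood)."""
    feat = [c for c in train_df.columns if c != "outcome"]
    Xtr = train_df[feat].to_numpy(dtype=float)
    Xev = eval_df[feat].to_numpy(dtype=float)
    Xtr, Xev = _zscore_cols(Xtr, Xev)
    ytr = train_df["outcome"].to_numpy(dtype=float)
    ones_tr = np.ones((len(Xtr), 1))
    beta = fit_logistic(np.hstack([ones_tr, Xtr]), ytr)
    return predict_proba(np.hstack([np.ones((len(Xev), 1)), Xev]), beta)


def _make_folds(y: np.ndarray, folds: int, seed: int):
    """Shuffled folds; redrawn stratified by outcome if any training part
    would be single-class."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(y))
    if any(len(np.unique(y[tr])) < 2 for tr, _ in splits):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(np.zeros_like(y), y))
    return splits


def cv_auc(
    spec: ModelSpec,
    cohort: CohortTable,
    zmatrix: pd.DataFrame | None = None,
    level_y: pd.Series | None = None,
    folds: int = 10,
    seed: int = 0,
):
    """Pooled out-of-fold AUC under k-fold CV.

    Returns ``(auc, fold_aucs, scores_frame)`` where ``scores_frame`` holds
    the pooled out-of-fold probabilities and outcomes (for paired
    bootstrap comparisons)."""
    ref = resolve_reference(spec.reference, zmatrix, level_y) if (
        spec.reference != "none"
    ) else None
    _guard_degenerate(spec, cohort, ref)
    df = _model_frame(spec, cohort, ref)
    y = df["outcome"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    scores = np.full(len(df), np.nan)
    fold_aucs = []
    for tr, te in _make_folds(y, folds, seed):
        p = _fit_score(df.iloc[tr], df.iloc[te])
        scores[te] = p
        if len(np.unique(y[te])) == 2:
            fold_aucs.append(auc(p, y[te]))
        else:
            fold_aucs.append(np.nan)
    pooled = auc(scores, y)
    frame = pd.DataFrame({"score": scores, "outcome": y}, index=df.index)
    return pooled, np.asarray(fold_aucs), frame


def holdout_auc(
    spec: ModelSpec,
    train_cohort: CohortTable,
    test_cohort: CohortTable,
    z_train: pd.DataFrame | None = None,
    z_test: pd.DataFrame | None = None,
    level_train: pd.Series | None = None,
    level_test: pd.Series | None = None,
):
    """Refit on the full training set, score the held-out test set once."""
    ref_tr = resolve_reference(spec.reference, z_train, level_train) if (
        spec.reference != "none"
    ) else None
    ref_te = resolve_reference(spec.reference, z_test, level_test) if (
        spec.reference != "none"
    ) else None
    _guard_degenerate(spec, train_cohort, ref_tr)
    df_tr = _model_frame(spec, train_cohort, ref_tr)
    df_te = _model_frame(spec, test_cohort, ref_te)
    p = _fit_score(df_tr, df_te)
    y = df_te["outcome"].to_numpy(dtype=float)
    frame = pd.DataFrame({"score": p, "outcome": y}, index=df_te.index)
    return auc(p, y), frame


def oob_bootstrap_eval(
    spec: ModelSpec,
    cohort: CohortTable,
    zmatrix: pd.DataFrame | None = None,
    level_y: pd.Series | None = None,
    n_iter: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-bag bootstrap: resample to full size with replacement, fit,
    evaluate on the never-selected participants; returns the AUCs.

    Iterations whose out-of-bag part lacks an outcome class are skipped
    with a logged count.  The expected out-of-bag fraction is
    (1 - 1/n)^n -> 1/e for large n.
    """
    ref = resolve_reference(spec.reference, zmatrix, level_y) if (
        spec.reference != "none"
    ) else None
    _guard_degenerate(spec, cohort, ref)
    df = _model_frame(spec, cohort, ref)
    n = len(df)
    rng = np.random.default_rng(seed)
    y = df["outcome"].to_numpy(dtype=float)
    out = []
    skipped = 0
    for _ in range(n_iter):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) == 0 or len(np.unique(y[oob])) < 2 or len(
            np.unique(y[idx])
        ) < 2:
            skipped += 1
            continue
        p = _fit_score(df.iloc[idx], df.iloc[oob])
        out.append(auc(p, y[oob]))
    if skipped:
        logger.info("oob_bootstrap_eval: %d iterations skipped", skipped)
    return np.asarray(out)


def _guard_degenerate(spec, cohort, ref: pd.Series | None) -> None:
    if ref is None:
        return
    if spec.reference == f"protein:{spec.main_predictor}":
        raise ValueError("reference equal to the main predictor is degenerate")
    pred = cohort.df[spec.main_predictor]
    both = pd.concat([pred, ref.reindex(pred.index)], axis=1).dropna()
    if len(both) > 2 and np.allclose(
        np.corrcoef(both.iloc[:, 0], both.iloc[:, 1])[0, 1], 1.0, atol=1e-12
    ):
        raise ValueError("reference is identical to the main predictor")


# ---------------------------------------------------------------------------
# Bootstrap ROC comparison, BH, SVD


def bootstrap_roc_test(
    scores_a,
    scores_b,
    labels,
    n_iter: int = 2000,
    seed: int = 0,
) -> float:
    """One-sided bootstrap test of "b better than a" on paired scores.

    Participants are resampled with replacement; p is the fraction of
    iterations with AUC(b) - AUC(a) <= 0, with the (k+1)/(n_valid+1)
    small-sample correction.  Identical score vectors therefore give p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("scores_a, scores_b and labels must be paired")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(y), size=(n_iter, len(y)))
    auc_a = _auc_rows(a[idx], y[idx])
    auc_b = _auc_rows(b[idx], y[idx])
    diff = auc_b - auc_a
    valid = np.isfinite(diff)
    k = int((diff[valid] <= 0).sum())
    return (k + 1) / (int(valid.sum()) + 1)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def svd_composite(candidates: pd.DataFrame) -> pd.Series:
    """First right-singular-direction composite of candidate z-columns.

    Columns are re-standardized on complete cases; the projection onto the
    first right-singular vector is sign-fixed to correlate positively with
    the candidates' mean.  Rows with any missing candidate get NaN.
    """
    if candidates.shape[1] < 1:
        raise ValueError("at least one candidate column required")
    complete = candidates.dropna()
    X = complete.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0) or len(complete) < 2:
        raise ValueError("zero-variance candidate block")
    X = (X - X.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    comp = u[:, 0] * s[0]
    if np.corrcoef(comp, X.mean(axis=1))[0, 1] < 0:
        comp = -comp
    return pd.Series(comp, index=complete.index, name="svd_composite").reindex(
        candidates.index
    )


# ---------------------------------------------------------------------------
# Grid evaluation and candidate selection


def evaluate_reference_grid(
    specs,
    references,
    cohort: CohortTable,
    zmatrix: pd.DataFrame,
    level_y: pd.Series,
    scheme: str = "cv",
    test_cohort: CohortTable | None = None,
    z_test: pd.DataFrame | None = None,
    level_test: pd.Series | None = None,
    folds: int = 10,
    n_iter: int = 2000,
    seed: int = 0,
) -> ReferenceEvalResult:
    """Full (model x reference) AUC grid with comparison p-values.

    References always include "none" and, when present in ``references``,
    "mean_level"; every reference is compared against both baselines with
    the one-sided bootstrap ROC test on the scheme's paired scores, and
    p-values are BH-adjusted across the whole grid.
    """
    if scheme not in ("cv", "holdout", "oob"):
        raise ValueError("scheme must be one of cv, holdout, oob")
    refs = list(dict.fromkeys(["none", *references]))
    rows = []
    for spec in specs:
        per_ref = {}
        for ref in refs:
            s = spec.with_reference(ref)
            if scheme == "cv":
                a, _, frame = cv_auc(s, cohort, zmatrix, level_y, folds, seed)
            elif scheme == "holdout":
                if test_cohort is None:
                    raise ValueError("holdout scheme requires test data")
                a, frame = holdout_auc(
                    s, cohort, test_cohort, zmatrix, z_test, level_y, level_test
                )
            else:
                dist = oob_bootstrap_eval(s, cohort, zmatrix, level_y, n_iter, seed)
                a, frame = float(np.mean(dist)), dist
            per_ref[ref] = (a, frame)
        for ref in refs:
            a, frame = per_ref[ref]
            row = {"model": spec.name, "reference": ref, "auc": a,
                   "p_vs_none": np.nan, "p_vs_mean_level": np.nan}
            for base_name, col in (("none", "p_vs_none"),
                                   ("mean_level", "p_vs_mean_level")):
                if ref == base_name or base_name not in per_ref:
                    continue
                base = per_ref[base_name][1]
                if scheme == "oob":
                    # Paired by iteration seed: same resamples per reference.
                    m = min(len(base), len(frame))
                    d = np.asarray(frame)[:m] - np.asarray(base)[:m]
                    row[col] = (int((d <= 0).sum()) + 1) / (m + 1)
                else:
                    joined = per_ref[base_name][1].join(
                        frame, how="inner", lsuffix="_a", rsuffix="_b"
                    )
                    row[col] = bootstrap_roc_test(
                        joined["score_a"],
                        joined["score_b"],
                        joined["outcome_a"],
                        n_iter=n_iter,
                        seed=seed,
                    )
            rows.append(row)
    table = pd.DataFrame(rows)
    for col in ("p_vs_none", "p_vs_mean_level"):
        mask = table[col].notna()
        table.loc[mask, col.replace("p_", "q_")] = (
            bh_adjust(table.loc[mask, col].to_numpy()) if mask.any() else np.nan
        )
    return ReferenceEvalResult(table=table, scheme=scheme)


def per_protein_reference_auc(
    spec: ModelSpec,
    cohort: CohortTable,
    zmatrix: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
):
    """CV AUC for every protein used as the reference in ``spec``.

    One fold split (from ``seed``) and one listwise-complete participant
    set are shared across proteins, so the resulting per-protein AUCs are
    paired.  Missing z-scores must already be imputed.  Returns
    ``(Series of AUCs, no-reference baseline AUC)``.
    """
    base_df = _model_frame(spec, cohort, None)
    y = base_df["outcome"].to_numpy(dtype=float)
    splits = _make_folds(y, folds, seed)
    covar_cols = ["predictor", *spec.covariates]
    X_base = base_df[covar_cols].to_numpy(dtype=float)
    Z = zmatrix.loc[base_df.index].to_numpy(dtype=float)

    def _cv(Xfull: np.ndarray) -> float:
        scores = np.empty(len(y))
        for tr, te in splits:
            Xtr, Xte = _zscore_cols(Xfull[tr], Xfull[te])
            beta = fit_logistic(
                np.hstack([np.ones((len(tr), 1)), Xtr]), y[tr]
            )
            scores[te] = predict_proba(
                np.hstack([np.ones((len(te), 1)), Xte]), beta
            )
        return auc(scores, y)

    baseline = _cv(X_base)
    aucs = {}
    for j, pid in enumerate(zmatrix.columns):
        if pid == spec.main_predictor:
            aucs[pid] = np.nan
            continue
        Xfull = np.column_stack([X_base, Z[:, j]])
        aucs[pid] = _cv(Xfull)
    return pd.Series(aucs, name=f"auc_ref_{spec.name}"), baseline


def select_candidates(
    cluster_labels: pd.Series,
    auc_maps: pd.DataFrame,
    baselines: dict,
    panel_ids,
    cluster_id=None,
) -> pd.DataFrame:
    """Reference-candidate selection: in the winning cluster, AUC gain in
    both search models, and measured on the validation panel.

    ``auc_maps`` must have columns ``auc_as_reference_tau_model`` and
    ``auc_as_reference_abeta_model``; ``baselines`` the two no-reference
    AUCs keyed by model name.  ``cluster_id`` defaults to the cluster with
    the best mean AUC across both models.  Candidates are ranked by mean
    AUC gain (ties broken by protein id).
    """
    tau_col = "auc_as_reference_tau_model"
    ab_col = "auc_as_reference_abeta_model"
    base_tau = baselines.get("ptau_taupet")
    base_ab = baselines.get("abeta_abpet")
    if cluster_id is None:
        means = auc_maps.groupby(cluster_labels)[[tau_col, ab_col]].mean()
        cluster_id = means.mean(axis=1).idxmax()
    panel_ids = set(panel_ids)
    in_cluster = cluster_labels == cluster_id
    gains = (auc_maps[tau_col] > base_tau) & (auc_maps[ab_col] > base_ab)
    in_panel = auc_maps.index.to_series().isin(panel_ids)
    if not in_panel.any():
        logger.warning("no proteins overlap the validation panel")
    keep = in_cluster & gains & in_panel
    out = auc_maps.loc[keep, [tau_col, ab_col]].copy()
    out["mean_gain"] = (
        (out[tau_col] - base_tau) + (out[ab_col] - base_ab)
    ) / 2.0
    out["cluster"] = cluster_id
    order = np.lexsort((out.index.to_numpy().astype(str), -out["mean_gain"]))
    return out.iloc[order]
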