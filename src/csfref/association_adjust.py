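"""Effect of reference adjustment on protein/group/genotype associations.

Partial Pearson correlations between biomarker proteins are computed with
and without a reference protein among the covariates; AT(N) groups are
compared by one-way ANCOVA adjusted for age and sex; single-variant pQTL
linear models are refit with the reference added; and a bootstrap
enrichment test compares per-protein feature proportions of a subset
against equal-size random draws from the background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from csfref.reference_eval import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class PartialCorrelationMatrix:
    """Symmetric partial Pearson matrix over a named protein set."""

    matrix: pd.DataFrame
    covariates: tuple[str, ...]
    n_used: int


@dataclass
class GroupComparisonResult:
    """Covariate-adjusted group means/SDs and BH-adjusted pairwise contrasts."""

    group_stats: pd.DataFrame  # index group; columns adj_mean, sd, n
    contrasts: pd.DataFrame  # columns: group_a, group_b, estimate, p, q
    model: str


def _residualize(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), C]) if C.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_correlation(x, y, covariates=None) -> float:
    """Pearson correlation of x and y after regressing out the covariates.

    With no covariates this is the plain Pearson correlation.  Complete
    cases only; requires n >= n_covariates + 3.  Constant residuals give
    NaN with a warning.
    """
    x = pd.Series(x).astype(float)
    y = pd.Series(y).astype(float).reindex(x.index)
    if covariates is None or (
        hasattr(covariates, "shape") and np.size(covariates) == 0
    ):
        C = pd.DataFrame(index=x.index)
    else:
        C = pd.DataFrame(covariates).reindex(x.index)
    df = pd.concat([x.rename("_x"), y.rename("_y"), C], axis=1).dropna()
    ncov = C.shape[1]
    if len(df) < ncov + 3:
        raise ValueError("need at least n_covariates + 3 complete cases")
    rx = _residualize(df["_x"].to_numpy(), df.iloc[:, 2:].to_numpy())
    ry = _residualize(df["_y"].to_numpy(), df.iloc[:, 2:].to_numpy())
    if rx.std() == 0 or ry.std() == 0:
        logger.warning("constant residuals; partial correlation undefined")
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def partial_correlation_matrix(
    proteins: pd.DataFrame,
    covariates: pd.DataFrame,
    reference: pd.Series | None = None,
    order_key: pd.Series | None = None,
):
    """Paired partial-correlation matrices without/with the reference.

    ``proteins`` holds the protein columns, ``covariates`` the always-on
    adjustment set (age, sex).  When ``reference`` is given the second
    matrix adds it to the covariates; otherwise the second element is None.
    Listwise-complete rows across everything involved.  ``order_key``
    (e.g. per-protein association with the mean CSF level) sorts
    rows/columns by decreasing value.
    """
    cols = list(proteins.columns)
    if order_key is not None:
        cols = list(order_key.loc[cols].sort_values(ascending=False).index)
    blocks = [proteins[cols], covariates]
    if reference is not None:
        blocks.append(reference.rename("_reference"))
    df = pd.concat(blocks, axis=1).dropna()
    n = len(df)
    P = df[cols].to_numpy(dtype=float)
    C0 = df[covariates.columns].to_numpy(dtype=float)

    def _pcorr(C: np.ndarray) -> pd.DataFrame:
        R = np.column_stack([_residualize(P[:, j], C) for j in range(P.shape[1])])
        M = np.corrcoef(R, rowvar=False)
        np.fill_diagonal(M, 1.0)
        return pd.DataFrame(M, index=cols, columns=cols)

    without = PartialCorrelationMatrix(
        matrix=_pcorr(C0), covariates=tuple(covariates.columns), n_used=n
    )
    if reference is None:
        return without, None
    C1 = np.column_stack([C0, df["_reference"].to_numpy(dtype=float)])
    with_ref = PartialCorrelationMatrix(
        matrix=_pcorr(C1),
        covariates=tuple(covariates.columns) + ("reference",),
        n_used=n,
    )
    return without, with_ref


def ancova_group_compare(
    values,
    groups,
    covariates: pd.DataFrame,
) -> GroupComparisonResult:
    """One-way ANCOVA: values ~ group + covariates, with pairwise contrasts.

    Pairwise group differences use the model's pooled residual variance;
    p-values are BH-adjusted over all pairwise contrasts.  Each group needs
    n >= 3.
    """
    values = pd.Series(values).astype(float)
    groups = pd.Series(groups).reindex(values.index)
    df = pd.concat(
        [values.rename("_y"), groups.rename("_g"), covariates], axis=1
    ).dropna()
    levels = sorted(df["_g"].unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    sizes = df.groupby("_g").size()
    if (sizes < 3).any():
        raise ValueError(f"groups with n < 3: {sizes[sizes < 3].index.tolist()}")

    dummies = pd.get_dummies(df["_g"], prefix="g", dtype=float)[
        [f"g_{lv}" for lv in levels[1:]]
    ]
    X = pd.concat(
        [pd.Series(1.0, index=df.index, name="const"), dummies,
         df[covariates.columns]],
        axis=1,
    ).astype(float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular ANCOVA design")
    fit = sm.OLS(df["_y"].to_numpy(), X.to_numpy()).fit()
    params = pd.Series(fit.params, index=X.columns)
    cov = pd.DataFrame(fit.cov_params(), index=X.columns, columns=X.columns)

    # Covariate-adjusted group means: intercept + group effect at mean covars.
    covar_means = df[covariates.columns].mean()
    base = params["const"] + float(covar_means @ params[covariates.columns])
    adj_mean = {levels[0]: base}
    for lv in levels[1:]:
        adj_mean[lv] = base + params[f"g_{lv}"]
    stats_rows = pd.DataFrame(
        {
            "adj_mean": pd.Series(adj_mean),
            "sd": df.groupby("_g")["_y"].std(ddof=1),
            "n": sizes,
        }
    )

    def _effect(lv):
        return params.get(f"g_{lv}", 0.0)

    def _contrast_var(la, lb):
        v = pd.Series(0.0, index=X.columns)
        if la != levels[0]:
            v[f"g_{la}"] = 1.0
        if lb != levels[0]:
            v[f"g_{lb}"] -= 1.0
        return float(v @ cov @ v)

    rows = []
    for la, lb in combinations(levels, 2):
        est = _effect(la) - _effect(lb)
        se = np.sqrt(_contrast_var(la, lb))
        tval = est / se
        p = 2 * stats.t.sf(abs(tval), df=fit.df_resid)
        rows.append({"group_a": la, "group_b": lb, "estimate": est, "p": p})
    contrasts = pd.DataFrame(rows)
    contrasts["q"] = bh_adjust(contrasts["p"].to_numpy())
    return GroupComparisonResult(
        group_stats=stats_rows,
        contrasts=contrasts,
        model="y ~ group + " + " + ".join(covariates.columns),
    )


def pqtl_assoc(
    protein,
    dosage,
    covariates: pd.DataFrame,
    reference: pd.Series | None = None,
) -> pd.DataFrame:
    """Linear pQTL model of a protein on allele dosage, with and without a
    reference among the covariates.

    Returns one row per model variant (``without_reference`` and, when a
    reference is given, ``with_reference``) with the dosage beta, SE and p.
    """
    protein = pd.Series(protein).astype(float)
    dosage = pd.Series(dosage).astype(float).reindex(protein.index)
    d = dosage.dropna()
    if d.nunique() < 2:
        raise ValueError("monomorphic genotype")
    if ((d < 0) | (d > 2)).any():
        raise ValueError("dosage must lie in [0, 2]")

    def _fit(extra: pd.Series | None):
        blocks = [protein.rename("_y"), dosage.rename("dosage"), covariates]
        if extra is not None:
            blocks.append(extra.rename("_reference"))
        df = pd.concat(blocks, axis=1).dropna()
        X = sm.add_constant(df.drop(columns="_y").astype(float))
        fit = sm.OLS(df["_y"].to_numpy(), X.to_numpy()).fit()
        i = list(X.columns).index("dosage")
        return {
            "beta": fit.params[i],
            "se": fit.bse[i],
            "p": fit.pvalues[i],
            "n": int(fit.nobs),
        }

    rows = {"without_reference": _fit(None)}
    if reference is not None:
        rows["with_reference"] = _fit(reference)
    return pd.DataFrame(rows).T


def bootstrap_enrichment_test(
    subset_ids,
    background_ids,
    features: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap enrichment of per-protein feature proportions.

    The observed statistic is the subset mean of each feature column; the
    null distribution is the mean over ``n_boot`` equal-size random draws
    from the background.  Two-sided p is the fraction of draws at least as
    far from the null center as the observation, with the (k+1)/(n+1)
    correction, BH-adjusted across features.
    """
    subset = list(subset_ids)
    background = list(background_ids)
    if not set(subset) <= set(background):
        raise ValueError("subset must be contained in background")
    if len(subset) == 0 or len(subset) == len(background):
        raise ValueError("subset must be a proper non-empty subset")
    F = features.loc[background].to_numpy(dtype=float)
    obs = features.loc[subset].to_numpy(dtype=float).mean(axis=0)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(background), size=(n_boot, len(subset)))
    null_means = F[idx].mean(axis=1)  # n_boot x n_features
    center = null_means.mean(axis=0)
    k = (np.abs(null_means - center) >= np.abs(obs - center)).sum(axis=0)
    p = (k + 1) / (n_boot + 1)
    out = pd.DataFrame(
        {"observed": obs, "null_mean": center, "p": p, "q": bh_adjust(p)},
        index=features.columns,
    )
    return out
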