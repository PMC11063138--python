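"""Standardization and the mean standardized CSF protein level.

The central statistic is the per-participant mean z-score over the protein
panel,

    y_i = (1 / n_proteins) * sum_j z_ij,

a proxy for non-disease inter-individual differences in overall CSF protein
concentration.  Standardization (per-protein location/scale) is always
fitted on training participants only and applied unchanged elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from csfref.cohort_io import CohortTable, ProteinMatrix

logger = logging.getLogger(__name__)


@dataclass
class StandardizationModel:
    """Per-protein training mean (NPX) and sample SD (NPX, ddof=1)."""

    location: pd.Series
    scale: pd.Series


@dataclass
class MeanCSFLevel:
    """Per-participant mean standardized CSF level (unitless z-units)."""

    y: pd.Series
    n_proteins: int
    n_contributing: pd.Series


@dataclass
class AssociationResult:
    """Standardized coefficients with SEs and p-values for one linear model."""

    table: pd.DataFrame  # index: term; columns: beta, se, p
    model: str
    n_used: int


def fit_standardization(train: ProteinMatrix) -> StandardizationModel:
    """Per-protein mean and sample SD over non-missing training values."""
    counts = train.values.notna().sum(axis=0)
    too_few = counts.index[counts < 2].tolist()
    if too_few:
        raise ValueError(f"proteins with <2 non-missing training values: {too_few[:5]}")
    loc = train.values.mean(axis=0, skipna=True)
    scale = train.values.std(axis=0, ddof=1, skipna=True)
    degenerate = scale.index[(scale <= 0) | ~np.isfinite(scale)].tolist()
    if degenerate:
        raise ValueError(f"zero-variance proteins: {degenerate[:5]}")
    return StandardizationModel(location=loc, scale=scale)


def apply_standardization(
    model: StandardizationModel, matrix: ProteinMatrix
) -> ProteinMatrix:
    """Elementwise (value - location) / scale; missing stays missing."""
    unknown = matrix.protein_ids.difference(model.location.index).tolist()
    if unknown:
        raise KeyError(f"proteins not covered by standardization model: {unknown[:5]}")
    z = (matrix.values - model.location[matrix.protein_ids]) / model.scale[
        matrix.protein_ids
    ]
    return ProteinMatrix(z, matrix.panel)


def mean_csf_level(standardized: ProteinMatrix) -> MeanCSFLevel:
    """Count-weighted mean of the non-missing z-scores per participant.

    Missing z-scores are excluded from the average (not imputed as zero):
    imputing zero would bias y toward 0 for high-missingness participants.
    With a complete matrix this is exactly the plain average.
    """
    z = standardized.values
    counts = z.notna().sum(axis=1)
    y = z.mean(axis=1, skipna=True)
    if (counts == 0).any():
        logger.warning(
            "%d participants have no contributing proteins; y set missing",
            int((counts == 0).sum()),
        )
    return MeanCSFLevel(
        y=y.rename("mean_csf_level"),
        n_proteins=standardized.n_proteins,
        n_contributing=counts.rename("n_contributing"),
    )


def _std_beta(
    response: np.ndarray, target: np.ndarray, covars: np.ndarray
) -> float:
    """Standardized coefficient of ``target`` regressing response on
    [1, target, covars], all continuous columns z-scored."""

    def z(v):
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    X = np.column_stack([np.ones_like(target), z(target)] + [z(c) for c in covars.T])
    beta, *_ = np.linalg.lstsq(X, z(response), rcond=None)
    return float(beta[1])


def order_by_level_association(
    standardized: ProteinMatrix,
    level: MeanCSFLevel,
    cohort: CohortTable,
) -> pd.Series:
    """Per-protein |standardized beta| of z_j on y, adjusted for age and sex.

    Returns the |beta| values sorted ascending (ties broken by protein id),
    i.e. the protein ordering used to visualize which proteins co-vary with
    the mean standardized CSF level.
    """
    y = level.y.loc[standardized.participant_ids].to_numpy()
    if not np.isfinite(y).all():
        raise ValueError("mean CSF level must be finite for every participant")
    covars = cohort.df.loc[standardized.participant_ids, ["age", "sex"]].to_numpy(
        dtype=float
    )
    out = {}
    zvals = standardized.values
    for pid_ in standardized.protein_ids:
        zj = zvals[pid_].to_numpy()
        ok = np.isfinite(zj)
        if ok.sum() < 4:
            out[pid_] = np.nan
            continue
        out[pid_] = abs(_std_beta(zj[ok], y[ok], covars[ok]))
    res = pd.Series(out, name="abs_beta")
    # Ascending by |beta|; ties (and NaNs, last) broken by protein id.
    order = np.lexsort((res.index.to_numpy().astype(str), res.to_numpy()))
    return res.iloc[order]


DEFAULT_COVARIATE_TERMS = (
    "age",
    "sex",
    "education",
    "icv",
    "gm_volume",
    "ventricle_volume",
)


def level_covariate_model(
    level: MeanCSFLevel,
    cohort: CohortTable,
    terms: tuple[str, ...] = DEFAULT_COVARIATE_TERMS,
) -> AssociationResult:
    """Multiple linear regression of y on demographic/volumetric terms.

    Continuous terms are z-scored so coefficients are standardized; sex
    (0/1) enters as-is.  Listwise deletion on the included terms, with the
    dropped count logged.  A rank-deficient design raises an error naming
    the aliased terms.
    """
    df = pd.concat([level.y, cohort.df[list(terms)]], axis=1).dropna()
    n_dropped = len(level.y) - len(df)
    if n_dropped:
        logger.info("level_covariate_model: %d incomplete cases dropped", n_dropped)
    X = pd.DataFrame(index=df.index)
    for term in terms:
        v = df[term].to_numpy(dtype=float)
        if term == "sex":
            X[term] = v
        else:
            sd = v.std(ddof=0)
            X[term] = (v - v.mean()) / sd if sd > 0 else 0.0
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # Identify aliased columns via QR pivoting on the correlation scale.
        _, r = np.linalg.qr(Xc.to_numpy())
        aliased = [
            Xc.columns[i] for i in range(Xc.shape[1]) if abs(r[i, i]) < 1e-10
        ]
        raise ValueError(f"collinear design; aliased terms: {aliased}")
    fit = sm.OLS(df.iloc[:, 0].to_numpy(), Xc).fit()
    table = pd.DataFrame(
        {"beta": fit.params, "se": fit.bse, "p": fit.pvalues}
    ).drop(index="const")
    return AssociationResult(
        table=table, model="y ~ " + " + ".join(terms), n_used=len(df)
    )
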