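"""AT(N) grouping by CSF and by PET, and their concordance.

A-status comes from the CSF Abeta42/Abeta40 ratio (A+ when ratio < 0.08).
T-status comes either from CSF P-tau181 (unadjusted cutoff > 21.8 pg/ml,
or a reference-adjusted linear boundary ptau > a + b * c_ref with the
reference in z-units), or from tau-PET (Braak I-IV SUVR > 1.36).
Amyloid-PET positivity uses centiloids > 20.  The concordance matrix
counts participants over the four groups {A-T-, A-T+, A+T-, A+T+}, CSF in
rows and PET in columns; by convention the A axis is CSF-based in both
groupings, so only the T axis differs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit

from csfref._logistic import fit_logistic, predict_proba

logger = logging.getLogger(__name__)

GROUPS = ("A-T-", "A-T+", "A+T-", "A+T+")


@dataclass
class ATNConfig:
    """Cutoffs for AT(N) grouping (positive cutoffs, strict comparisons)."""

    abeta_ratio_cutoff: float = 0.08  # A+ when ratio < cutoff
    ptau_cutoff_pgml: float = 21.8  # T+ when above
    tau_pet_suvr_cutoff: float = 1.36
    amyloid_centiloid_cutoff: float = 20.0
    adjusted_intercept: float = 39.0  # pg/ml
    adjusted_slope: float = 10.1  # pg/ml per reference z-unit

    def __post_init__(self) -> None:
        for name in ("abeta_ratio_cutoff", "ptau_cutoff_pgml",
                     "tau_pet_suvr_cutoff", "amyloid_centiloid_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ConcordanceMatrix:
    """4x4 counts over AT groups (CSF rows, PET columns) plus accuracy."""

    counts: pd.DataFrame
    accuracy: float

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


def _labelled(values, positive_mask) -> pd.Series:
    values = pd.Series(values)
    out = pd.Series(pd.NA, index=values.index, dtype="object")
    ok = values.notna()
    out[ok] = np.where(positive_mask[ok], "+", "-")
    return out


def classify_A(abeta_ratio, config: ATNConfig = ATNConfig()) -> pd.Series:
    """A+ iff Abeta42/Abeta40 < cutoff (strict); missing ratio -> missing."""
    ratio = pd.Series(abeta_ratio)
    return "A" + _labelled(ratio, ratio < config.abeta_ratio_cutoff)


def classify_T_csf(
    ptau,
    reference_z=None,
    config: ATNConfig = ATNConfig(),
    adjusted: bool = False,
) -> pd.Series:
    """Unadjusted: T+ iff ptau > cutoff.  Adjusted: T+ iff
    ptau > intercept + slope * reference_z."""
    ptau = pd.Series(ptau)
    if adjusted:
        if reference_z is None:
            raise ValueError("adjusted classification requires reference_z")
        thr = config.adjusted_intercept + config.adjusted_slope * pd.Series(
            reference_z
        ).reindex(ptau.index)
        return "T" + _labelled(ptau, ptau > thr)
    return "T" + _labelled(ptau, ptau > config.ptau_cutoff_pgml)


def classify_T_pet(suvr, config: ATNConfig = ATNConfig()) -> pd.Series:
    suvr = pd.Series(suvr)
    return "T" + _labelled(suvr, suvr > config.tau_pet_suvr_cutoff)


def classify_A_pet(centiloid, config: ATNConfig = ATNConfig()) -> pd.Series:
    centiloid = pd.Series(centiloid)
    return "A" + _labelled(centiloid, centiloid > config.amyloid_centiloid_cutoff)


def combine_at(a_labels: pd.Series, t_labels: pd.Series) -> pd.Series:
    """Join A and T labels into the four-group AT label (missing propagates)."""
    out = a_labels.astype("object") + t_labels.astype("object")
    out[a_labels.isna() | t_labels.isna()] = pd.NA
    return out


def derive_adjusted_boundary(
    ptau,
    reference_z,
    pet_positive,
    config: ATNConfig = ATNConfig(),
    operating_rule: str = "prob05",
) -> tuple[float, float]:
    """Derive the reference-adjusted T boundary (a, b) from a logistic fit.

    Fits ``pet_positive ~ ptau + reference`` and converts the line of
    constant predicted probability into pg/ml space: T+ iff
    ptau > a + b * reference_z.  Operating rules for the probability level:

    * ``prob05`` (default): the 0.5-probability boundary, i.e. the
      operating point is refit to the PET outcome;
    * ``match_specificity``: match the specificity of the unadjusted
      pg/ml cutoff on the same data;
    * ``youden``: maximize sensitivity + specificity - 1.

    The default follows from the form of published reference-adjusted
    boundaries, whose threshold at the mean reference sits far above the
    conventional unadjusted cutoff - a pattern a matched-specificity rule
    cannot produce.
    """
    df = pd.DataFrame(
        {"ptau": ptau, "ref": reference_z, "pet": pet_positive}
    ).dropna()
    y = df["pet"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both PET classes must be present")
    X = np.column_stack(
        [np.ones(len(df)), df["ptau"].to_numpy(), df["ref"].to_numpy()]
    )
    beta = fit_logistic(X, y)
    if abs(beta[1]) < 1e-12:
        raise ValueError("ptau coefficient is zero; no boundary in pg/ml")
    # z-statistic for the ptau coefficient from the observed information.
    p_hat = predict_proba(X, beta)
    w = p_hat * (1 - p_hat)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    if abs(beta[1] / np.sqrt(cov[1, 1])) < 1.96:
        logger.warning("ptau coefficient not significant; boundary returned anyway")

    probs = predict_proba(X, beta)
    if operating_rule == "match_specificity":
        neg = df["ptau"].to_numpy()[y == 0]
        specificity = float((neg <= config.ptau_cutoff_pgml).mean())
        # Probability threshold reproducing that specificity on the fit.
        p_star = float(np.quantile(probs[y == 0], specificity))
    elif operating_rule == "prob05":
        p_star = 0.5
    elif operating_rule == "youden":
        order = np.argsort(probs)
        cand = probs[order]
        best, p_star = -np.inf, 0.5
        n_pos, n_neg = y.sum(), (1 - y).sum()
        for thr in cand:
            sens = float(((probs > thr) & (y == 1)).sum() / n_pos)
            spec = float(((probs <= thr) & (y == 0)).sum() / n_neg)
            j = sens + spec - 1
            if j > best:
                best, p_star = j, float(thr)
    else:
        raise ValueError(f"unknown operating rule {operating_rule!r}")

    p_star = float(np.clip(p_star, 1e-12, 1 - 1e-12))
    eta = float(logit(p_star))
    a = (eta - beta[0]) / beta[1]
    b = -beta[2] / beta[1]
    return float(a), float(b)


def concordance(csf_labels: pd.Series, pet_labels: pd.Series) -> ConcordanceMatrix:
    """4x4 group counts (CSF rows, PET columns) and agreement accuracy."""
    csf = pd.Series(csf_labels)
    pet = pd.Series(pet_labels).reindex(csf.index)
    if csf.isna().any() or pet.isna().any():
        raise ValueError("concordance requires paired labels without missing")
    bad = set(csf) | set(pet)
    if not bad <= set(GROUPS):
        raise ValueError(f"labels outside AT groups: {sorted(bad - set(GROUPS))}")
    counts = pd.DataFrame(0, index=list(GROUPS), columns=list(GROUPS))
    for c, p in zip(csf, pet):
        counts.loc[c, p] += 1
    n = len(csf)
    accuracy = float(np.trace(counts.to_numpy()) / n) if n else float("nan")
    counts.index.name = "csf"
    counts.columns.name = "pet"
    return ConcordanceMatrix(counts=counts, accuracy=accuracy)
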