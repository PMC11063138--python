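"""Cohort/protein-matrix containers, I/O, detectability, and splitting.

The protein matrix holds participants x proteins NPX values (log2-scale
relative abundances) with ``NaN`` marking values below the limit of
detection.  Missing values are never imputed at I/O time; each downstream
operation declares its own handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns a cohort table must provide.  Everything else (volumes,
#: biomarker concentrations, PET measures, outcomes) is optional and only
#: required by the analyses that consume it.
MANDATORY_COHORT_COLUMNS = ("participant_id", "age", "sex")

DIAGNOSES = ("NC", "SCD", "MCI", "Dementia", "Other")


class FormatError(ValueError):
    """A delimited input file violates the table contract."""


@dataclass
class CohortTable:
    """Per-participant covariates, diagnoses, biomarkers and outcomes.

    ``df`` is indexed by unique ``participant_id``.  ``sex`` is 0/1
    (1 = male), ``age``/``education`` in years, volumes in consistent
    arbitrary units, P-tau181/Abeta42/Abeta40 in pg/ml.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicated participant_id values: {dups[:5]}")
        sex = self.df.get("sex")
        if sex is not None:
            bad = sex.dropna()[~sex.dropna().isin([0, 1])]
            if len(bad):
                raise FormatError("sex must be coded 0/1")

    @property
    def participant_ids(self) -> pd.Index:
        return self.df.index

    def __len__(self) -> int:
        return len(self.df)

    def loc(self, ids) -> "CohortTable":
        return CohortTable(self.df.loc[ids].copy())


@dataclass
class ProteinMatrix:
    """Participants x proteins NPX matrix with missingness mask and panels."""

    values: pd.DataFrame
    panel: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()]
            raise FormatError(f"duplicated protein ids: {list(dups[:5])}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()]
            raise FormatError(f"duplicated participant_id values: {list(dups[:5])}")
        if self.panel is not None:
            self.panel = self.panel.reindex(self.values.columns)

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def participant_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def loc(self, ids) -> "ProteinMatrix":
        return ProteinMatrix(self.values.loc[ids].copy(), self.panel)

    def select_proteins(self, ids) -> "ProteinMatrix":
        panel = self.panel.loc[ids] if self.panel is not None else None
        return ProteinMatrix(self.values.loc[:, ids].copy(), panel)


# ---------------------------------------------------------------------------
# Reading and writing


def _read_table(path) -> pd.DataFrame:
    # sep=None lets pandas sniff TSV vs CSV from the header line.
    return pd.read_csv(path, sep=None, engine="python")


def read_cohort(path) -> CohortTable:
    """Read a delimited cohort table; unparseable numeric cells become NaN."""
    raw = _read_table(path)
    missing = [c for c in MANDATORY_COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"cohort table missing mandatory columns: {missing}")
    raw = raw.set_index("participant_id")
    n_coerced = 0
    for col in raw.columns:
        if col == "diagnosis":
            continue
        before = raw[col].notna().sum()
        raw[col] = pd.to_numeric(raw[col], errors="coerce")
        n_coerced += int(before - raw[col].notna().sum())
    if n_coerced:
        logger.warning("read_cohort: %d unparseable cells set to missing", n_coerced)
    for col in ("icv", "gm_volume", "ventricle_volume"):
        if col in raw.columns:
            nonpos = raw[col].dropna() <= 0
            if nonpos.any():
                raise FormatError(f"non-positive volumes in column {col!r}")
    return CohortTable(raw)


def read_matrix(path, panel: pd.Series | None = None) -> ProteinMatrix:
    """Read a participants x proteins NPX table (first column participant_id)."""
    raw = _read_table(path)
    first = raw.columns[0]
    raw = raw.set_index(first)
    raw.index.name = "participant_id"
    raw.columns.name = "protein_id"
    n_coerced = 0
    for col in raw.columns:
        before = raw[col].notna().sum()
        raw[col] = pd.to_numeric(raw[col], errors="coerce")
        n_coerced += int(before - raw[col].notna().sum())
    if n_coerced:
        logger.warning("read_matrix: %d unparseable cells set to missing", n_coerced)
    return ProteinMatrix(raw.astype(float), panel)


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.df.to_csv(path, sep="\t", index=True, index_label="participant_id")


def write_matrix(matrix: ProteinMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index=True, index_label="participant_id")


# ---------------------------------------------------------------------------
# Detectability


def missing_frequency(matrix: ProteinMatrix) -> pd.Series:
    """Fraction of participants with a missing value, per protein."""
    return matrix.values.isna().mean(axis=0)


def detectability_filter(matrix: ProteinMatrix, max_missing: float) -> ProteinMatrix:
    """Keep proteins with missing frequency strictly below ``max_missing``.

    Strict "<" mirrors the usual detectability convention (e.g. a <75%
    missing-frequency filter); fully observed proteins are always kept, so
    ``max_missing=0`` retains exactly the complete proteins.  Protein order
    is preserved; an empty result is a warning, not an error.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    freq = missing_frequency(matrix)
    keep = freq.index[(freq < max_missing) | (freq == 0)]
    if len(keep) == 0:
        logger.warning("detectability_filter removed every protein")
    return matrix.select_proteins(keep)


# ---------------------------------------------------------------------------
# Splitting


def train_test_split(
    cohort: CohortTable,
    matrix: ProteinMatrix,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratify_by: str | None = None,
):
    """Random, disjoint, exhaustive participant split.

    Plain rounding of ``n * test_fraction`` decides the test size.  Simple
    random sampling by default; ``stratify_by`` draws proportionally within
    levels of a cohort column.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    ids = cohort.participant_ids
    if not ids.equals(matrix.participant_ids):
        raise FormatError("cohort and matrix participants differ")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        n_test = int(round(len(ids) * test_fraction))
        test_ids = set(rng.choice(ids.to_numpy(), size=n_test, replace=False))
    else:
        test_ids = set()
        for _, grp in cohort.df.groupby(stratify_by, dropna=False, sort=True):
            k = int(round(len(grp) * test_fraction))
            test_ids |= set(rng.choice(grp.index.to_numpy(), size=k, replace=False))
    mask = ids.isin(test_ids)
    train_ids, test_idx = ids[~mask], ids[mask]
    return (
        (cohort.loc(train_ids), matrix.loc(train_ids)),
        (cohort.loc(test_idx), matrix.loc(test_idx)),
    )
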