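"""Protein embedding, clustering, and the six reference-nomination maps.

Each protein is a point in participant space (its standardized values
across participants).  t-SNE projects the panel to 2-D, K-means partitions
the map, and six per-protein "metric maps" summarize how suitable each
protein is as a reference: association with the mean standardized CSF
level, with ventricular volume, with P-tau181 and Abeta42 among cognitively
unimpaired amyloid-negative participants, and cross-validated AUC when used
as the reference covariate in the two biomarker search models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from csfref.cohort_io import CohortTable, ProteinMatrix
from csfref.csf_level import MeanCSFLevel, _std_beta
from csfref import reference_eval as re_mod

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "assoc_mean_level",
    "assoc_ventricle",
    "assoc_ptau_cu_abneg",
    "assoc_abeta42_cu_abneg",
    "auc_as_reference_tau_model",
    "auc_as_reference_abeta_model",
)


@dataclass
class EmbeddingClusters:
    """2-D coordinates plus K-means labels (1..K) for every protein."""

    coordinates: pd.DataFrame  # columns: tsne1, tsne2
    labels: pd.Series  # values in 1..k
    k: int
    seed: int
    perplexity: float


@dataclass
class MetricMaps:
    """Six per-protein criteria plus their min-max scaled versions."""

    maps: pd.DataFrame  # proteins x METRIC_NAMES
    scaled: pd.DataFrame
    baseline_auc: dict  # model name -> no-reference CV AUC


def _impute_zero(standardized: ProteinMatrix) -> pd.DataFrame:
    z = standardized.values
    n_missing = int(z.isna().to_numpy().sum())
    if n_missing:
        logger.info("imputing %d missing z-scores as 0", n_missing)
        z = z.fillna(0.0)
    return z


def embed_proteins(
    standardized: ProteinMatrix, perplexity: float = 30.0, seed: int = 0
) -> pd.DataFrame:
    """t-SNE of proteins-as-points; deterministic for a fixed seed.

    Missing z-scores are imputed as 0 (the training mean) with a logged
    count before embedding.  PCA initialization keeps the layout a
    deterministic function of the input and seed.
    """
    z = _impute_zero(standardized)
    points = z.to_numpy().T  # proteins x participants
    if perplexity >= points.shape[0]:
        raise ValueError(
            f"perplexity ({perplexity}) must be < number of proteins "
            f"({points.shape[0]})"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        max_iter=1000,
    )
    coords = tsne.fit_transform(points)
    return pd.DataFrame(
        coords, index=standardized.protein_ids, columns=["tsne1", "tsne2"]
    )


def cluster_embedding(
    coordinates: pd.DataFrame,
    k: int = 20,
    seed: int = 0,
    merge_overrides: list[tuple[int, int]] | None = None,
) -> EmbeddingClusters:
    """K-means on the 2-D map, with reproducible semi-supervised merges.

    The "semi-supervised" adjustment is expressed as an explicit list of
    label pairs to merge, recorded in configuration, rather than
    interactive tuning.  Input-order invariance is guaranteed by fitting on
    the coordinates sorted by protein id.
    """
    if k < 1 or k > len(coordinates):
        raise ValueError("k must be in [1, n_proteins]")
    ordered = coordinates.sort_index()
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(ordered.to_numpy()) + 1  # 1..k
    labels = pd.Series(raw, index=ordered.index, name="cluster").loc[
        coordinates.index
    ]
    if merge_overrides:
        parent = {i: i for i in range(1, k + 1)}

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in merge_overrides:
            if a not in parent or b not in parent:
                raise ValueError(f"merge override ({a}, {b}) outside 1..{k}")
            ra, rb = find(a), find(b)
            parent[max(ra, rb)] = min(ra, rb)
        labels = labels.map(lambda x: find(int(x)))
    # Relabel to contiguous 1..k_eff preserving ascending order.
    uniq = sorted(labels.unique())
    remap = {old: i + 1 for i, old in enumerate(uniq)}
    labels = labels.map(remap)
    return EmbeddingClusters(
        coordinates=coordinates,
        labels=labels,
        k=len(uniq),
        seed=seed,
        perplexity=float("nan"),
    )


def cu_abneg_mask(cohort: CohortTable, ratio_cutoff: float = 0.08) -> pd.Series:
    """Cognitively unimpaired amyloid-negative participants:
    diagnosis in {NC, SCD} and Abeta42/Abeta40 >= cutoff."""
    df = cohort.df
    return df["diagnosis"].isin(["NC", "SCD"]) & (df["abeta_ratio"] >= ratio_cutoff)


def _assoc_map(
    z: pd.DataFrame, target: np.ndarray, covars: np.ndarray
) -> pd.Series:
    ok = np.isfinite(target) & np.isfinite(covars).all(axis=1)
    out = {}
    for pid in z.columns:
        out[pid] = abs(
            _std_beta(z[pid].to_numpy()[ok], target[ok], covars[ok])
        )
    return pd.Series(out)


def _minmax(v: pd.Series) -> pd.Series:
    lo, hi = v.min(), v.max()
    if not np.isfinite(hi - lo) or hi == lo:
        logger.warning("constant metric map; scaled version set to all-zero")
        return pd.Series(0.0, index=v.index)
    return (v - lo) / (hi - lo)


def metric_maps(
    standardized: ProteinMatrix,
    level: MeanCSFLevel,
    cohort: CohortTable,
    models=None,
    folds: int = 10,
    fold_seed: int = 0,
    ratio_cutoff: float = 0.08,
) -> MetricMaps:
    """Compute the six per-protein reference-nomination criteria.

    Association maps are absolute standardized betas adjusted for age and
    sex.  The two AUC maps use 10-fold CV with one fold seed shared across
    proteins, so per-protein AUC differences are paired.  Missing z-scores
    are imputed as 0 for these screens (logged).
    """
    if models is None:
        models = re_mod.SEARCH_MODELS
    z = _impute_zero(standardized)
    df = cohort.df.loc[standardized.participant_ids]
    covars = df[["age", "sex"]].to_numpy(dtype=float)

    cu = cu_abneg_mask(cohort, ratio_cutoff).loc[standardized.participant_ids]
    cu &= df["ptau181"].notna() & df["abeta42"].notna()
    if cu.sum() == 0:
        raise ValueError("empty cognitively-unimpaired amyloid-negative subset")

    maps = pd.DataFrame(index=standardized.protein_ids, columns=METRIC_NAMES,
                        dtype=float)
    y = level.y.loc[standardized.participant_ids].to_numpy()
    maps["assoc_mean_level"] = _assoc_map(z, y, covars)
    maps["assoc_ventricle"] = _assoc_map(
        z, df["ventricle_volume"].to_numpy(dtype=float), covars
    )
    zcu = z.loc[cu[cu].index]
    ccu = covars[cu.to_numpy()]
    maps["assoc_ptau_cu_abneg"] = _assoc_map(
        zcu, df.loc[cu, "ptau181"].to_numpy(dtype=float), ccu
    )
    maps["assoc_abeta42_cu_abneg"] = _assoc_map(
        zcu, df.loc[cu, "abeta42"].to_numpy(dtype=float), ccu
    )

    baseline = {}
    for spec, col in zip(models, ("auc_as_reference_tau_model",
                                  "auc_as_reference_abeta_model")):
        aucs, base = re_mod.per_protein_reference_auc(
            spec, cohort, z, folds=folds, seed=fold_seed
        )
        maps[col] = aucs
        baseline[spec.name] = base

    scaled = maps.apply(_minmax)
    return MetricMaps(maps=maps, scaled=scaled, baseline_auc=baseline)


def cluster_auc_summary(
    clusters: EmbeddingClusters | pd.Series, maps: MetricMaps
) -> pd.DataFrame:
    """Per-cluster mean +/- SD of the two reference-model AUC maps.

    SD is the population SD (ddof=0) so a singleton cluster reports 0.
    ``clusters`` may be an :class:`EmbeddingClusters` or a bare label
    Series (e.g. planted ground-truth clusters).
    """
    labels = clusters.labels if isinstance(clusters, EmbeddingClusters) else clusters
    rows = []
    for c, idx in labels.groupby(labels).groups.items():
        sub = maps.maps.loc[idx]
        rows.append(
            {
                "cluster": c,
                "n_proteins": len(idx),
                "mean_auc_tau": sub["auc_as_reference_tau_model"].mean(),
                "sd_auc_tau": sub["auc_as_reference_tau_model"].std(ddof=0),
                "mean_auc_abeta": sub["auc_as_reference_abeta_model"].mean(),
                "sd_auc_abeta": sub["auc_as_reference_abeta_model"].std(ddof=0),
            }
        )
    out = pd.DataFrame(rows).set_index("cluster").sort_index()
    for name, base in maps.baseline_auc.items():
        out.attrs[f"baseline_auc_{name}"] = base
    return out
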