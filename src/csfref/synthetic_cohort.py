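"""Synthetic CSF proteomics cohorts with a planted dilution factor.

The generator emulates the statistical structure the downstream analyses
assume about a memory-clinic CSF proteomics cohort:

* a per-participant latent concentration ("dilution") factor ``d`` that
  loads on a large fraction of the protein panel, is higher with age and
  male sex and lower with larger ventricular volume;
* correlated protein clusters with cluster-specific mean loadings on ``d``;
* correlated amyloid (``a``) and tau (``t``) pathology burdens driving
  designated biomarker proteins and the pg/ml immunoassay biomarkers
  (P-tau181-like, Abeta42-like, Abeta40-like);
* PET outcomes obtained by thresholding noisy continuous PET measures that
  are monotone in the latent burdens, at prevalence-matched cutoffs;
* below-LOD censoring recorded as missing values.

Everything latent is retained in :class:`SyntheticTruth`, so parameter
recovery and directional analyses can be checked against ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from csfref.cohort_io import CohortTable, ProteinMatrix

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A simulation configuration field violates its invariant."""


#: Default per-cluster mean loadings on the dilution factor.  One cluster
#: (the last) is the planted "reference" cluster: highest loading, zero
#: disease effect.  Zero-loading clusters represent proteins unrelated to
#: the overall CSF concentration level.
DEFAULT_LOADINGS = (0.0, 0.1, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.9, 1.2)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults match the training split of a large memory-clinic CSF
    proteomics cohort: 658 participants, with a 500-protein, 10-cluster
    panel standing in for a full multi-thousand-protein discovery library
    at desk scale.  Effect signs follow the directions such cohorts report
    (mean CSF level higher with age and male sex, lower with ventricular
    volume).
    """

    n_participants: int = 658
    n_proteins: int = 500
    n_clusters: int = 10
    cluster_sizes: tuple[int, ...] | None = None
    dilution_sd: float = 1.0
    loading_by_cluster: tuple[float, ...] | None = None
    loading_jitter_sd: float = 0.08
    noise_sd: float = 1.0
    amyloid_prevalence: float = 0.33
    tau_prevalence: float = 0.27
    conversion_prevalence: float = 0.12
    effect_amyloid: float = -1.2
    effect_tau: float = 1.5
    age_effect: float = 0.30
    sex_effect: float = 0.20
    ventricle_effect: float = -0.35
    burden_correlation: float = 0.5
    pet_noise_sd: float = 0.5
    lod_quantile: float = 0.02
    pathway_sd: float = 1.0
    genotype_maf: float = 0.3
    genotype_dilution_effect: float = 0.25
    genotype_direct_effect: float = 0.6
    seed: int = 0

    def resolved_cluster_sizes(self) -> np.ndarray:
        if self.cluster_sizes is not None:
            return np.asarray(self.cluster_sizes, dtype=int)
        base = self.n_proteins // self.n_clusters
        sizes = np.full(self.n_clusters, base, dtype=int)
        sizes[: self.n_proteins - base * self.n_clusters] += 1
        return sizes

    def resolved_loadings(self) -> np.ndarray:
        if self.loading_by_cluster is not None:
            lam = np.asarray(self.loading_by_cluster, dtype=float)
        else:
            lam = np.asarray(DEFAULT_LOADINGS, dtype=float)
            if self.n_clusters != len(lam):
                # Interpolate the default profile onto n_clusters values.
                lam = np.interp(
                    np.linspace(0.0, 1.0, self.n_clusters),
                    np.linspace(0.0, 1.0, len(lam)),
                    lam,
                )
        return lam

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if not 1 <= self.n_clusters <= self.n_proteins:
            raise ConfigError("n_clusters must be in [1, n_proteins]")
        sizes = self.resolved_cluster_sizes()
        if len(sizes) != self.n_clusters:
            raise ConfigError("cluster_sizes length must equal n_clusters")
        if sizes.sum() != self.n_proteins:
            raise ConfigError("cluster_sizes must sum to n_proteins")
        if (sizes <= 0).any():
            raise ConfigError("cluster_sizes must be positive")
        lam = self.resolved_loadings()
        if len(lam) != self.n_clusters:
            raise ConfigError("loading_by_cluster length must equal n_clusters")
        for name in ("dilution_sd", "loading_jitter_sd", "noise_sd", "pet_noise_sd",
                     "pathway_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("amyloid_prevalence", "tau_prevalence", "conversion_prevalence"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1)")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ConfigError("lod_quantile must be in [0, 1)")
        if not -1.0 < self.burden_correlation < 1.0:
            raise ConfigError("burden_correlation must be in (-1, 1)")
        if not 0.0 < self.genotype_maf < 1.0:
            raise ConfigError("genotype_maf must be in (0, 1)")


@dataclass
class SyntheticTruth:
    """Latent ground truth for one generated cohort."""

    d: pd.Series
    a: pd.Series
    t: pd.Series
    lam: pd.Series
    beta_a: pd.Series
    beta_t: pd.Series
    cluster_label: pd.Series
    designated_roles: dict

    def to_json(self, path) -> None:
        payload = {
            "d": self.d.round(12).to_dict(),
            "a": self.a.round(12).to_dict(),
            "t": self.t.round(12).to_dict(),
            "lam": self.lam.round(12).to_dict(),
            "beta_a": self.beta_a.round(12).to_dict(),
            "beta_t": self.beta_t.round(12).to_dict(),
            "cluster_label": {k: int(v) for k, v in self.cluster_label.items()},
            "designated_roles": self.designated_roles,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            d=pd.Series(payload["d"]),
            a=pd.Series(payload["a"]),
            t=pd.Series(payload["t"]),
            lam=pd.Series(payload["lam"]),
            beta_a=pd.Series(payload["beta_a"]),
            beta_t=pd.Series(payload["beta_t"]),
            cluster_label=pd.Series(payload["cluster_label"], dtype=int),
            designated_roles=payload["designated_roles"],
        )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[CohortTable, ProteinMatrix, SyntheticTruth]:
    """Generate one cohort; bit-identical for identical config (incl. seed).

    Protein value for participant i, protein j:

        x_ij = mu_j + lambda_j * d_i + beta_a_j * a_i + beta_t_j * t_i + eps_ij

    with eps ~ N(0, noise_sd^2), and d_i a linear predictor in standardized
    age, sex and log-ventricular volume plus N(0, dilution_sd^2) noise (and
    a small additive genotype term for the dilution-acting variant).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    p = config.n_proteins

    pid = pd.Index([f"S{i:04d}" for i in range(n)], name="participant_id")
    protein_ids = pd.Index([f"P{j:04d}" for j in range(p)], name="protein_id")

    # --- covariates -------------------------------------------------------
    age = rng.normal(68.2, 12.0, n).clip(40, 95)
    sex = (rng.random(n) < 0.533).astype(float)  # 1 = male
    education = rng.normal(12.4, 3.75, n).clip(6, 25)
    icv = rng.normal(1450.0, 140.0, n).clip(1000)
    gm_volume = (0.42 * icv + rng.normal(0.0, 40.0, n)).clip(300)
    log_vent = np.log(30.0) + 0.02 * (age - 68.2) + rng.normal(0.0, 0.45, n)
    ventricle_volume = np.exp(log_vent)

    snp_dilution = rng.binomial(2, config.genotype_maf, n).astype(float)
    snp_direct = rng.binomial(2, config.genotype_maf, n).astype(float)

    # --- latent factors ---------------------------------------------------
    d = (
        config.age_effect * _zscore(age)
        + config.sex_effect * (sex - sex.mean())
        + config.ventricle_effect * _zscore(np.log(ventricle_volume))
        + config.genotype_dilution_effect * (snp_dilution - snp_dilution.mean())
        + rng.normal(0.0, config.dilution_sd, n)
    )
    rho = config.burden_correlation
    za = rng.normal(size=n)
    zt = rho * za + np.sqrt(1.0 - rho**2) * rng.normal(size=n)
    a_burden = za
    t_burden = zt
    # Non-disease "pathway" factor shared between the pg/ml tau biomarker
    # and its specific reference candidates (the analogue of two proteins
    # co-varying through a common production pathway, as Abeta40 does with
    # Abeta42).  Single references that carry it can outperform the mean
    # standardized level, which barely contains it.
    w_pathway = rng.normal(size=n) * config.pathway_sd

    # --- protein panel ----------------------------------------------------
    sizes = config.resolved_cluster_sizes()
    loadings = config.resolved_loadings()
    cluster_label = np.repeat(np.arange(config.n_clusters), sizes)
    lam = loadings[cluster_label] + rng.normal(0.0, config.loading_jitter_sd, p)
    beta_a = np.zeros(p)
    beta_t = np.zeros(p)

    ref_cluster = int(np.argmax(loadings))
    order = np.argsort(loadings)
    mid_cluster = int(order[len(order) // 2])
    if mid_cluster == ref_cluster and config.n_clusters > 1:
        mid_cluster = int(order[len(order) // 2 - 1])

    def _cluster_members(c: int) -> np.ndarray:
        return np.flatnonzero(cluster_label == c)

    mid = _cluster_members(mid_cluster)
    ref = _cluster_members(ref_cluster)
    max_lam = float(loadings.max())

    roles: dict[str, object] = {}
    k = 0

    def _take(name: str) -> int:
        nonlocal k
        j = int(mid[min(k, len(mid) - 1)])
        k += 1
        roles[name] = str(protein_ids[j])
        return j

    j_ptau = _take("ptau181")
    lam[j_ptau] = 0.5 * max_lam
    beta_t[j_ptau] = config.effect_tau

    j_ab42 = _take("abeta42")
    lam[j_ab42] = 0.35 * max_lam
    beta_a[j_ab42] = config.effect_amyloid

    # Small disease module sharing the tau effect: genuinely disease-driven
    # protein-protein correlation that must survive reference adjustment.
    module = []
    for i in range(3):
        jm = _take(f"disease_module_{i}")
        lam[jm] = 0.2 * max_lam
        beta_t[jm] = 0.6 * config.effect_tau
        module.append(str(protein_ids[jm]))
    roles["disease_module"] = module
    for key in list(roles):
        if key.startswith("disease_module_"):
            del roles[key]

    j_ab40 = int(ref[0])
    roles["abeta40"] = str(protein_ids[j_ab40])
    lam[j_ab40] = max_lam  # strongly dilution-loaded, disease-free
    j_pqtl = int(ref[min(1, len(ref) - 1)])
    roles["pqtl_target"] = str(protein_ids[j_pqtl])
    # Specific reference candidates: reference-cluster proteins that also
    # carry the pathway factor shared with the pg/ml tau biomarker.
    specific = ref[2:12] if len(ref) > 2 else ref[:1]
    roles["specific_candidates"] = [str(protein_ids[j]) for j in specific]
    roles["reference_candidates"] = [str(protein_ids[j]) for j in ref]
    roles["reference_cluster"] = ref_cluster
    w_loading = np.zeros(p)
    w_loading[specific] = 0.5 * max_lam

    mu = rng.normal(0.0, 0.5, p)
    eps = rng.normal(0.0, config.noise_sd, size=(n, p))
    values = (
        mu[None, :]
        + np.outer(d, lam)
        + np.outer(a_burden, beta_a)
        + np.outer(t_burden, beta_t)
        + np.outer(w_pathway, w_loading)
        + eps
    )
    values[:, j_pqtl] += config.genotype_direct_effect * (
        snp_direct - snp_direct.mean()
    )
    npx_ab40_centered = values[:, j_ab40] - mu[j_ab40]

    # --- below-LOD censoring ---------------------------------------------
    if config.lod_quantile > 0:
        lod = np.quantile(values, config.lod_quantile, axis=0)
        values = np.where(values < lod[None, :], np.nan, values)

    # --- pg/ml biomarkers and PET measures --------------------------------
    d_c = d - d.mean()
    u_t = t_burden + rng.normal(0.0, config.pet_noise_sd, n)
    u_a = a_burden + rng.normal(0.0, config.pet_noise_sd, n)
    q_t = float(np.quantile(u_t, 1.0 - config.tau_prevalence))
    q_a = float(np.quantile(u_a, 1.0 - config.amyloid_prevalence))

    # Continuous PET measures: monotone in the noisy latent burden, anchored
    # so that the conventional cutoffs sit at the prevalence quantile.
    dt = u_t - q_t
    tau_pet_suvr = 1.36 + np.where(dt > 0, 0.55 * dt, 0.12 * dt) + rng.normal(
        0.0, 0.02, n
    )
    da = u_a - q_a
    amyloid_centiloid = 20.0 + np.where(da > 0, 45.0 * da, 18.0 * da) + rng.normal(
        0.0, 2.0, n
    )

    # pg/ml immunoassay biomarkers.  P-tau181 rises exponentially with tau
    # burden (right-skewed, as in real cohorts: negatives ~19 +/- 8,
    # positives ~37 +/- 16 pg/ml) and is additively confounded by dilution
    # and the shared pathway factor.  Abeta40 is tied directly to its NPX
    # panel analogue (shared dilution and measurement component), and
    # Abeta42 inherits Abeta40's non-disease variation through the ratio.
    ptau181 = (
        12.5
        + 6.0 * np.exp(0.9 * t_burden)
        + 4.5 * d_c
        + 2.5 * w_pathway
        + rng.normal(0.0, 1.5, n)
    ).clip(1.0)
    abeta40_pgml = (18000.0 * (1.0 + 0.16 * npx_ab40_centered)).clip(2000.0)
    f_a = expit(1.8 * da)
    ratio = (0.100 - 0.050 * f_a + rng.normal(0.0, 0.006, n)).clip(0.02)
    abeta42 = abeta40_pgml * ratio

    # --- diagnosis and conversion ----------------------------------------
    sev = t_burden + 0.5 * a_burden + rng.normal(0.0, 1.0, n)
    qs = np.quantile(sev, [0.32, 0.47, 0.71])
    diagnosis = np.select(
        [sev < qs[0], sev < qs[1], sev < qs[2]],
        ["NC", "SCD", "MCI"],
        default="Dementia",
    )
    other = rng.random(n) < 0.05
    diagnosis = np.where(other, "Other", diagnosis)

    eligible = ~np.isin(diagnosis, ["Dementia", "Other"])
    u_c = t_burden + rng.normal(0.0, config.pet_noise_sd, n)
    conv = np.full(n, np.nan)
    if eligible.sum() > 1:
        q_c = np.quantile(u_c[eligible], 1.0 - config.conversion_prevalence)
        conv[eligible] = (u_c[eligible] > q_c).astype(float)

    cohort = CohortTable(
        pd.DataFrame(
            {
                "age": age,
                "sex": sex,
                "education": education,
                "diagnosis": diagnosis,
                "icv": icv,
                "gm_volume": gm_volume,
                "ventricle_volume": ventricle_volume,
                "ptau181": ptau181,
                "abeta42": abeta42,
                "abeta40": abeta40_pgml,
                "abeta_ratio": abeta42 / abeta40_pgml,
                "tau_pet_suvr": tau_pet_suvr,
                "amyloid_centiloid": amyloid_centiloid,
                "tau_pet_pos": (tau_pet_suvr > 1.36).astype(float),
                "abeta_pet_pos": (amyloid_centiloid > 20.0).astype(float),
                "add_conversion": conv,
                "snp_dilution": snp_dilution,
                "snp_direct": snp_direct,
            },
            index=pid,
        )
    )

    panel = pd.Series(
        [f"panel_{1 + (j % 8)}" for j in range(p)], index=protein_ids, name="panel"
    )
    matrix = ProteinMatrix(pd.DataFrame(values, index=pid, columns=protein_ids), panel)
    truth = SyntheticTruth(
        d=pd.Series(d, index=pid, name="d"),
        a=pd.Series(a_burden, index=pid, name="a"),
        t=pd.Series(t_burden, index=pid, name="t"),
        lam=pd.Series(lam, index=protein_ids, name="lambda"),
        beta_a=pd.Series(beta_a, index=protein_ids, name="beta_a"),
        beta_t=pd.Series(beta_t, index=protein_ids, name="beta_t"),
        cluster_label=pd.Series(cluster_label, index=protein_ids, name="cluster"),
        designated_roles=roles,
    )
    return cohort, matrix, truth


# ---------------------------------------------------------------------------
# Canned fixtures used throughout the test suite


def fixture_cohort(kind: str, seed: int = 0, **overrides):
    """Three canonical study conditions.

    ``"null"``: no dilution structure (all loadings zero) and no panel
    disease effects.  ``"dilution"``: dilution structure only (panel disease
    effects zero).  ``"dilution_disease"``: the full default generative
    model.  The pg/ml assay biomarkers always carry their disease signal;
    the fixture names describe the NPX panel.
    """
    if kind == "null":
        cfg = SimulationConfig(
            loading_by_cluster=(0.0,) * 10,
            effect_amyloid=0.0,
            effect_tau=0.0,
            genotype_dilution_effect=0.0,
            seed=seed,
        )
    elif kind == "dilution":
        cfg = SimulationConfig(effect_amyloid=0.0, effect_tau=0.0, seed=seed)
    elif kind == "dilution_disease":
        cfg = SimulationConfig(seed=seed)
    else:
        raise ValueError(f"unknown fixture kind: {kind!r}")
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return generate_cohort(cfg)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def config_from_dict(payload: dict) -> SimulationConfig:
    cfg = SimulationConfig(**payload)
    for name in ("cluster_sizes", "loading_by_cluster"):
        v = getattr(cfg, name)
        if v is not None:
            setattr(cfg, name, tuple(v))
    return cfg
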