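"""Partial correlations, ANCOVA group contrasts, pQTL and enrichment."""

import numpy as np
import pandas as pd
import pytest

from csfref import (
    ancova_group_compare,
    bootstrap_enrichment_test,
    partial_correlation,
    partial_correlation_matrix,
    pqtl_assoc,
)


def _idx(n):
    return [f"S{i}" for i in range(n)]


def test_no_covariates_equals_pearson():
    rng = np.random.default_rng(0)
    x = pd.Series(rng.normal(size=50), index=_idx(50))
    y = pd.Series(x + rng.normal(size=50), index=_idx(50))
    assert partial_correlation(x, y) == pytest.approx(
        np.corrcoef(x, y)[0, 1], abs=1e-12
    )


def test_identical_series_gives_one():
    rng = np.random.default_rng(1)
    x = pd.Series(rng.normal(size=40), index=_idx(40))
    c = pd.DataFrame({"c": rng.normal(size=40)}, index=_idx(40))
    assert partial_correlation(x, x, c) == pytest.approx(1.0)


def test_shared_cause_removed_by_conditioning():
    rng = np.random.default_rng(2)
    n = 2000
    z = rng.normal(size=n)
    x = pd.Series(z + rng.normal(size=n), index=_idx(n))
    y = pd.Series(z + rng.normal(size=n), index=_idx(n))
    c = pd.DataFrame({"z": z}, index=_idx(n))
    assert abs(partial_correlation(x, y, c)) < 0.05
    assert partial_correlation(x, y) > 0.3


def _precision_oracle(x, y, C):
    """Partial correlation from the inverse covariance matrix."""
    M = np.column_stack([x, y, C])
    P = np.linalg.inv(np.cov(M, rowvar=False))
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])


@pytest.mark.parametrize("seed", range(5))
def test_residual_method_matches_precision_matrix_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 80
    ncov = int(rng.integers(1, 4))
    C = rng.normal(size=(n, ncov))
    x = pd.Series(C @ rng.normal(size=ncov) + rng.normal(size=n), index=_idx(n))
    y = pd.Series(C @ rng.normal(size=ncov) + rng.normal(size=n), index=_idx(n))
    got = partial_correlation(x, y, pd.DataFrame(C, index=_idx(n)))
    assert got == pytest.approx(_precision_oracle(x, y, C), abs=1e-10)


def test_too_few_complete_cases_rejected():
    x = pd.Series([1.0, 2.0, 3.0], index=_idx(3))
    c = pd.DataFrame({"a": [1.0, 2.0, 1.0], "b": [0.0, 1.0, 2.0]}, index=_idx(3))
    with pytest.raises(ValueError):
        partial_correlation(x, x, c)


def test_matrix_symmetric_unit_diagonal(disease_split):
    ds = disease_split
    z = ds["z_train"].values.fillna(0.0)
    cols = list(z.columns[:6])
    covars = ds["cohort_train"].df[["age", "sex"]].astype(float)
    without, with_ref = partial_correlation_matrix(
        z[cols], covars, reference=ds["level_train"].y
    )
    for pcm in (without, with_ref):
        M = pcm.matrix.to_numpy()
        assert np.allclose(M, M.T, atol=1e-12)
        assert np.allclose(np.diag(M), 1.0)
        assert np.all(np.abs(M) <= 1 + 1e-12)


def test_dilution_correlation_attenuates_disease_persists(disease_split):
    """Conditioning on a reference kills dilution-driven correlations but
    leaves genuinely disease-driven ones."""
    ds = disease_split
    roles = ds["truth"].designated_roles
    z = ds["z_train"].values.fillna(0.0)
    covars = ds["cohort_train"].df[["age", "sex"]].astype(float)
    dil_pair = roles["reference_candidates"][20:22]
    dis_pair = roles["disease_module"][:2]
    cols = list(dil_pair) + list(dis_pair)
    without, with_ref = partial_correlation_matrix(
        z[cols], covars, reference=ds["level_train"].y
    )
    dil_before = without.matrix.loc[dil_pair[0], dil_pair[1]]
    dil_after = with_ref.matrix.loc[dil_pair[0], dil_pair[1]]
    dis_before = without.matrix.loc[dis_pair[0], dis_pair[1]]
    dis_after = with_ref.matrix.loc[dis_pair[0], dis_pair[1]]
    assert dil_before > 0.3
    assert abs(dil_after) < 0.15
    assert dis_after > 0.5 * dis_before


def test_independent_noise_covariate_barely_moves_coefficient():
    rng = np.random.default_rng(7)
    n = 2000
    z = rng.normal(size=n)
    x = pd.Series(z + rng.normal(size=n), index=_idx(n))
    y = pd.Series(z + rng.normal(size=n), index=_idx(n))
    c0 = pd.DataFrame({"a": rng.normal(size=n)}, index=_idx(n))
    c1 = c0.assign(noise=rng.normal(size=n))
    r0 = partial_correlation(x, y, c0)
    r1 = partial_correlation(x, y, c1)
    assert abs(r0 - r1) < 3 / np.sqrt(n)


def test_ancova_detects_planted_shift():
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 300
        g = np.repeat(["A", "B", "C"], n // 3)
        age = rng.normal(70, 8, n)
        y = 0.02 * age + rng.normal(size=n) + (g == "C") * 1.0
        res = ancova_group_compare(
            pd.Series(y, index=_idx(n)),
            pd.Series(g, index=_idx(n)),
            pd.DataFrame({"age": age, "sex": rng.integers(0, 2, n)},
                         index=_idx(n)),
        )
        sig = res.contrasts.query("group_a == 'A' and group_b == 'C'")["q"]
        hits += float(sig.iloc[0]) < 0.05
    assert hits == 5


def test_ancova_null_groups_similar_means():
    rng = np.random.default_rng(3)
    n = 300
    y = pd.Series(rng.normal(size=n), index=_idx(n))
    g = pd.Series(rng.choice(["A", "B"], size=n), index=_idx(n))
    covars = pd.DataFrame(
        {"age": rng.normal(70, 8, n), "sex": rng.integers(0, 2, n)}, index=_idx(n)
    )
    res = ancova_group_compare(y, g, covars)
    means = res.group_stats["adj_mean"]
    assert abs(means["A"] - means["B"]) < 0.3


def test_ancova_input_validation():
    y = pd.Series(np.arange(10.0), index=_idx(10))
    covars = pd.DataFrame({"age": np.arange(10.0)}, index=_idx(10))
    with pytest.raises(ValueError, match="two groups"):
        ancova_group_compare(y, pd.Series(["A"] * 10, index=_idx(10)), covars)
    g = pd.Series(["A"] * 8 + ["B"] * 2, index=_idx(10))
    with pytest.raises(ValueError, match="n < 3"):
        ancova_group_compare(y, g, covars)


def test_pqtl_attenuation_and_persistence():
    """A variant acting through dilution attenuates when the reference is
    added; a direct-effect variant does not."""
    from csfref import (
        apply_standardization,
        fit_standardization,
        fixture_cohort,
        mean_csf_level,
    )

    cohort_t, matrix, truth = fixture_cohort(
        "dilution_disease", seed=17, genotype_dilution_effect=0.6,
        lod_quantile=0.0,
    )
    roles = truth.designated_roles
    cohort = cohort_t.df
    zm = apply_standardization(fit_standardization(matrix), matrix)
    z = zm.values
    covars = cohort[["age", "sex"]].astype(float)
    ref = mean_csf_level(zm).y

    dil = pqtl_assoc(z[roles["abeta40"]], cohort["snp_dilution"], covars, ref)
    assert abs(dil.loc["with_reference", "beta"]) < 0.5 * abs(
        dil.loc["without_reference", "beta"]
    )
    direct = pqtl_assoc(z[roles["pqtl_target"]], cohort["snp_direct"], covars,
                        ref)
    assert direct.loc["with_reference", "beta"] == pytest.approx(
        direct.loc["without_reference", "beta"], rel=0.35
    )
    assert direct.loc["with_reference", "p"] < 0.01


def test_pqtl_monomorphic_rejected():
    y = pd.Series(np.random.default_rng(0).normal(size=20), index=_idx(20))
    dos = pd.Series(np.ones(20), index=_idx(20))
    with pytest.raises(ValueError, match="monomorphic"):
        pqtl_assoc(y, dos, pd.DataFrame(index=_idx(20)))


def test_enrichment_detects_planted_shift():
    rng = np.random.default_rng(5)
    n_bg = 300
    bg = [f"P{i}" for i in range(n_bg)]
    features = pd.DataFrame(
        {"f1": rng.random(n_bg), "f2": rng.random(n_bg)}, index=bg
    )
    subset = bg[:40]
    features.loc[subset, "f1"] += 0.4  # strong planted shift
    res = bootstrap_enrichment_test(subset, bg, features, n_boot=2000, seed=0)
    assert res.loc["f1", "q"] < 0.05
    assert res.loc["f2", "p"] > 0.05


def test_enrichment_near_degenerate_subset():
    rng = np.random.default_rng(6)
    bg = [f"P{i}" for i in range(50)]
    features = pd.DataFrame({"f": rng.random(50)}, index=bg)
    res = bootstrap_enrichment_test(bg[:-1], bg, features, n_boot=500, seed=1)
    assert res["p"].iloc[0] > 0.3
    with pytest.raises(ValueError):
        bootstrap_enrichment_test(bg, bg, features, n_boot=10, seed=0)
    with pytest.raises(ValueError):
        bootstrap_enrichment_test([], bg, features, n_boot=10, seed=0)
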