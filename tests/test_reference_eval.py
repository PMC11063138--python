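"""AUC machinery, resampling tests, SVD composites and selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from csfref import (
    CohortTable,
    ModelSpec,
    SEARCH_MODELS,
    auc,
    bh_adjust,
    bootstrap_roc_test,
    cv_auc,
    evaluate_reference_grid,
    oob_bootstrap_eval,
    select_candidates,
    svd_composite,
)
from csfref._logistic import fit_logistic


def _pairwise_auc(scores, labels):
    """Exhaustive pairwise-comparison oracle with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_hand_example():
    assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
    assert auc([1, 2, 3, 10], [0, 0, 1, 1]) == 1.0
    assert auc([1.0, 1.0, 1.0, 1.0], [0, 0, 1, 1]) == 0.5


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        auc([0.1, 0.2], [1, 1])


@pytest.mark.parametrize("seed", range(5))
def test_auc_matches_pairwise_and_sklearn(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 200))
    scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    got = auc(scores, labels)
    assert got == pytest.approx(_pairwise_auc(scores, labels), abs=1e-12)
    assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_logistic_matches_sklearn():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(300, 3))
    y = (rng.random(300) < 1 / (1 + np.exp(-(0.5 + X @ [1.0, -0.7, 0.2])))).astype(
        float
    )
    ours = fit_logistic(np.hstack([np.ones((300, 1)), X]), y)
    sk = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-10).fit(X, y)
    assert np.allclose(ours[0], sk.intercept_[0], atol=1e-5)
    assert np.allclose(ours[1:], sk.coef_[0], atol=1e-5)


def _toy_cohort(n=300, seed=0, separation=2.0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n).astype(float)
    x = y * separation + rng.normal(size=n)
    return CohortTable(
        pd.DataFrame(
            {
                "age": rng.normal(70, 8, n),
                "sex": rng.integers(0, 2, n).astype(float),
                "ptau181": x,
                "tau_pet_pos": y,
            },
            index=[f"S{i}" for i in range(n)],
        )
    )


def test_cv_auc_perfect_predictor():
    cohort = _toy_cohort(separation=50.0, seed=1)
    spec = ModelSpec("m", "ptau181", "tau_pet_pos")
    a, folds, _ = cv_auc(spec, cohort, folds=5, seed=0)
    assert a == 1.0
    assert len(folds) == 5


def test_cv_auc_null_near_half():
    aucs = []
    for seed in range(4):
        cohort = _toy_cohort(separation=0.0, seed=seed)
        spec = ModelSpec("m", "ptau181", "tau_pet_pos")
        a, _, _ = cv_auc(spec, cohort, folds=5, seed=seed)
        aucs.append(a)
    assert abs(np.mean(aucs) - 0.5) < 0.07


def test_cv_auc_deterministic():
    cohort = _toy_cohort(seed=3)
    spec = ModelSpec("m", "ptau181", "tau_pet_pos")
    a1, f1, _ = cv_auc(spec, cohort, folds=10, seed=5)
    a2, f2, _ = cv_auc(spec, cohort, folds=10, seed=5)
    assert a1 == a2
    assert np.array_equal(f1, f2)


def test_oob_bootstrap_properties():
    cohort = _toy_cohort(separation=50.0, seed=2, n=200)
    spec = ModelSpec("m", "ptau181", "tau_pet_pos")
    d1 = oob_bootstrap_eval(spec, cohort, n_iter=50, seed=4)
    d2 = oob_bootstrap_eval(spec, cohort, n_iter=50, seed=4)
    assert np.array_equal(d1, d2)
    assert np.all(d1 == 1.0)
    # Never-selected fraction of the same resampling scheme ~ 1/e.
    rng = np.random.default_rng(0)
    n = 200
    fracs = [
        len(np.setdiff1d(np.arange(n), rng.integers(0, n, n))) / n
        for _ in range(200)
    ]
    assert np.mean(fracs) == pytest.approx(np.exp(-1), abs=0.01)


def test_bootstrap_roc_test_identical_scores_gives_one():
    rng = np.random.default_rng(0)
    s = rng.normal(size=100)
    y = rng.integers(0, 2, size=100)
    assert bootstrap_roc_test(s, s, y, n_iter=200, seed=0) == 1.0


def test_bootstrap_roc_test_detects_planted_improvement():
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 400
        y = rng.integers(0, 2, size=n).astype(float)
        truth = y * 2.0 + rng.normal(size=n)
        weak = truth + 2.5 * rng.normal(size=n)
        strong = truth + 0.3 * rng.normal(size=n)
        p = bootstrap_roc_test(weak, strong, y, n_iter=500, seed=seed)
        hits += p < 0.05
    assert hits >= 4


def test_bootstrap_roc_test_unpaired_rejected():
    with pytest.raises(ValueError):
        bootstrap_roc_test([1, 2], [1, 2, 3], [0, 1], n_iter=10, seed=0)


def _bh_oracle(p):
    """Brute-force step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_examples_and_oracle():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)
    rng = np.random.default_rng(1)
    for _ in range(10):
        p = rng.random(int(rng.integers(1, 40)))
        assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_svd_composite_single_and_duplicate_columns():
    rng = np.random.default_rng(2)
    x = pd.Series(rng.normal(size=50), index=[f"S{i}" for i in range(50)])
    single = svd_composite(x.to_frame("A"))
    zx = (x - x.mean()) / x.std(ddof=1)
    assert np.allclose(single, zx, atol=1e-10)
    two = svd_composite(pd.DataFrame({"A": x, "B": x}))
    assert abs(np.corrcoef(two, x)[0, 1]) == pytest.approx(1.0, abs=1e-10)
    assert np.corrcoef(two, x)[0, 1] > 0  # sign convention


def test_svd_composite_negation_invariance_vs_eigen_oracle():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(
        rng.normal(size=(60, 3)) + rng.normal(size=(60, 1)),
        index=[f"S{i}" for i in range(60)],
        columns=["A", "B", "C"],
    )
    comp = svd_composite(X)
    flipped = X.copy()
    flipped["B"] = -flipped["B"]
    comp_f = svd_composite(flipped)
    assert abs(np.corrcoef(comp, comp_f)[0, 1]) == pytest.approx(1.0, abs=1e-10)
    # Eigen-decomposition oracle: projection onto the leading eigenvector
    # of the correlation matrix spans the same direction.
    Z = (X - X.mean()) / X.std(ddof=1)
    w, v = np.linalg.eigh(np.corrcoef(Z.to_numpy(), rowvar=False))
    lead = Z.to_numpy() @ v[:, np.argmax(w)]
    assert abs(np.corrcoef(comp, lead)[0, 1]) == pytest.approx(1.0, abs=1e-10)


def test_degenerate_reference_rejected():
    cohort = _toy_cohort(seed=6)
    z = pd.DataFrame({"PX": cohort.df["ptau181"]}, index=cohort.participant_ids)
    spec = ModelSpec("m", "ptau181", "tau_pet_pos", reference="protein:PX")
    with pytest.raises(ValueError, match="predictor"):
        cv_auc(spec, cohort, z, None, folds=5, seed=0)


def test_reference_improves_tau_model_on_fixture(disease_split):
    """Dilution-loaded references lift the tau model over no reference."""
    ds = disease_split
    refs = ds["truth"].designated_roles["specific_candidates"][:2]
    result = evaluate_reference_grid(
        [SEARCH_MODELS[0]],
        [f"protein:{r}" for r in refs],
        ds["cohort_train"],
        ds["z_train"].values.fillna(0.0),
        ds["level_train"].y,
        scheme="holdout",
        test_cohort=ds["cohort_test"],
        z_test=ds["z_test"].values.fillna(0.0),
        level_test=ds["level_test"].y,
        n_iter=500,
        seed=0,
    )
    t = result.table.set_index("reference")
    base = t.loc["none", "auc"]
    for r in refs:
        assert t.loc[f"protein:{r}", "auc"] > base
    # Adjusted p-values never smaller than raw ones.
    sub = result.table.dropna(subset=["p_vs_none"])
    assert (sub["q_vs_none"] >= sub["p_vs_none"] - 1e-12).all()


def test_single_reference_beats_mean_level_with_shared_covariation():
    """A reference sharing the biomarker's non-disease pathway beats the
    global mean level, which hardly contains that pathway factor."""
    from csfref import (
        apply_standardization,
        fit_standardization,
        fixture_cohort,
        mean_csf_level,
        train_test_split,
    )

    wins = 0
    for seed in range(3):
        cohort, matrix, truth = fixture_cohort(
            "dilution_disease", seed=30 + seed, noise_sd=0.45,
            lod_quantile=0.0,
        )
        (ctr, mtr), (cte, mte) = train_test_split(cohort, matrix, seed=seed)
        model = fit_standardization(mtr)
        ztr = apply_standardization(model, mtr)
        zte = apply_standardization(model, mte)
        ref = truth.designated_roles["specific_candidates"][0]
        res = evaluate_reference_grid(
            [SEARCH_MODELS[0]],
            ["mean_level", f"protein:{ref}"],
            ctr,
            ztr.values,
            mean_csf_level(ztr).y,
            scheme="holdout",
            test_cohort=cte,
            z_test=zte.values,
            level_test=mean_csf_level(zte).y,
            n_iter=200,
            seed=seed,
        )
        t = res.table.set_index("reference")["auc"]
        wins += t[f"protein:{ref}"] > t["mean_level"]
    assert wins >= 2


def test_select_candidates_toy_grid():
    maps = pd.DataFrame(
        {
            "auc_as_reference_tau_model": [0.90, 0.85, 0.91, 0.80, 0.92],
            "auc_as_reference_abeta_model": [0.95, 0.96, 0.94, 0.90, 0.97],
        },
        index=["P1", "P2", "P3", "P4", "P5"],
    )
    clusters = pd.Series([1, 1, 1, 2, 1], index=maps.index)
    baselines = {"ptau_taupet": 0.86, "abeta_abpet": 0.93}
    # P2 fails the tau gain; P4 is outside cluster 1; P5 not on the panel.
    out = select_candidates(clusters, maps, baselines, ["P1", "P2", "P3", "P4"],
                            cluster_id=1)
    assert list(out.index) == ["P3", "P1"] or list(out.index) == ["P1", "P3"]
    assert out["mean_gain"].is_monotonic_decreasing
    empty = select_candidates(clusters, maps, baselines, ["PX"], cluster_id=1)
    assert len(empty) == 0
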