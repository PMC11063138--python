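import pytest

from csfref import (
    SimulationConfig,
    apply_standardization,
    detectability_filter,
    fit_standardization,
    fixture_cohort,
    generate_cohort,
    mean_csf_level,
    train_test_split,
)


@pytest.fixture(scope="session")
def small_sim():
    """Small cohort for fast unit tests (160 participants, 60 proteins)."""
    cfg = SimulationConfig(
        n_participants=160, n_proteins=60, n_clusters=6, seed=42
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def disease_sim():
    """Default-size dilution+disease cohort."""
    return fixture_cohort("dilution_disease", seed=0)


@pytest.fixture(scope="session")
def disease_split(disease_sim):
    """Train/test split of the dilution+disease cohort with fitted
    standardization and mean CSF levels."""
    cohort, matrix, truth = disease_sim
    (ctr, mtr), (cte, mte) = train_test_split(cohort, matrix, seed=1)
    mtr = detectability_filter(mtr, 0.75)
    mte = mte.select_proteins(mtr.protein_ids)
    model = fit_standardization(mtr)
    ztr = apply_standardization(model, mtr)
    zte = apply_standardization(model, mte)
    return {
        "truth": truth,
        "cohort_train": ctr,
        "cohort_test": cte,
        "z_train": ztr,
        "z_test": zte,
        "level_train": mean_csf_level(ztr),
        "level_test": mean_csf_level(zte),
        "std_model": model,
    }


@pytest.fixture(scope="session")
def disease_maps(disease_split):
    """Six metric maps on the training half (shared; ~10 s to compute)."""
    from csfref import metric_maps

    return metric_maps(
        disease_split["z_train"],
        disease_split["level_train"],
        disease_split["cohort_train"],
        fold_seed=7,
    )
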