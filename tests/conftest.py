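import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design():
    from uncles.simulate import PlantedDesign

    return PlantedDesign(
        n_genes=200,
        n_datasets=4,
        min_presence=3,
        clusters=[(30, "down"), (40, "up")],
        anticorrelated_pairs=[(0, 1)],
        noise_sd=0.2,
        missing_fraction=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_collection(small_design):
    """Raw planted collection with truth, small enough for every unit test."""
    from uncles.simulate import generate_collection

    return generate_collection(small_design)


@pytest.fixture(scope="session")
def normalised_collection(small_collection):
    from uncles.preprocess import build_collection, normalise_dataset

    collection, truth = small_collection
    norm = [normalise_dataset(ds) for ds in collection.datasets]
    return build_collection(norm, collection.min_presence), truth


@pytest.fixture(scope="session")
def clinical_cohort():
    """Cohort with one prognostic signature (beta=1.5) and one null signature."""
    from uncles.simulate import ClinicalDesign, generate_clinical

    design = ClinicalDesign(
        n_samples=500,
        signature_effects={"hyp": 1.5, "null": 0.0},
        er_fold_changes={"hyp": 2.0},
        censoring_rate=0.3,
        n_background_genes=400,
        seed=7,
    )
    signatures = {
        "hyp": [f"HYP{i:03d}" for i in range(30)],
        "null": [f"NUL{i:03d}" for i in range(25)],
    }
    cohort, truth = generate_clinical(design, signatures)
    return cohort, truth, signatures
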