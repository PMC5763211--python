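import pytest

from psbinder import PsbModel, SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset for fast pipeline tests."""
    return generate_dataset(SyntheticSpec(n_per_class=40, seed=11))


@pytest.fixture(scope="session")
def standin_dataset():
    """Synthetic stand-in training set at the published study's shape:
    104 binders + 104 non-binders, generator defaults, dataset seed 0."""
    return generate_dataset(SyntheticSpec(n_per_class=104, seed=0))


@pytest.fixture(scope="session")
def odpc_runs(standin_dataset):
    """Full DPC pipeline (selection + grid search + CV) on the stand-in
    dataset over 10 evaluation seeds; shared by the evaluation tests."""
    return [
        PsbModel(standin_dataset, block="dpc").fit(seed=s) for s in range(10)
    ]


@pytest.fixture(scope="session")
def oaac_runs(standin_dataset):
    """AAC-block pipeline on the stand-in dataset over 10 seeds."""
    return [
        PsbModel(standin_dataset, block="aac").fit(seed=s) for s in range(10)
    ]
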