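import pytest

from flavorquant import generate_validation_study, load_panel, well_behaved


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def small_study(panel):
    """Two well-behaved batches; enough for batch assembly and drift."""
    inst = well_behaved(panel)
    return generate_validation_study(
        inst, panel, seed=11, n_batches=2,
        include_dilution_checks=False, include_stability=False,
    )


@pytest.fixture(scope="session")
def batch_one(panel, small_study):
    from flavorquant.quantify import assemble_batch

    manifest = small_study.manifest
    m1 = manifest[manifest["batch_id"] == "B1"]
    p1 = small_study.peaks[small_study.peaks["sample_id"].isin(m1["sample_id"])]
    return m1, p1, assemble_batch(m1, p1, panel)
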