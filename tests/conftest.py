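import pytest

from microtese.datasets import reference_cohort


@pytest.fixture(scope="session")
def reference_records():
    """Reconstructed 158-patient cohort matching the published count margins."""
    return reference_cohort()


@pytest.fixture()
def reference_csv(tmp_path, reference_records):
    from microtese.io import write_patient_csv

    path = tmp_path / "cohort.csv"
    write_patient_csv(reference_records, path)
    return path
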