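import pandas as pd
import pytest

from methdrift.datasets import load_example_cohort


@pytest.fixture(scope="session")
def example_cohort():
    """Synthetic study-shaped cohort: 79 patients, 16 pairs, 13 loci,
    3 THBS1 measurements missing across the pairs."""
    return load_example_cohort()


@pytest.fixture
def toy_matrix_tsv(tmp_path):
    path = tmp_path / "toy.tsv"
    path.write_text(
        "sample_id\tMLH1\tMGMT\n"
        "S1\t10.5\t20\n"
        "S2\tNA\t3.25\n"
        "S3\t99.9\t0\n"
    )
    return path


@pytest.fixture
def paired_meta():
    """Two patients, each with a primary and a metastasis sample."""
    return pd.DataFrame({
        "sample_id": ["A_P", "A_M", "B_P", "B_M"],
        "patient_id": ["A", "A", "B", "B"],
        "role": ["primary", "metastasis", "primary", "metastasis"],
        "stage": [4, 4, 4, 4],
        "location": ["distal"] * 4,
        "liver_metastasis": ["present", "not_applicable"] * 2,
        "timing": ["synchronous", "synchronous", "metachronous", "metachronous"],
        "interval_months": [3.0, 3.0, 46.0, 46.0],
    })
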