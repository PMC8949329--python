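import numpy as np
import pytest
from hypothesis import settings

from tmbgrid import TMBGrid, generate_synthetic_cohort, preset_cohort_spec

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_grid():
    return TMBGrid()


@pytest.fixture(scope="session")
def preset_cohort():
    """Two-histology synthetic cohort: melanoma-like (high TMB) and rcc-like (low)."""
    return generate_synthetic_cohort(preset_cohort_spec(seed=0))


@pytest.fixture()
def toy_cohort_file(tmp_path):
    """Well-formed 6-row TSV cohort with two histologies."""
    path = tmp_path / "cohort.tsv"
    rows = [
        ("s1", "Melanoma", 22.0),
        ("s2", "Melanoma", 14.5),
        ("s3", "Melanoma", 9.0),
        ("s4", "Renal Cell Carcinoma", 1.2),
        ("s5", "Renal Cell Carcinoma", 2.4),
        ("s6", "Renal Cell Carcinoma", 0.8),
    ]
    lines = ["sample_id\tcancer_type\ttmb"]
    lines += [f"{s}\t{c}\t{t}" for s, c, t in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
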