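import numpy as np
import pandas as pd
import pytest

from translen import DesignTable, FeatureSpec, FixtureSpec, LengthTable, generate_fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_length_table(rows):
    """Build a LengthTable from (read_id, library_id, feature_id, five_p, three_p) tuples."""
    df = pd.DataFrame(rows, columns=["read_id", "library_id", "feature_id", "five_p", "three_p"])
    df["length"] = df["three_p"] - df["five_p"]
    df["adapter"] = False
    df["polya_pass"] = "unknown"
    return LengthTable(df)


@pytest.fixture
def two_by_two_design():
    return DesignTable(
        pd.DataFrame(
            {
                "library_id": ["ctrl_1", "ctrl_2", "treat_1", "treat_2"],
                "condition": ["control", "control", "treated", "treated"],
            }
        ),
        reference_condition="control",
    )


@pytest.fixture(scope="session")
def fixture_experiment(tmp_path_factory):
    """A session-wide synthetic BAM experiment with ground truth."""
    out = tmp_path_factory.mktemp("fixture_bam")
    spec = FixtureSpec(
        features=(
            FeatureSpec("tx_stable", 1200, reads_per_library=50),
            FeatureSpec("tx_decay", 1500, reads_per_library=50, truncation_frac=0.3, cds_start=400),
        ),
        n_control_libs=2,
        n_treated_libs=2,
    )
    paths = generate_fixtures(spec, seed=101, out_dir=out)
    return spec, paths
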