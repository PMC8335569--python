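import warnings

import numpy as np
import pandas as pd
import pytest

import mutcell as mc


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """The pipeline warns on small cohorts and dropped genes; tests that do
    not assert on warnings should not drown in them."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def planted_cohort():
    """n=200 cohort with three planted up-effects of +2 SD at 30% frequency."""
    truth = mc.make_truth(
        10, 30,
        planted=[(0, 2, 1, 2.0), (3, 7, 1, 2.0), (5, 11, -1, 2.0)],
        frequency=0.3,
        survival_betas={"C001": 1.0, "C002": -1.0},
        seed=42,
    )
    return mc.generate_cohort(200, 30, 10, truth, expression=True)


@pytest.fixture
def tiny_maf(tmp_path):
    lines = [
        "#version 2.4",
        "Hugo_Symbol\tCenter\tVariant_Classification\tTumor_Sample_Barcode",
        "TP53\tX\tMissense_Mutation\tS1",
        "TP53\tX\tSilent\tS2",
        "CDH1\tX\tNonsense_Mutation\tS2",
    ]
    path = tmp_path / "tiny.maf"
    path.write_text("\n".join(lines) + "\n")
    return path


def write_tsv(df: pd.DataFrame, path) -> str:
    df.to_csv(path, sep="\t", index_label=df.index.name or "id")
    return str(path)
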