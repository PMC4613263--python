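from pathlib import Path

import pandas as pd
import pytest

from spotdiff import synthdata

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_calls() -> pd.DataFrame:
    """Curated differential-expression calls from the rat cerebellum
    ontogeny dataset: per protein the printed regulation labels for the
    P7 and P637 contrasts, the spot volume quotient, the H count, the
    fingerprint score and the matched-peak count Qm."""
    return pd.read_csv(DATA_DIR / "cerebellum_reference_calls.tsv", sep="\t")


@pytest.fixture(scope="session")
def small_experiment():
    """A 50-protein synthetic experiment shared across read-only tests."""
    config = synthdata.SyntheticConfig(n_proteins=50, seed=7)
    gels, truths = synthdata.generate_experiment(config)
    return config, gels, truths
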