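import numpy as np
import pandas as pd
import pytest

from codonopt import (
    AnticodonCountTable,
    TranscriptSet,
    load_bundled_anticodons,
)


@pytest.fixture(scope="session")
def anticodon_table() -> pd.DataFrame:
    return load_bundled_anticodons()


@pytest.fixture(scope="session")
def isotype_map(anticodon_table) -> dict[str, str]:
    return dict(zip(anticodon_table["anticodon"], anticodon_table["amino_acid"]))


@pytest.fixture
def toy_transcripts() -> TranscriptSet:
    return TranscriptSet(
        records=[
            ("g1", "GCGGCGGACTAA"),
            ("g2", "ATGGACGACGCGTAA"),
        ]
    )


def make_count_table(counts: dict[str, dict[str, int]], isotype: dict[str, str]) -> AnticodonCountTable:
    """counts: replicate -> anticodon -> reads."""
    df = pd.DataFrame(counts).fillna(0)
    return AnticodonCountTable(counts=df, isotype=isotype)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
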