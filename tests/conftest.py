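import numpy as np
import pandas as pd
import pytest

from g4screen.screen_counts import CountMatrix, GuideLibrary


@pytest.fixture
def toy_library() -> GuideLibrary:
    """Three genes x two guides plus one non-targeting control."""
    rows = [
        ("G1_g1", "G1", "ACGTACGTACGTACGTACGT", False),
        ("G1_g2", "G1", "TTTTACGTACGTACGTACGT", False),
        ("G2_g1", "G2", "CCCCACGTACGTACGTACGT", False),
        ("G2_g2", "G2", "GGGGACGTACGTACGTACGT", False),
        ("G3_g1", "G3", "ACACACGTACGTACGTACGT", False),
        ("G3_g2", "G3", "GTGTACGTACGTACGTACGT", False),
        ("NT_1", "NT", "TGCATGCATGCATGCATGCA", True),
    ]
    return GuideLibrary(
        pd.DataFrame(rows, columns=["sgrna_id", "gene", "spacer", "is_nt"])
    )


def make_count_matrix(counts: dict[str, list[int]], guides: list[str]) -> CountMatrix:
    """CountMatrix from a sample->counts dict with default metadata."""
    df = pd.DataFrame(counts, index=pd.Index(guides, name="sgrna_id"))
    samples = pd.DataFrame(
        {
            "condition": ["na"] * len(counts),
            "day": [0] * len(counts),
            "replicate": list(range(1, len(counts) + 1)),
        },
        index=pd.Index(list(counts), name="sample"),
    )
    return CountMatrix(df, samples)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210507)
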