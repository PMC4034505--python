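import numpy as np
import pandas as pd
import pytest

from raaindex.aaindex import RESIDUES, IndexTable, load_raaindex


@pytest.fixture(scope="session")
def raaindex_table():
    return load_raaindex()


@pytest.fixture
def rng():
    return np.random.default_rng(20140511)


def make_random_table(rng: np.random.Generator, m: int, prefix: str = "RND") -> IndexTable:
    data = {f"{prefix}{j:03d}": rng.normal(size=20) for j in range(m)}
    return IndexTable(pd.DataFrame(data, index=list(RESIDUES)))


def format_aaindex_record(accession: str, values: dict[str, float], description: str = "synthetic entry") -> str:
    """Render one AAindex1 flat-file record (two ten-value rows under I)."""

    def fmt(v):
        return "NA" if isinstance(v, float) and np.isnan(v) else f"{v:.2f}"

    row1 = "  ".join(fmt(values[r]) for r in RESIDUES[:10])
    row2 = "  ".join(fmt(values[r]) for r in RESIDUES[10:])
    return (
        f"H {accession}\n"
        f"D {description}\n"
        "R \n"
        "A Doe, J.\n"
        "T A synthetic index for testing\n"
        "J None (2014)\n"
        "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
        f"   {row1}\n"
        f"   {row2}\n"
        "//\n"
    )
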