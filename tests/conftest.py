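import numpy as np
import pytest

from barcodekit.extraction import AmpliconLayout


def levenshtein(a: str, b: str) -> int:
    """Independent DP Levenshtein distance (test oracle)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@pytest.fixture
def layout():
    """A simple amplicon layout with 12-bp flanks around a 20-bp barcode."""
    return AmpliconLayout(
        upstream="TTGACTCGTACG", downstream="AGAGACCTTAAG", barcode_length=20
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_barcode(rng, length=20):
    return "".join("ACGT"[i] for i in rng.integers(4, size=length))
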