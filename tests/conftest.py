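import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from teacore.genotypes import _CALL_TO_CODE, GenotypeMatrix, LocusInfo


def matrix_from_calls(rows: dict[str, list[str]], loci=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {sample_id: ["1/1", "NA", ...]}."""
    samples = list(rows)
    n_loci = len(next(iter(rows.values())))
    if loci is None:
        loci = [LocusInfo(f"L{j + 1}") for j in range(n_loci)]
    codes = np.array(
        [[_CALL_TO_CODE[c] for c in rows[s]] for s in samples], dtype=np.int8
    )
    return GenotypeMatrix(samples, loci, codes)


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 loci covering all four call states."""
    return matrix_from_calls(
        {
            "s1": ["1/1", "1/2"],
            "s2": ["1/2", "NA"],
            "s3": ["2/2", "2/2"],
        }
    )
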