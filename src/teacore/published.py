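"""Published diversity statistics for the 45-marker tea core panel.

The 45 core SNP markers for *Camellia sinensis* cultivar identification
were published with their chromosome positions and per-locus diversity
statistics (MAF, Na, Ne, I, Ho, PIC, PI) estimated on 117 cultivars.
Those printed values are shipped here as package data: they are the
reference inputs for recomputing the panel's fingerprinting and
parentage-exclusion power without access to the raw genotypes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: The eight low-PI markers published as the primary DNA fingerprint set,
#: in their published selection order.
FINGERPRINT_MARKERS = [
    "1_SNP_2",
    "1_SNP_1",
    "3_SNP_14",
    "3_SNP_15",
    "1_SNP_13",
    "2_SNP_14",
    "1_SNP_5",
    "2_SNP_4",
]

#: Number of cultivars the published statistics were estimated on.
N_CULTIVARS = 117


def load_published_panel() -> pd.DataFrame:
    """The published 45-marker table, indexed by marker name.

    Columns: chrom, pos, maf, na, ne, shannon_i, ho, pic, pi — printed
    values at 3-decimal precision.
    """
    with resources.files(__package__).joinpath("data/tea_core_panel.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("name")
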