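import numpy as np
import pandas as pd
import pytest

from repeatqtl.fragtrace import Peak, PeakTrace
from repeatqtl.qtl import CrossData, GeneticMap


def make_trace(peaks, sample="s1", tissue="striatum"):
    return PeakTrace(sample, tissue, tuple(Peak(int(l), float(h)) for l, h in peaks))


def make_cross(genotypes, phenotype, chrom_pos=None, bp=None):
    """Build a CrossData from a {marker: [codes]} dict.

    ``chrom_pos`` maps marker -> (chrom, cm); defaults to a single
    chromosome with 10 cM spacing.
    """
    markers = list(genotypes)
    n = len(next(iter(genotypes.values())))
    ids = [f"i{k + 1}" for k in range(n)]
    if chrom_pos is None:
        chrom_pos = {m: ("1", 10.0 * j) for j, m in enumerate(markers)}
    table = pd.DataFrame(
        {
            "marker": markers,
            "chrom": [chrom_pos[m][0] for m in markers],
            "cm": [chrom_pos[m][1] for m in markers],
        }
    )
    if bp is not None:
        table["bp"] = [bp.get(m, np.nan) for m in markers]
    geno = pd.DataFrame(
        {m: pd.Series(genotypes[m], index=ids, dtype=object) for m in markers}
    )
    return CrossData(geno, GeneticMap(table), pd.Series(phenotype, index=ids, dtype=float))


@pytest.fixture
def toy_cross_8():
    """8-individual, fully typed two-marker cross with a fixed phenotype."""
    return make_cross(
        {
            "m1": ["BB", "BB", "BH", "BH", "BH", "HH", "HH", "BB"],
            "m2": ["BB", "BH", "BH", "HH", "BH", "HH", "BH", "BB"],
        },
        [2.3, 1.9, 1.4, 0.2, 1.1, -0.3, 0.9, 2.8],
    )
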