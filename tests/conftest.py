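import numpy as np
import pytest

from ampcnv import (
    Amplicon,
    AmpliconDesign,
    RunMatrix,
    make_design,
)
from ampcnv.simulate import make_gene_sizes


@pytest.fixture
def small_design() -> AmpliconDesign:
    """Ten amplicons: 6 on chr1 (two genes, two pools), 4 on chr2."""
    return make_design([3, 3, 4], ["GA", "GB", "GC"], n_chromosomes=2, n_pools=2)


@pytest.fixture
def flat_run(small_design) -> RunMatrix:
    """Noiseless run: 4 samples, every count 100."""
    n = len(small_design)
    return RunMatrix(
        design=small_design,
        sample_ids=["S1", "S2", "S3", "S4"],
        counts=np.full((n, 4), 100, dtype=np.int64),
        missing=np.zeros((n, 4), dtype=bool),
    )


@pytest.fixture(scope="session")
def panel_design() -> AmpliconDesign:
    """Panel-scale design: 2,394 amplicons with named genes of the sizes
    used in the desk-scale experiments; the 98-amplicon region sits alone
    on chrX."""
    special = {
        "G10": 10, "G58": 58, "G98": 98, "G25A": 25, "G25B": 25,
        "G4": 4, "G7": 7, "GDEL80": 80,
    }
    names, sizes = make_gene_sizes(2394, special)
    return make_design(sizes, names, chromosome_of={"G98": "chrX"})


def single_chrom_design(n: int, chrom: str = "chr1") -> AmpliconDesign:
    """n amplicons, one gene, one chromosome, one pool."""
    return AmpliconDesign(
        Amplicon(
            id=f"A_{i + 1:03d}",
            chromosome=chrom,
            start=1000 * (i + 1),
            end=1000 * (i + 1) + 199,
            gene="A",
            pool=1,
        )
        for i in range(n)
    )
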