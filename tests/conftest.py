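import numpy as np
import pytest

from capreg.genome_io import CagePeak, Genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome(rng):
    """Two random 60 kb chromosomes (enough room for negative bands)."""
    bases = np.array(list("ACGT"))
    return Genome(
        sequences={
            f"chr{i}": "".join(bases[rng.integers(0, 4, size=60_000)])
            for i in (1, 2)
        }
    )


@pytest.fixture
def toy_peaks():
    """Three well-separated peaks per chromosome, all with upstream room."""
    return [
        CagePeak(chrom, start, start + 1)
        for chrom in ("chr1", "chr2")
        for start in (25_000, 40_000, 55_000)
    ]
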