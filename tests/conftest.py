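from pathlib import Path

import numpy as np
import pytest

from lohtime import (
    SimSegment,
    TumorSimParams,
    fixture_catalog,
    simulate_tumor,
)

DATA = Path(__file__).parent / "data"

# hand-derived survivor set for the packaged 12-record toy VCF:
# removed — 1:200 (tumor depth 9), 1:300 (normal depth 9), 1:400 (2 normal alt
# reads), 1:700 (2 of 4 mapping cutoffs), 1:800 (4 of 4), 1:900 (in PON),
# 2:150 (2 of 4); kept — everything else, incl. 1:600 (1 of 4 cutoffs) and
# 1:1000 (PON hit at same position but different alt).
TOY_SURVIVORS = {("1", 100), ("1", 500), ("1", 600), ("1", 1000), ("2", 250)}


@pytest.fixture(scope="session")
def toy_vcf():
    return DATA / "toy.vcf"


@pytest.fixture(scope="session")
def toy_annotations():
    return DATA / "toy_annotations.tsv"


@pytest.fixture(scope="session")
def toy_pon():
    return DATA / "toy_pon.tsv"


@pytest.fixture(scope="session")
def catalog():
    return fixture_catalog()


@pytest.fixture(scope="session")
def cnloh_tumor():
    """Whole-chr17 CN-LOH tumor with the gain at pi_true=0.25 (defaults)."""
    return simulate_tumor(TumorSimParams(n_mutations=2000), seed=20_001)


@pytest.fixture(scope="session")
def clonal_cnloh_tumor():
    """Same scenario without subclonal mutations (clean timing truth)."""
    params = TumorSimParams(
        n_mutations=2000,
        subclonal_fraction=0.0,
        segments=[SimSegment("17", 0, 81_195_210, 2, 0, pi_true=0.25)],
    )
    return simulate_tumor(params, seed=20_002)


def rng_seeds(master: int, n: int):
    """Stable child seeds below 2**31 for repeated simulations."""
    return np.random.default_rng(master).integers(2**31, size=n)
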