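import numpy as np
import pytest

from gbsex import (
    AlleleDepthMatrix,
    SnpTable,
    make_filter_fixture,
    make_gender_series,
)


@pytest.fixture(scope="session")
def filter_fixture():
    return make_filter_fixture()


@pytest.fixture()
def tiny_adm():
    """3 samples x 4 SNPs (2 X, 1 Y, 1 autosome) with assorted depths."""
    ref = np.array(
        [
            [3, 0, 2, 1],
            [0, 1, 0, 0],
            [2, 2, 5, 4],
        ]
    )
    alt = np.array(
        [
            [1, 0, 0, 0],
            [0, 1, 0, 2],
            [0, 3, 0, 0],
        ]
    )
    adm = AlleleDepthMatrix(["s1", "s2", "s3"], ["x1", "x2", "y1", "a1"], ref, alt)
    snps = SnpTable.from_arrays(
        ["x1", "x2", "y1", "a1"],
        ["X", "X", "Y", "AUTOSOME"],
        [1_000_000, 2_000_000, 500, 42],
    )
    genders = make_gender_series(["s1", "s2", "s3"], ["M", "F", "F"])
    return adm, snps, genders
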