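"""Shared fixtures: planted ISH sections and small expression matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ishnet.coexpr import SampleMatrix
from ishnet.synthetic import IshFixtureSpec, RoiSpec, gen_ish_fixture

# Representative in-bin gray means per intensity scale, all >= 3 gray
# levels away from the nearest bin edge.
MU_FOR_L = {7: 15.0, 6: 47.0, 5: 79.0, 4: 111.0, 3: 143.0, 2: 167.0, 1: 183.0}
# Mid-bin signal fractions per density scale.
P_FOR_D = {1: 0.025, 2: 0.12, 3: 0.45, 4: 0.85}


def planted_section(L: int, D: int, *, size: int = 120, seed: int = 0):
    """One synthetic ISH/Nissl/mask triplet whose single ROI scores (L, D).

    The ROI is size x size (>= 10,000 px at the default), with the signal
    gray mean centred in the L bin and the signal fraction centred in the
    D bin.
    """
    if L == 0 or D == 0:
        p, mu = 0.0, 100.0
    else:
        p, mu = P_FOR_D[D], MU_FOR_L[L]
    spec = IshFixtureSpec(
        shape=(size + 20, size + 20),
        rois=(RoiSpec(label=1, name="ROI", rect=(10, 10, 10 + size, 10 + size), p=p, mu=mu, sigma=2.0),),
        seed=seed,
    )
    ish, nissl, mask, names, truth = gen_ish_fixture(spec)
    return ish, nissl, mask, truth


@pytest.fixture
def toy_sample_matrix() -> SampleMatrix:
    """3 genes x 4 samples with hand-checkable correlations."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [4.0, 3.0, 2.0, 1.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return SampleMatrix(values=values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
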