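import numpy as np
import pytest

import ugimem as u


@pytest.fixture(scope="session")
def library():
    """The packaged 5 x 5 x 12 x 5 Ugi library (1500 products)."""
    return u.default_library()


@pytest.fixture(scope="session")
def toy_codebook():
    """Small constant-weight codebook: n=64, w=8, K=256, d_min>=6."""
    return u.build_codebook(n=64, w=8, K=256, d_min=6, seed=1)


@pytest.fixture(scope="session")
def tiny_codebook():
    """Very small codebook for exhaustive flip enumeration: n=16, w=4, K=8."""
    return u.build_codebook(n=16, w=4, K=8, d_min=4, seed=3)


@pytest.fixture(scope="session")
def paper_codebook():
    """Paper-scale codebook: 2^16 weight-32 words of length 512, d_min>=36.

    Built once per session; construction plus exact verification of all
    ~2^31 pairwise distances takes a couple of minutes.
    """
    return u.build_codebook(n=512, w=32, K=65536, d_min=36, seed=1)


def naive_min_distance(words: np.ndarray) -> int:
    """O(K^2) double-loop Hamming distance oracle."""
    words = np.asarray(words, dtype=np.int64)
    best = words.shape[1] * 2
    for i in range(len(words) - 1):
        d = np.abs(words[i + 1:] - words[i]).sum(axis=1).min()
        best = min(best, int(d))
    return best
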