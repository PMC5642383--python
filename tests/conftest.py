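import numpy as np
import pandas as pd
import pytest

from regmut import MutationCatalog, make_windows


@pytest.fixture
def two_windows():
    return make_windows({"chr1": 2_000_000}, 1_000_000)


@pytest.fixture
def ten_windows():
    return make_windows({"chr1": 10_000_000}, 1_000_000)


def make_catalog(records, metadata=None):
    """records: list of (chrom, pos, ref, alt, sample_id)."""
    rec = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt", "sample_id"])
    if metadata is None:
        ids = sorted(set(rec["sample_id"])) if len(rec) else []
        metadata = pd.DataFrame({"sample_id": ids})
    return MutationCatalog(rec, metadata)


@pytest.fixture
def catalog_factory():
    return make_catalog


def uniform_catalog(n, n_windows, seed, sample_id="s0", window_size=1_000_000):
    """n uniform mutations over the first n_windows megabase windows."""
    rng = np.random.default_rng(seed)
    pos = rng.integers(0, n_windows * window_size, size=n)
    return make_catalog([("chr1", int(p), "A", "T", sample_id) for p in pos]), pos
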