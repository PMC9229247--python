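import numpy as np
import pandas as pd
import pytest

from hostadapt import OtuTable


@pytest.fixture
def toy_table() -> OtuTable:
    """4 OTUs x 4 samples over two hosts, with hand-checkable values."""
    counts = pd.DataFrame(
        {
            "h1": [5, 15, 80, 0],
            "h2": [0, 3, 96, 1],
            "p1": [10, 0, 85, 5],
            "p2": [0, 0, 99, 1],
        },
        index=["otuA", "otuB", "otuC", "otuD"],
    )
    hosts = {"h1": "human", "h2": "human", "p1": "pig", "p2": "pig"}
    return OtuTable(counts, hosts)


@pytest.fixture
def make_random_table():
    """Factory for random valid tables: overdispersed counts, >= 2 hosts."""

    def _make(
        seed: int,
        n_otus: int = 25,
        hosts=(("human", 4), ("pig", 4), ("chicken", 4)),
    ) -> OtuTable:
        rng = np.random.default_rng(seed)
        sample_ids, host_of = [], {}
        for host, n in hosts:
            for i in range(n):
                sid = f"{host}{i}"
                sample_ids.append(sid)
                host_of[sid] = host
        counts = rng.negative_binomial(1, 0.02, size=(n_otus, len(sample_ids)))
        # guarantee every sample has at least one read
        counts[0, :] += 1
        frame = pd.DataFrame(
            counts,
            index=[f"otu{i:03d}" for i in range(n_otus)],
            columns=sample_ids,
        )
        return OtuTable(frame, host_of)

    return _make
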