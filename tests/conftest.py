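from __future__ import annotations

import numpy as np
import pytest

import mitomarkers as mm

FIG_SEQS = ["TAGCACG", "TTAGACG", "CACGTAG"]


def forward_only(seqs):
    """Index entries for the given strings, no reverse complements."""
    return [
        mm.IndexedSequence(i, f"s{i}", "+", s) for i, s in enumerate(seqs)
    ]


def random_sequences(rng: np.random.Generator, n_seqs: int, max_len: int,
                     min_len: int = 5) -> list:
    return [
        "".join("ACGT"[c] for c in rng.integers(0, 4, rng.integers(min_len, max_len + 1)))
        for _ in range(n_seqs)
    ]


@pytest.fixture(scope="session")
def fig_tree():
    """3-truncated tree over the three worked-example sequences."""
    return mm.build_truncated_gst(forward_only(FIG_SEQS), 3)


@pytest.fixture(scope="session")
def mini_clean():
    """Small mitogenome-like dataset with clean annotations."""
    params = mm.mini_params(n_genomes=12, mutation_rate=0.02, seed=101)
    return mm.generate(params)


@pytest.fixture(scope="session")
def mini_clean_tree(mini_clean):
    ds = mini_clean.dataset("truth")
    return mm.build_truncated_gst(ds.derived, 30)


@pytest.fixture(scope="session")
def mini_guided_markers(mini_clean, mini_clean_tree):
    return mm.detect_guided(mini_clean_tree, mini_clean.truth)
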