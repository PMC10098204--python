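"""Shared fixtures and small deterministic helpers."""

from __future__ import annotations

import numpy as np
import pytest

from mitagprofiler.community import TaxonomyTree

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def random_taxonomy_tree(rng: np.random.Generator) -> TaxonomyTree:
    from mitagprofiler.simulate import random_taxonomy

    return random_taxonomy(rng)


@pytest.fixture(scope="session")
def demo_setup():
    """One small simulated community shared by read-level tests."""
    import mitagprofiler as m

    community, refs = m.demo_community(11)
    cfg = m.SimulationConfig(depth=120, seed=11)
    pairs, truth = m.simulate_reads(community, refs, cfg)
    return community, refs, cfg, pairs, truth
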