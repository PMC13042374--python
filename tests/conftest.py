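"""Shared fixtures: a tiny handcrafted genome and a small synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from freesv.core import FragmentRecord, Gene, GenomicInterval, ReferenceGenome
from freesv.simulate import (
    SimConfig,
    simulate_cohort,
    simulate_panel,
    simulate_reference,
    toy_signature_pool,
)


@pytest.fixture(scope="session")
def toy_reference() -> ReferenceGenome:
    """A 2 kb deterministic chromosome with two genes."""
    rng = np.random.default_rng(123)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
    genes = [
        Gene("chrT", 200, 700, "+", "geneA"),
        Gene("chrT", 1200, 1700, "-", "geneB"),
    ]
    return ReferenceGenome({"chrT": seq}, genes)


@pytest.fixture(scope="session")
def signature_pool():
    return toy_signature_pool(8, seed=0)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_controls=4, n_cancers=4, master_seed=11)


@pytest.fixture(scope="session")
def small_world(small_config):
    """Reference + nucleosome centers + cohort + panel, generated once."""
    reference, centers = simulate_reference(small_config)
    samples, manifest = simulate_cohort(small_config, reference, centers)
    panel = simulate_panel(small_config, reference, centers, 4000)
    return small_config, reference, centers, samples, manifest, panel


def make_fragment(chrom: str, start: int, end: int, name: str = "f",
                  mapq: int = 60, base_calls=None, meth_calls=None) -> FragmentRecord:
    return FragmentRecord(
        GenomicInterval(chrom, start, end), name=name, mapq=mapq,
        base_calls=list(base_calls or []), meth_calls=meth_calls,
    )
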