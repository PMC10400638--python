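"""Shared fixtures: small hand-built datasets with known statistics."""

from __future__ import annotations

import numpy as np
import pytest

from ribovar.io import AnnotatedDataset, SampleMetadata, SequenceRecord


def make_dataset(seqs: dict[str, str], meta: dict[str, tuple]) -> AnnotatedDataset:
    """Build a dataset from {id: residues} and {id: (specimen, pop, basin, status, genotype)}."""
    records = [SequenceRecord(i, s) for i, s in seqs.items()]
    metadata = [
        SampleMetadata(i, *meta[i]) for i in seqs
    ]
    return AnnotatedDataset(records, metadata)


def random_dataset(
    rng: np.random.Generator,
    n: int,
    L: int,
    n_pops: int = 2,
    clones_per_specimen: int = 1,
    alphabet: str = "ACGT",
) -> AnnotatedDataset:
    """iid random alignment with a simple nested sampling design."""
    seqs, meta = {}, {}
    for i in range(n):
        sid = f"s{i:03d}"
        seqs[sid] = "".join(rng.choice(list(alphabet), size=L))
        pop = f"pop{i % n_pops}"
        specimen = f"{pop}_sp{i // (n_pops * clones_per_specimen)}_{i % n_pops}"
        meta[sid] = (specimen, pop, f"basin{(i % n_pops) // max(1, n_pops // 2)}", "native", "Ia")
    return make_dataset(seqs, meta)


@pytest.fixture
def toy4() -> AnnotatedDataset:
    """4 x 10 alignment: variants at columns 9 (A/G) and 10 (A/T).

    Pairwise difference multiset {1, 1, 1, 2, 2, 0}: k_bar = 7/6, S = 2,
    pi = (7/6)/10, three haplotypes with frequencies (2, 1, 1).
    """
    seqs = {
        "t1": "AAAAAAAAAA",
        "t2": "AAAAAAAAGA",
        "t3": "AAAAAAAAAT",
        "t4": "AAAAAAAAAT",
    }
    meta = {
        "t1": ("sp1", "Eilat", "Red Sea", "native", "Ia"),
        "t2": ("sp1", "Eilat", "Red Sea", "native", "Ia"),
        "t3": ("sp2", "Shikmona", "Mediterranean", "established_invader", "Ia"),
        "t4": ("sp2", "Shikmona", "Mediterranean", "established_invader", "Ia"),
    }
    return make_dataset(seqs, meta)


@pytest.fixture
def design16() -> AnnotatedDataset:
    """2 basins x 2 populations x 2 specimens x 2 clones = 16 sequences."""
    rng = np.random.default_rng(42)
    seqs, meta = {}, {}
    i = 0
    for b in ("basinA", "basinB"):
        for p in range(2):
            pop = f"{b}_pop{p}"
            for s in range(2):
                specimen = f"{pop}_sp{s}"
                for c in range(2):
                    sid = f"q{i:02d}"
                    seqs[sid] = "".join(rng.choice(list("ACGT"), size=20))
                    status = "native" if b == "basinA" else "invasion_front"
                    meta[sid] = (specimen, pop, b, status, "Ia")
                    i += 1
    return make_dataset(seqs, meta)
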