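"""Diversity statistics: masks, haplotypes, pi, S and Tajima's D."""

from fractions import Fraction
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribovar.popgen import (
    build_site_mask,
    collapse_haplotypes,
    group_summary,
    mean_pairwise_differences,
    nucleotide_diversity,
    pairwise_differences,
    segregating_sites,
    tajimas_d,
)
from tests.conftest import make_dataset, random_dataset


# -- site masks -------------------------------------------------------------

def test_mask_all_columns_when_clean(toy4):
    mask = build_site_mask(toy4)
    assert mask.usable_columns == tuple(range(1, 11))


def test_mask_excludes_gapped_column():
    ds = make_dataset(
        {"a": "ACGT-ACGTA", "b": "ACGTAACGTA"},
        {
            "a": ("sp1", "p", "b", "native", "Ia"),
            "b": ("sp2", "p", "b", "native", "Ia"),
        },
    )
    mask = build_site_mask(ds, "complete_deletion")
    assert 5 not in mask.usable_columns
    assert mask.n_usable == 9


def test_mask_errors_when_everything_gapped():
    ds = make_dataset(
        {"a": "-N", "b": "A-"},
        {
            "a": ("sp1", "p", "b", "native", "Ia"),
            "b": ("sp2", "p", "b", "native", "Ia"),
        },
    )
    with pytest.raises(ValueError, match="zero usable columns"):
        build_site_mask(ds)


def test_pairwise_deletion_keeps_all_columns():
    ds = make_dataset(
        {"a": "AC-T", "b": "ACGT", "c": "TCGT"},
        {
            "a": ("sp1", "p", "b", "native", "Ia"),
            "b": ("sp2", "p", "b", "native", "Ia"),
            "c": ("sp3", "p", "b", "native", "Ia"),
        },
    )
    mask = build_site_mask(ds, "pairwise_deletion")
    assert mask.n_usable == 4
    d = pairwise_differences(ds, mask)
    assert d["a", "b"] == 0  # gap column skipped for this pair
    assert d["b", "c"] == 1


# -- haplotypes / S / pi ------------------------------------------------------

def test_collapse_haplotypes_toy(toy4):
    table = collapse_haplotypes(toy4, build_site_mask(toy4))
    assert table.H == 3
    assert [h.frequency for h in table.haplotypes] == [2, 1, 1]
    assert table.haplotypes[0].member_ids == ("t3", "t4")
    assert sum(h.frequency for h in table.haplotypes) == table.n == 4


def test_collapse_all_identical():
    ds = make_dataset(
        {f"s{i}": "ACGTACGT" for i in range(5)},
        {f"s{i}": (f"sp{i}", "p", "b", "native", "Ia") for i in range(5)},
    )
    table = collapse_haplotypes(ds, build_site_mask(ds))
    assert table.H == 1 and table.haplotypes[0].frequency == 5


def test_segregating_sites_toy(toy4):
    assert segregating_sites(toy4, build_site_mask(toy4)) == 2


def test_segregating_sites_monomorphic():
    ds = make_dataset(
        {"a": "AAAA", "b": "AAAA"},
        {
            "a": ("sp1", "p", "b", "native", "Ia"),
            "b": ("sp2", "p", "b", "native", "Ia"),
        },
    )
    assert segregating_sites(ds, build_site_mask(ds)) == 0
    assert nucleotide_diversity(ds, build_site_mask(ds)) == 0.0


def test_pairwise_differences_toy(toy4):
    d = pairwise_differences(toy4, build_site_mask(toy4))
    assert d["t3", "t4"] == 0
    assert d["t1", "t2"] == 1
    assert d["t2", "t3"] == 2
    # Hamming distance: triangle inequality on every triple
    ids = list(d.ids)
    for i in ids:
        for j in ids:
            for k in ids:
                assert d[i, k] <= d[i, j] + d[j, k]


def test_nucleotide_diversity_toy(toy4):
    pi = nucleotide_diversity(toy4, build_site_mask(toy4))
    assert pi == pytest.approx((7 / 6) / 10, abs=1e-12)


# -- Tajima's D ---------------------------------------------------------------

def _tajima_oracle(n: int, S: int, k_bar: Fraction) -> float:
    """Independent high-precision evaluation of the 1989 formula."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float(k_bar - S / a1) / math.sqrt(float(var))


def test_tajimas_d_toy_matches_exact_formula(toy4):
    res = tajimas_d(toy4, build_site_mask(toy4))
    assert res.S == 2
    assert res.k_bar == pytest.approx(7 / 6, abs=1e-12)
    expected = _tajima_oracle(4, 2, Fraction(7, 6))
    assert expected == pytest.approx(0.59, abs=0.005)  # the hand value
    assert res.D == pytest.approx(expected, abs=1e-9)
    assert 0 <= res.p <= 1


def test_tajimas_d_zero_when_kbar_equals_s_over_a1():
    # n=4: a1 = 11/6; choose S=11 and k_bar = 6 by construction:
    # sequences pairwise differ by exactly 6 at 11 segregating sites
    # 8 private-singleton columns (2 per sequence) + 3 balanced-split columns
    seqs = {
        "a": "CCAAAAAACCC",
        "b": "AACCAAAACAA",
        "c": "AAAACCAAACA",
        "d": "AAAAAACCAAC",
    }
    # check the construction: all pairwise Hamming distances are 6
    vals = list(seqs.values())
    assert all(
        sum(x != y for x, y in zip(vals[i], vals[j])) == 6
        for i in range(4)
        for j in range(i + 1, 4)
    )
    ds = make_dataset(
        seqs, {k: (f"sp{k}", "p", "b", "native", "Ia") for k in seqs}
    )
    res = tajimas_d(ds, build_site_mask(ds))
    assert res.S == 11
    assert res.D == pytest.approx(0.0, abs=1e-12)


def test_tajimas_d_undefined_and_errors():
    ds = make_dataset(
        {f"s{i}": "ACGT" for i in range(4)},
        {f"s{i}": (f"sp{i}", "p", "b", "native", "Ia") for i in range(4)},
    )
    res = tajimas_d(ds, build_site_mask(ds))
    assert not res.defined and res.D is None and res.p is None

    small = make_dataset(
        {"a": "ACGT", "b": "ACGA", "c": "ACGT"},
        {k: (f"sp{k}", "p", "b", "native", "Ia") for k in ("a", "b", "c")},
    )
    with pytest.raises(ValueError, match="n >= 4"):
        tajimas_d(small, build_site_mask(small))


# -- brute-force oracle and invariances ---------------------------------------

def _naive_stats(dataset, mask):
    """Direct recount of S and pi over all pairs/columns."""
    cols = [c - 1 for c in mask.usable_columns]
    seqs = [r.residues for r in dataset.alignment]
    S = 0
    for c in cols:
        states = {s[c] for s in seqs if s[c] in "ACGT"}
        if len(states) >= 2:
            S += 1
    n = len(seqs)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(seqs[i][c] != seqs[j][c] for c in cols)
    k_bar = total / (n * (n - 1) / 2)
    return S, k_bar / len(cols)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    n=st.integers(2, 6),
    L=st.integers(2, 12),
    seed=st.integers(0, 10_000),
)
def test_pi_and_s_match_bruteforce(n, L, seed):
    rng = np.random.default_rng(seed)
    ds = random_dataset(rng, n, L)
    mask = build_site_mask(ds)
    S_naive, pi_naive = _naive_stats(ds, mask)
    assert segregating_sites(ds, mask) == S_naive
    assert nucleotide_diversity(ds, mask) == pytest.approx(pi_naive, abs=1e-12)


def test_order_invariance():
    rng = np.random.default_rng(3)
    ds = random_dataset(rng, 6, 30)
    mask = build_site_mask(ds)
    perm = np.random.default_rng(1).permutation(6)
    shuffled = make_dataset(
        {ds.ids[i]: ds.alignment[i].residues for i in perm},
        {
            ds.ids[i]: (
                ds.metadata[i].specimen_id,
                ds.metadata[i].population,
                ds.metadata[i].basin,
                ds.metadata[i].invasion_status,
                ds.metadata[i].genotype,
            )
            for i in perm
        },
    )
    mask2 = build_site_mask(shuffled)
    assert nucleotide_diversity(ds, mask) == nucleotide_diversity(shuffled, mask2)
    assert tajimas_d(ds, mask).D == tajimas_d(shuffled, mask2).D


# -- group summaries -----------------------------------------------------------

def test_group_summary_basins(design16):
    rows = group_summary(design16, "basin")
    assert [r.group for r in rows] == ["basinA", "basinB"]
    assert all(r.n == 8 for r in rows)


def test_group_summary_small_group_flagged(toy4):
    rows = group_summary(toy4, "basin")
    assert all(r.n == 2 for r in rows)
    assert all(r.tajimas_d is None for r in rows)  # n < 4: undefined, not 0


def test_group_summary_unknown_grouping(toy4):
    with pytest.raises(ValueError, match="grouping"):
        group_summary(toy4, "color")
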