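"""Haplotype collapsing and per-group diversity statistics.

Implements the classic summary statistics of within-group polymorphism on a
gap/ambiguity-masked alignment: number of haplotypes H, segregating sites S,
mean pairwise differences k-bar, nucleotide diversity pi = k-bar / Lu, and
Tajima's (1989) D with its beta-approximation significance.

Sites containing alignment gaps or IUPAC ambiguity codes are handled by a
:class:`SiteMask` built under one of two policies:

``complete_deletion`` (default)
    a column is usable iff *no* sequence has a gap/ambiguity there; all
    statistics and haplotype identity are evaluated on usable columns only.
``pairwise_deletion``
    all columns are nominally usable; each pairwise comparison skips the
    columns where either sequence is not a plain A/C/G/T.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from skbio import DistanceMatrix

from ribovar.io import AnnotatedDataset

logger = logging.getLogger(__name__)

GapPolicy = Literal["complete_deletion", "pairwise_deletion"]

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _matrix(dataset: AnnotatedDataset) -> np.ndarray:
    """Alignment as an (n, L) uint8 array of ASCII codes."""
    return np.frombuffer(
        "".join(r.residues for r in dataset.alignment).encode("ascii"),
        dtype=np.uint8,
    ).reshape(dataset.n, dataset.length)


def _is_acgt(mat: np.ndarray) -> np.ndarray:
    return np.isin(mat, _ACGT)


@dataclass(frozen=True)
class SiteMask:
    """Usable alignment columns (1-based) under a gap/ambiguity policy."""

    usable_columns: tuple[int, ...]
    policy: GapPolicy

    @property
    def n_usable(self) -> int:
        return len(self.usable_columns)

    def indices(self) -> np.ndarray:
        """0-based column indices for array slicing."""
        return np.asarray(self.usable_columns, dtype=int) - 1


@dataclass(frozen=True)
class Haplotype:
    residues: str
    frequency: int
    member_ids: tuple[str, ...]


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct sequence types over usable columns, by decreasing frequency."""

    haplotypes: tuple[Haplotype, ...]
    n: int

    @property
    def H(self) -> int:
        return len(self.haplotypes)

    def representative_ids(self) -> list[str]:
        """First-seen member id of each haplotype, in table order."""
        return [h.member_ids[0] for h in self.haplotypes]


@dataclass(frozen=True)
class TajimaResult:
    """Tajima's D with its 1989 constants and beta-approximation p-value.

    When S = 0 the statistic is undefined: ``D`` and ``p`` are None and
    ``defined`` is False.
    """

    n: int
    S: int
    k_bar: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float | None
    p: float | None

    @property
    def defined(self) -> bool:
        return self.D is not None


@dataclass(frozen=True)
class DiversitySummary:
    """One row of a Table-style per-group diversity summary."""

    group: str
    n: int
    usable_columns: int
    nucleotide_diversity: float | None
    n_haplotypes: int
    n_segregating: int
    tajimas_d: float | None
    tajima_p: float | None


def build_site_mask(
    dataset: AnnotatedDataset, policy: GapPolicy = "complete_deletion"
) -> SiteMask:
    """Determine usable columns under the given gap/ambiguity policy.

    Raises ``ValueError`` when complete deletion leaves zero usable columns.
    """
    mat = _matrix(dataset)
    if policy == "complete_deletion":
        usable = _is_acgt(mat).all(axis=0)
        cols = tuple(int(c) + 1 for c in np.flatnonzero(usable))
        if not cols:
            raise ValueError(
                "complete_deletion mask left zero usable columns "
                f"(all {dataset.length} columns contain a gap or ambiguity)"
            )
        masked = dataset.length - len(cols)
        if masked:
            logger.info(
                "site mask (complete_deletion): %d of %d columns masked",
                masked,
                dataset.length,
            )
        return SiteMask(usable_columns=cols, policy=policy)
    if policy == "pairwise_deletion":
        return SiteMask(
            usable_columns=tuple(range(1, dataset.length + 1)), policy=policy
        )
    raise ValueError(f"unknown gap policy {policy!r}")


def collapse_haplotypes(dataset: AnnotatedDataset, mask: SiteMask) -> HaplotypeTable:
    """Collapse sequences identical on all usable columns into haplotypes.

    Ordering is deterministic: decreasing frequency, ties broken by the
    alignment position of the first member sequence.
    """
    idx = mask.indices()
    groups: dict[str, list[str]] = {}
    for rec in dataset.alignment:
        key = "".join(rec.residues[i] for i in idx)
        groups.setdefault(key, []).append(rec.id)
    order = {rec_id: i for i, rec_id in enumerate(dataset.ids)}
    haps = [
        Haplotype(residues=key, frequency=len(members), member_ids=tuple(members))
        for key, members in groups.items()
    ]
    haps.sort(key=lambda h: (-h.frequency, order[h.member_ids[0]]))
    return HaplotypeTable(haplotypes=tuple(haps), n=dataset.n)


def segregating_sites(dataset: AnnotatedDataset, mask: SiteMask) -> int:
    """Number of usable columns with >= 2 distinct states among A/C/G/T."""
    mat = _matrix(dataset)[:, mask.indices()]
    ok = _is_acgt(mat)
    S = 0
    for j in range(mat.shape[1]):
        states = np.unique(mat[ok[:, j], j])
        if states.size >= 2:
            S += 1
    return int(S)


def pairwise_differences(
    dataset: AnnotatedDataset, mask: SiteMask
) -> DistanceMatrix:
    """Absolute number of nucleotide differences for every sequence pair.

    Under complete deletion this is the Hamming distance on usable columns;
    under pairwise deletion, columns where either sequence is not a plain
    A/C/G/T are skipped for that pair.
    """
    if dataset.n < 2:
        raise ValueError("need >= 2 sequences for pairwise differences")
    mat = _matrix(dataset)[:, mask.indices()]
    ok = _is_acgt(mat)
    n = dataset.n
    out = np.zeros((n, n))
    for i in range(n):
        both_ok = ok[i] & ok[i + 1 :]
        diffs = (mat[i] != mat[i + 1 :]) & both_ok
        out[i, i + 1 :] = diffs.sum(axis=1)
    out = out + out.T
    return DistanceMatrix(out, ids=dataset.ids)


def mean_pairwise_differences(
    dataset: AnnotatedDataset, mask: SiteMask
) -> float:
    """k-bar: mean number of pairwise differences over all sequence pairs."""
    d = pairwise_differences(dataset, mask)
    n = dataset.n
    return float(d.condensed_form().sum() / (n * (n - 1) / 2))


def nucleotide_diversity(dataset: AnnotatedDataset, mask: SiteMask) -> float:
    """pi: mean pairwise differences per usable site (k-bar / Lu)."""
    return mean_pairwise_differences(dataset, mask) / mask.n_usable


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(dataset: AnnotatedDataset, mask: SiteMask) -> TajimaResult:
    """Tajima's D from k-bar and S, with a two-sided beta-approximation p.

    D = (k_bar - S/a1) / sqrt(e1*S + e2*S*(S-1)); the null density of D is
    approximated by a beta distribution rescaled to D's attainable range
    [D_min, D_max], following Tajima (1989), and the two-sided p is
    2 * min(F(D), 1 - F(D)).

    Requires n >= 4 sequences. With S = 0 the result is flagged undefined.
    """
    n = dataset.n
    if n < 4:
        raise ValueError(f"Tajima's D requires n >= 4 sequences, got {n}")
    S = segregating_sites(dataset, mask)
    k_bar = mean_pairwise_differences(dataset, mask)
    c = _tajima_constants(n)
    if S == 0:
        return TajimaResult(n=n, S=0, k_bar=k_bar, D=None, p=None, **c)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    D = (k_bar - S / c["a1"]) / math.sqrt(var)
    # Rescale D onto its attainable range and evaluate a mean-0/var-1 beta.
    d_min = (2.0 / n - 1.0 / c["a1"]) / math.sqrt(c["e2"])
    d_max = ((n + 1) / (2.0 * n) - 1.0 / c["a1"]) / math.sqrt(c["e2"])
    tmp1 = 1.0 + d_min * d_max
    tmp2 = d_max - d_min
    a = -tmp1 * d_max / tmp2
    b = tmp1 * d_min / tmp2
    cdf = float(stats.beta.cdf((D - d_min) / tmp2, b, a))
    p = 2.0 * min(cdf, 1.0 - cdf)
    p = min(max(p, 0.0), 1.0)
    return TajimaResult(n=n, S=S, k_bar=k_bar, D=float(D), p=p, **c)


_GROUPINGS = ("genotype", "basin", "invasion_status", "population")


def group_summary(
    dataset: AnnotatedDataset,
    grouping: str,
    policy: GapPolicy = "complete_deletion",
) -> list[DiversitySummary]:
    """Per-group diversity summary (one Table-style row per group).

    Each group is analysed on its own subset with a subset-specific site
    mask, so the usable length Lu can differ between groups. Groups with
    n < 4 or S = 0 get an undefined (None) Tajima's D rather than a number.
    Groups are emitted in sorted label order.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"grouping must be one of {_GROUPINGS}, got {grouping!r}")
    labels = sorted({getattr(m, grouping) for m in dataset.metadata})
    rows = []
    for label in labels:
        sub = dataset.subset(**{grouping: label})
        sub_mask = build_site_mask(sub, policy)
        table = collapse_haplotypes(sub, sub_mask)
        S = segregating_sites(sub, sub_mask)
        pi = nucleotide_diversity(sub, sub_mask) if sub.n >= 2 else None
        D = p = None
        if sub.n >= 4 and S >= 1:
            res = tajimas_d(sub, sub_mask)
            D, p = res.D, res.p
        rows.append(
            DiversitySummary(
                group=label,
                n=sub.n,
                usable_columns=sub_mask.n_usable,
                nucleotide_diversity=pi,
                n_haplotypes=table.H,
                n_segregating=S,
                tajimas_d=D,
                tajima_p=p,
            )
        )
    return rows


def summary_frame(rows: Sequence[DiversitySummary]):
    """Diversity summaries as a DataFrame in Table 1/2 column layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "group": [r.group for r in rows],
            "n_sequences": [r.n for r in rows],
            "usable_columns": [r.usable_columns for r in rows],
            "nucleotide_diversity": [r.nucleotide_diversity for r in rows],
            "n_haplotypes": [r.n_haplotypes for r in rows],
            "n_segregating_sites": [r.n_segregating for r in rows],
            "tajimas_d": [r.tajimas_d for r in rows],
            "tajima_p": [r.tajima_p for r in rows],
        }
    )
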