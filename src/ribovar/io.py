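"""Reading, validation and joining of alignments, metadata and trees.

The universal input of every analysis stage is an :class:`AnnotatedDataset`:
an aligned set of clone-level sequences joined to a metadata table that
places every sequence in the sampling hierarchy
(specimen -> population -> oceanic basin) and records its invasion status
and genotype lineage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: Valid invasion-status labels, from native range to newly invaded front.
INVASION_STATUSES = frozenset(
    {"native", "established_invader", "invasion_front", "outgroup"}
)

#: Columns required in a metadata TSV, in canonical order.
METADATA_COLUMNS = (
    "sequence_id",
    "specimen_id",
    "population",
    "basin",
    "invasion_status",
    "genotype",
)

# IUPAC nucleotide codes (incl. ambiguity) plus alignment gap.
VALID_RESIDUES = frozenset("ACGTURYSWKMBDHVN-")


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned clone sequence.

    Residues are uppercase characters over the IUPAC nucleotide alphabet
    plus ``-`` for alignment gaps; every record in one alignment has the
    same number of columns.
    """

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SampleMetadata:
    """Hierarchy labels for one sequence.

    A sequence is one cloned rRNA gene copy from one specimen; specimens
    nest in populations (sampling localities), populations nest in oceanic
    basins. ``invasion_status`` distinguishes native-range populations from
    established invaders and the invasion front; ``genotype`` is the
    species-level lineage label (e.g. Ia, IIa, IIc).
    """

    sequence_id: str
    specimen_id: str
    population: str
    basin: str
    invasion_status: str
    genotype: str

    def __post_init__(self) -> None:
        if self.invasion_status not in INVASION_STATUSES:
            raise ValueError(
                f"unknown invasion_status {self.invasion_status!r} for "
                f"sequence {self.sequence_id!r}; expected one of "
                f"{sorted(INVASION_STATUSES)}"
            )


class AnnotatedDataset:
    """Aligned sequences totally joined to their metadata.

    The join is validated at construction: every sequence has exactly one
    metadata row and vice versa, all sequences have equal length, and the
    specimen/population/basin nesting is consistent.
    """

    def __init__(
        self,
        alignment: Sequence[SequenceRecord],
        metadata: Sequence[SampleMetadata],
    ) -> None:
        self.alignment = list(alignment)
        self.metadata = list(metadata)
        _check_constant_length(self.alignment)
        aln_ids = [r.id for r in self.alignment]
        if len(set(aln_ids)) != len(aln_ids):
            dupes = sorted({i for i in aln_ids if aln_ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in alignment: {dupes}")
        meta_ids = [m.sequence_id for m in self.metadata]
        if len(set(meta_ids)) != len(meta_ids):
            dupes = sorted({i for i in meta_ids if meta_ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in metadata: {dupes}")
        only_aln = sorted(set(aln_ids) - set(meta_ids))
        only_meta = sorted(set(meta_ids) - set(aln_ids))
        if only_aln or only_meta:
            raise ValueError(
                "alignment/metadata join is not total; "
                f"sequences without metadata: {only_aln}; "
                f"metadata without sequences: {only_meta}"
            )
        _check_nesting(self.metadata)
        self._meta_by_id = {m.sequence_id: m for m in self.metadata}
        # metadata follows alignment order for deterministic iteration
        self.metadata = [self._meta_by_id[i] for i in aln_ids]

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        """Number of sequences."""
        return len(self.alignment)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.alignment[0]) if self.alignment else 0

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.alignment]

    def meta(self, sequence_id: str) -> SampleMetadata:
        return self._meta_by_id[sequence_id]

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedDataset):
            return NotImplemented
        return (
            self.alignment == other.alignment and self.metadata == other.metadata
        )

    # -- derived views ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame indexed by sequence_id, in alignment order."""
        df = pd.DataFrame([vars(m) for m in self.metadata])
        return df.set_index("sequence_id")

    def subset(self, **criteria: str | Iterable[str]) -> "AnnotatedDataset":
        """Filter by metadata field values.

        Parameters are metadata field names mapped to one allowed value or
        an iterable of allowed values, e.g. ``subset(genotype="Ia")`` or
        ``subset(basin=["Red Sea", "Mediterranean"])``.
        """
        allowed = {}
        for field, value in criteria.items():
            if field not in METADATA_COLUMNS[1:]:
                raise ValueError(f"unknown metadata field {field!r}")
            if isinstance(value, str):
                allowed[field] = {value}
            else:
                allowed[field] = set(value)
        keep = [
            m.sequence_id
            for m in self.metadata
            if all(getattr(m, f) in v for f, v in allowed.items())
        ]
        keep_set = set(keep)
        return AnnotatedDataset(
            [r for r in self.alignment if r.id in keep_set],
            [m for m in self.metadata if m.sequence_id in keep_set],
        )

    def group_counts(self) -> pd.DataFrame:
        """Sequence counts per (basin, population), a small validation report."""
        df = self.to_frame()
        return (
            df.groupby(["basin", "population"], sort=True)
            .size()
            .rename("n_sequences")
            .reset_index()
        )


def _check_constant_length(records: Sequence[SequenceRecord]) -> None:
    if not records:
        raise ValueError("empty alignment")
    L = len(records[0])
    for rec in records:
        if len(rec) != L:
            raise ValueError(
                f"ragged alignment: sequence {rec.id!r} has length "
                f"{len(rec)}, expected {L} (from {records[0].id!r})"
            )


def _check_nesting(metadata: Sequence[SampleMetadata]) -> None:
    spec_to_pop: dict[str, str] = {}
    pop_to_basin: dict[str, str] = {}
    for m in metadata:
        prev = spec_to_pop.setdefault(m.specimen_id, m.population)
        if prev != m.population:
            raise ValueError(
                f"specimen {m.specimen_id!r} mapped to two populations: "
                f"{prev!r} and {m.population!r}"
            )
        prev = pop_to_basin.setdefault(m.population, m.basin)
        if prev != m.basin:
            raise ValueError(
                f"population {m.population!r} mapped to two basins: "
                f"{prev!r} and {m.basin!r}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> list[SequenceRecord]:
    """Read an aligned FASTA file.

    Residues are uppercased; all records must have identical length.
    Raises ``ValueError`` on an empty file, a ragged alignment (naming the
    offending record) or residues outside the IUPAC alphabet.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        bad = set(residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {rec.id!r} contains invalid residues {sorted(bad)}"
            )
        records.append(SequenceRecord(id=rec.id, residues=residues))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    _check_constant_length(records)
    return records


def write_alignment(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write aligned sequences as FASTA."""
    _check_constant_length(list(records))
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a tab-delimited metadata table.

    The header must contain the columns
    ``sequence_id specimen_id population basin invasion_status genotype``.
    Enum values and the specimen/population/basin nesting are validated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing required columns: {missing}")
    if df[list(METADATA_COLUMNS)].isna().any().any():
        raise ValueError("metadata table contains empty required fields")
    rows = [
        SampleMetadata(**{c: str(rec[c]) for c in METADATA_COLUMNS})
        for rec in df.to_dict("records")
    ]
    _check_nesting(rows)
    ids = [m.sequence_id for m in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence_id rows in metadata: {dupes}")
    return rows


def write_metadata(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    """Write metadata rows as a tab-delimited table."""
    df = pd.DataFrame([vars(m) for m in metadata], columns=list(METADATA_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def join_dataset(
    alignment: Sequence[SequenceRecord], metadata: Sequence[SampleMetadata]
) -> AnnotatedDataset:
    """Join an alignment to its metadata; the join must be total.

    Orphans on either side raise ``ValueError`` listing the offending ids.
    Logs sequence counts per basin/population.
    """
    ds = AnnotatedDataset(alignment, metadata)
    if logger.isEnabledFor(logging.INFO):
        counts = ds.group_counts()
        logger.info(
            "joined %d sequences across %d populations in %d basins:\n%s",
            ds.n,
            counts["population"].nunique(),
            counts["basin"].nunique(),
            counts.to_string(index=False),
        )
    return ds


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a newick tree with branch lengths.

    Quoted labels and polytomies are allowed. Raises ``ValueError`` if any
    non-root edge lacks a branch length, a branch length is negative, or
    leaf labels are duplicated.
    """
    from dendropy.utility.error import DataParseError

    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except DataParseError as exc:
        raise ValueError(f"invalid newick in {path}: {exc}") from exc
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or leaf.taxon.label is None:
            raise ValueError("tree contains an unlabeled leaf")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels in tree: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # the root edge may legitimately lack a length
        if edge.length is None:
            head = edge.head_node
            name = (
                head.taxon.label
                if head.taxon is not None
                else f"internal node with {len(head.leaf_nodes())} leaves"
            )
            raise ValueError(f"missing branch length on edge above {name!r}")
        if edge.length < 0:
            raise ValueError("negative branch length in tree")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as newick with branch lengths."""
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)
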