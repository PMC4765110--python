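"""Core data model and I/O for homology clusters.

A *cluster* is a named set of amino-acid sequences that some upstream
orthology heuristic (InParanoid-style reciprocal-best-hit chains, HMM
searches, ...) grouped as putatively homologous.  Clusters may carry a
multiple sequence alignment and a ground-truth label used for training
the false-positive filter.

FASTA parsing/writing is delegated to Biopython; pairwise homology
relations are plain two-column text.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: the 20 standard amino-acid one-letter codes
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN_RESIDUE = "X"
#: characters legal inside a stored residue string
RESIDUE_ALPHABET = frozenset(STANDARD_AA + UNKNOWN_RESIDUE + GAP)


class ClusterLabel(str, enum.Enum):
    H = "H"
    NH = "NH"
    UNKNOWN = "UNKNOWN"


class Provenance(str, enum.Enum):
    REAL = "REAL"
    NH_RANDOM = "NH_RANDOM"
    NH_EVOLVED_0 = "NH_EVOLVED_0"
    NH_EVOLVED_25 = "NH_EVOLVED_25"
    NH_EVOLVED_50 = "NH_EVOLVED_50"
    H_SYNTH = "H_SYNTH"


class MalformedClusterError(ValueError):
    """Raised when a cluster file violates the ≥2-member contract."""


class ResidueParseError(ValueError):
    """Raised when a sequence contains characters outside the alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """One amino-acid sequence; ``residues`` may contain gaps."""

    id: str
    residues: str
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ResidueParseError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - RESIDUE_ALPHABET
        if bad:
            raise ResidueParseError(
                f"sequence {self.id!r} contains illegal residue characters: "
                f"{sorted(bad)}"
            )
        if not self.ungapped():
            raise ResidueParseError(f"sequence {self.id!r} is all gaps")

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count(GAP)


@dataclass(frozen=True)
class Alignment:
    """Rectangular gapped residue matrix (rows are sequences)."""

    rows: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0].residues)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.rows)


@dataclass
class Cluster:
    """A putative homology cluster: members, optional MSA, label."""

    cluster_id: str
    members: list[SequenceRecord]
    alignment: Alignment | None = None
    label: ClusterLabel = ClusterLabel.UNKNOWN
    provenance: Provenance = Provenance.REAL
    #: externally supplied count of randomly aligned positions (ALISCORE);
    #: overrides the internal scorer when set
    aliscore_precomputed: int | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise MalformedClusterError(
                f"cluster {self.cluster_id!r} has {len(self.members)} member(s); "
                "need at least 2"
            )
        if self.alignment is not None:
            self._check_alignment_consistency()

    def _check_alignment_consistency(self) -> None:
        by_id = {m.id: m.ungapped() for m in self.members}
        aln_by_id = {r.id: r.ungapped() for r in self.alignment.rows}
        if by_id != aln_by_id:
            raise ValueError(
                f"cluster {self.cluster_id!r}: alignment rows do not match "
                "members (compared by id on ungapped residues)"
            )

    @property
    def size(self) -> int:
        return len(self.members)

    def with_alignment(self, alignment: Alignment) -> "Cluster":
        return Cluster(
            cluster_id=self.cluster_id,
            members=list(self.members),
            alignment=alignment,
            label=self.label,
            provenance=self.provenance,
            aliscore_precomputed=self.aliscore_precomputed,
        )


@dataclass(frozen=True)
class PairwiseRelation:
    """An unordered putative-homology pair of gene identifiers."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-relation {self.gene_a!r}")

    def key(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


def _sanitize_residues(record_id: str, raw: str) -> str:
    seq = raw.upper()
    if "*" in seq:
        logger.warning("stripping stop codon character '*' from %s", record_id)
        seq = seq.replace("*", "")
    return seq


def read_cluster_fasta(
    path: str | Path,
    cluster_id: str | None = None,
    force_aligned: bool = False,
) -> Cluster:
    """Read one cluster from a multi-FASTA file.

    The file is treated as aligned iff all sequences have equal length and
    at least one contains a gap, or ``force_aligned`` is set.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = _sanitize_residues(rec.id, str(rec.seq))
        try:
            records.append(SequenceRecord(id=rec.id, residues=residues))
        except ResidueParseError:
            raise
    if len(records) < 2:
        raise MalformedClusterError(
            f"{path}: found {len(records)} record(s); a cluster needs ≥ 2"
        )
    cid = cluster_id if cluster_id is not None else path.stem
    equal_len = len({len(r.residues) for r in records}) == 1
    any_gap = any(GAP in r.residues for r in records)
    aligned = force_aligned or (equal_len and any_gap)
    if aligned and not equal_len:
        raise ValueError(f"{path}: forced aligned but rows have unequal length")
    if aligned:
        alignment = Alignment(rows=tuple(records))
        members = [
            SequenceRecord(id=r.id, residues=r.ungapped(), taxon=r.taxon)
            for r in records
        ]
        return Cluster(cluster_id=cid, members=members, alignment=alignment)
    return Cluster(cluster_id=cid, members=records)


def write_cluster_fasta(
    cluster: Cluster, path: str | Path, aligned: bool = False
) -> None:
    """Write a cluster as multi-FASTA; round-trips ids and residues exactly."""
    if aligned and cluster.alignment is None:
        raise ValueError(
            f"cluster {cluster.cluster_id!r}: aligned output requested but no "
            "alignment is present"
        )
    rows: Sequence[SequenceRecord]
    rows = cluster.alignment.rows if aligned else cluster.members
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in rows
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_cluster_directory(
    directory: str | Path, force_aligned: bool = False
) -> list[Cluster]:
    """Read every ``*.fasta``/``*.fa`` file in a directory as one cluster."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix in {".fasta", ".fa", ".faa"}
    )
    return [read_cluster_fasta(p, force_aligned=force_aligned) for p in paths]


def read_relations(path: str | Path) -> list[PairwiseRelation]:
    """Read pairwise homology relations from two-column text.

    Reversed and duplicate pairs are collapsed; self-pairs are dropped with
    a warning.  Lines starting with ``#`` are comments.
    """
    seen: set[frozenset] = set()
    relations: list[PairwiseRelation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tokens, got {len(tokens)}"
                )
            a, b = tokens
            if a == b:
                logger.warning(
                    "%s:%d: dropping self-pair %r", path, lineno, a
                )
                continue
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            relations.append(PairwiseRelation(gene_a=min(a, b), gene_b=max(a, b)))
    return relations
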