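"""Typed records shared across the pipeline.

Coordinate conventions (also stated in every file written by
:mod:`denovopost.io_formats`):

* read-status placements, variant positions and BLAST query/subject
  coordinates are **1-based inclusive** (BLAST/VCF habit);
* ORF records are **0-based half-open** (BED habit).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ValidationError(ValueError):
    """Raised when an on-disk record violates an invariant."""


_VALID_STATUSES = ("assembled", "partially_assembled", "singleton", "discarded")
_BASES = set("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (contig, singleton or read)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"invalid sequence id {self.id!r}")
        if not self.residues:
            raise ValidationError(f"empty sequence for id {self.id!r}")
        if any(c.isspace() for c in self.residues):
            raise ValidationError(f"whitespace inside residues of {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReadPlacement:
    """How one portion of a read was placed on a contig (1-based, inclusive)."""

    contig_id: str
    read_start: int
    read_end: int
    contig_start: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.read_start < 1 or self.read_end < self.read_start:
            raise ValidationError(
                f"bad read interval {self.read_start}-{self.read_end} on {self.contig_id}"
            )
        if self.contig_start < 1:
            raise ValidationError(f"contig_start must be >= 1 on {self.contig_id}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class ReadStatusRecord:
    """One read's sex of origin, placement status and 0-2 placements.

    Two placements mean the assembler split the read between two contigs;
    these split reads are the edge evidence of the contig graph.
    """

    read_id: str
    sex: str
    status: str
    placements: tuple[ReadPlacement, ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"read {self.read_id}: sex must be F or M")
        if self.status not in _VALID_STATUSES:
            raise ValidationError(f"read {self.read_id}: unknown status {self.status!r}")
        n = len(self.placements)
        if self.status in ("assembled", "partially_assembled"):
            if n == 0:
                raise ValidationError(f"read {self.read_id}: {self.status} but no placement")
        else:
            if n != 0:
                raise ValidationError(f"read {self.read_id}: {self.status} with placements")
        if n > 2:
            raise ValidationError(f"read {self.read_id}: more than two placements")
        if n == 2:
            a, b = self.placements
            if a.contig_id == b.contig_id:
                raise ValidationError(
                    f"read {self.read_id}: both placements on contig {a.contig_id}"
                )
            lo, hi = sorted((a, b), key=lambda p: p.read_start)
            if hi.read_start <= lo.read_end:
                raise ValidationError(
                    f"read {self.read_id}: split placements overlap on the read"
                )

    @property
    def is_split(self) -> bool:
        return len(self.placements) == 2


@dataclass(frozen=True)
class BlastHit:
    """One row of tabular homology evidence (db name + standard 12 columns)."""

    query_id: str
    db_name: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: identity out of [0,100]"
            )
        if self.query_start > self.query_end:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: query_start > query_end"
            )
        if self.evalue < 0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: negative evalue")
        if self.bitscore < 0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: negative bitscore")


@dataclass(frozen=True)
class VariantRecord:
    """A SNP or INDEL call on a contig with coverage and posterior probability.

    INDEL convention: deletions carry the deleted base(s) as ``ref_allele`` and
    ``"-"`` as ``alt_allele``; insertions the reverse.
    """

    contig_id: str
    position: int
    ref_allele: str
    alt_allele: str
    var_type: str
    coverage: int
    probability: float

    def __post_init__(self) -> None:
        if self.var_type not in ("SNP", "INS", "DEL"):
            raise ValidationError(f"{self.contig_id}:{self.position}: bad var_type")
        if self.position < 1:
            raise ValidationError(f"{self.contig_id}:{self.position}: position must be >= 1")
        if self.coverage < 0:
            raise ValidationError(f"{self.contig_id}:{self.position}: negative coverage")
        if not (0.0 <= self.probability <= 1.0):
            raise ValidationError(
                f"{self.contig_id}:{self.position}: probability out of [0,1]"
            )
        if self.var_type == "SNP":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValidationError(
                    f"{self.contig_id}:{self.position}: SNP alleles must be single bases"
                )
            if self.ref_allele == self.alt_allele:
                raise ValidationError(
                    f"{self.contig_id}:{self.position}: SNP alleles identical"
                )

    @property
    def is_indel(self) -> bool:
        return self.var_type in ("INS", "DEL")


@dataclass(frozen=True)
class OrfRecord:
    """A predicted open reading frame, 0-based half-open on the contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"ORF on {self.contig_id}: end <= start")
        if (self.end - self.start) < 30:
            raise ValidationError(f"ORF on {self.contig_id}: shorter than 30 bp")
        if (self.end - self.start) % 3 != 0:
            raise ValidationError(f"ORF on {self.contig_id}: length not a codon multiple")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"ORF on {self.contig_id}: bad strand")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GoAnnotation:
    seq_id: str
    term_id: str

    def __post_init__(self) -> None:
        if not self.seq_id or not self.term_id:
            raise ValidationError("empty field in GO annotation")
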