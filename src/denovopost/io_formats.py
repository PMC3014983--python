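"""Readers and writers for every on-disk artifact the pipeline touches.

All tables are plain TSV with ``#`` comment headers stating the coordinate
convention.  FASTA goes through Biopython.  The read-status table is a
project-defined format (the upstream assembler's native formats are out of
scope here); its layout is normative:

    read_id <TAB> sex <TAB> status [<TAB> placement [<TAB> placement]]
    placement = contig_id:read_start-read_end:strand:contig_start

Variants are stored as TSV rather than VCF because the calls are against
transcript contigs and carry a per-call posterior probability; a minimal VCF
exporter is provided for interchange.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .records import (
    BlastHit,
    GoAnnotation,
    OrfRecord,
    ReadPlacement,
    ReadStatusRecord,
    SequenceRecord,
    ValidationError,
    VariantRecord,
)

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Duplicate ids and empty sequences are hard errors naming the offender.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if not residues:
            raise ValidationError(f"empty sequence for id {rec.id!r} in {path}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    """Write records as FASTA, wrapped at 80 columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# read status table

_READ_STATUS_HEADER = (
    "# read_status v1: read_id<TAB>sex<TAB>status[<TAB>placement[<TAB>placement]]\n"
    "# placement = contig_id:read_start-read_end:strand:contig_start "
    "(1-based inclusive)\n"
)


def _parse_placement(token: str, lineno: int) -> ReadPlacement:
    try:
        contig_id, span, strand, contig_start = token.split(":")
        start_s, end_s = span.split("-")
        return ReadPlacement(
            contig_id=contig_id,
            read_start=int(start_s),
            read_end=int(end_s),
            contig_start=int(contig_start),
            strand=strand,
        )
    except (ValueError, ValidationError) as exc:
        raise ValidationError(f"line {lineno}: bad placement {token!r}: {exc}") from exc


def _format_placement(p: ReadPlacement) -> str:
    return f"{p.contig_id}:{p.read_start}-{p.read_end}:{p.strand}:{p.contig_start}"


def read_read_status(path: str | os.PathLike) -> list[ReadStatusRecord]:
    records: list[ReadStatusRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"line {lineno}: expected >=3 fields")
            read_id, sex, status = fields[:3]
            placements = tuple(
                _parse_placement(tok, lineno) for tok in fields[3:] if tok
            )
            try:
                records.append(
                    ReadStatusRecord(
                        read_id=read_id, sex=sex, status=status, placements=placements
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
    return records


def write_read_status(
    records: Iterable[ReadStatusRecord], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write(_READ_STATUS_HEADER)
        for r in records:
            fields = [r.read_id, r.sex, r.status]
            fields.extend(_format_placement(p) for p in r.placements)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# tabular readers (blast / variant / orf / go)


def _rows(path: str | os.PathLike):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _parse_blast_row(fields: Sequence[str], lineno: int) -> BlastHit:
    if len(fields) != 13:
        raise ValidationError(f"line {lineno}: blast row needs 13 columns")
    (db, q, s, pid, alen, mm, go_, qs, qe, ss, se, ev, bs) = fields
    return BlastHit(
        query_id=q,
        db_name=db,
        subject_id=s,
        percent_identity=float(pid),
        align_length=int(alen),
        mismatches=int(mm),
        gap_opens=int(go_),
        query_start=int(qs),
        query_end=int(qe),
        subject_start=int(ss),
        subject_end=int(se),
        evalue=float(ev),
        bitscore=float(bs),
    )


def _parse_variant_row(fields: Sequence[str], lineno: int) -> VariantRecord:
    if len(fields) != 7:
        raise ValidationError(f"line {lineno}: variant row needs 7 columns")
    contig, pos, ref, alt, vtype, cov, prob = fields
    return VariantRecord(
        contig_id=contig,
        position=int(pos),
        ref_allele=ref,
        alt_allele=alt,
        var_type=vtype,
        coverage=int(cov),
        probability=float(prob),
    )


def _parse_orf_row(fields: Sequence[str], lineno: int) -> OrfRecord:
    # BED6: chrom start end name score strand
    if len(fields) < 6:
        raise ValidationError(f"line {lineno}: orf row needs 6 BED columns")
    contig, start, end, _name, _score, strand = fields[:6]
    return OrfRecord(contig_id=contig, start=int(start), end=int(end), strand=strand)


def _parse_go_row(fields: Sequence[str], lineno: int) -> GoAnnotation:
    if len(fields) != 2:
        raise ValidationError(f"line {lineno}: go row needs 2 columns")
    return GoAnnotation(seq_id=fields[0], term_id=fields[1])


_SCHEMAS = {
    "blast": _parse_blast_row,
    "variant": _parse_variant_row,
    "orf": _parse_orf_row,
    "go": _parse_go_row,
}


def read_tabular(path: str | os.PathLike, schema: str) -> list:
    """Read a TSV file into typed records; row order is preserved.

    ``schema`` is one of ``blast`` (leading db_name column + the standard
    12-column tabular hit format), ``variant``, ``orf`` (BED6) or ``go``.
    Out-of-range values raise :class:`ValidationError` with the row number.
    """
    try:
        parser = _SCHEMAS[schema]
    except KeyError:
        raise ValueError(f"unknown schema {schema!r}") from None
    out = []
    seen_go: set[tuple[str, str]] = set()
    for lineno, fields in _rows(path):
        try:
            rec = parser(fields, lineno)
        except ValidationError as exc:
            if str(exc).startswith(f"line {lineno}"):
                raise
            raise ValidationError(f"line {lineno}: {exc}") from exc
        except ValueError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from exc
        if schema == "go":
            key = (rec.seq_id, rec.term_id)
            if key in seen_go:
                raise ValidationError(f"line {lineno}: duplicate GO pair {key}")
            seen_go.add(key)
        out.append(rec)
    return out


def write_blast_hits(hits: Iterable[BlastHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# blast.tsv: db_name + standard 12 tabular columns "
            "(1-based inclusive coordinates)\n"
        )
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.db_name,
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        h.align_length,
                        h.mismatches,
                        h.gap_opens,
                        h.query_start,
                        h.query_end,
                        h.subject_start,
                        h.subject_end,
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


def write_variants(variants: Iterable[VariantRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# variants.tsv: contig_id pos(1-based) ref alt type coverage probability\n"
        )
        for v in variants:
            fh.write(
                f"{v.contig_id}\t{v.position}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t{v.var_type}\t{v.coverage}\t{v.probability:.6f}\n"
            )


def write_orfs(orfs: Iterable[OrfRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# orfs.bed: BED6, 0-based half-open\n")
        for i, o in enumerate(orfs):
            fh.write(f"{o.contig_id}\t{o.start}\t{o.end}\torf{i}\t0\t{o.strand}\n")


def write_go_map(annotations: Iterable[GoAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# go_map.tsv: seq_id term_id\n")
        for a in annotations:
            fh.write(f"{a.seq_id}\t{a.term_id}\n")


def write_variants_vcf(
    variants: Iterable[VariantRecord],
    contigs: dict[str, str],
    path: str | os.PathLike,
) -> None:
    """Export variant calls as a minimal VCF 4.2 file.

    The posterior probability travels in the ``PROB`` INFO field and coverage
    in ``DP``.  INDELs are left-anchored on the preceding reference base as
    VCF requires.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read coverage">\n')
        fh.write(
            '##INFO=<ID=PROB,Number=1,Type=Float,Description="Posterior probability">\n'
        )
        for cid in sorted(contigs):
            fh.write(f"##contig=<ID={cid},length={len(contigs[cid])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            seq = contigs.get(v.contig_id)
            if seq is None:
                raise ValidationError(f"variant on unknown contig {v.contig_id}")
            if v.var_type == "SNP":
                pos, ref, alt = v.position, v.ref_allele, v.alt_allele
            elif v.var_type == "DEL":
                if v.position > 1:  # anchor on the preceding base
                    pos = v.position - 1
                    anchor = seq[pos - 1]
                    ref, alt = anchor + v.ref_allele, anchor
                else:  # deletion of base 1 anchors on the following base
                    pos = 1
                    anchor = seq[v.position - 1 + len(v.ref_allele)]
                    ref, alt = v.ref_allele + anchor, anchor
            else:  # INS (inserted before `position`)
                if v.position > 1:
                    pos = v.position - 1
                    anchor = seq[pos - 1]
                    ref, alt = anchor, anchor + v.alt_allele
                else:
                    pos = 1
                    anchor = seq[0]
                    ref, alt = anchor, v.alt_allele + anchor
            fh.write(
                f"{v.contig_id}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t"
                f"DP={v.coverage};PROB={v.probability:.6f}\n"
            )
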