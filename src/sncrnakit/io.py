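"""Readers and writers: FASTA, GFF3, BED6, BLAST-style tabular hits, and the
printed sncRNA locus-table dialect (``ID  Location  Strand  Distance  Neighbor``).

Every reader converts into the package's internal 0-based half-open
coordinates and every writer converts back out; GFF3 and locus tables are
1-based inclusive on disk, BED is natively 0-based half-open.  Location
strings like ``scaffold_59_650694–650810`` split on the RIGHTMOST underscore
(contig ids may themselves contain underscores) and accept an en-dash or an
ASCII hyphen between the coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .context import GeneModel, SncRnaLocus, infer_rna_class
from .homology import HomologyHit

__all__ = [
    "Contig",
    "LocusTableRow",
    "ParseError",
    "INTRON_SENTINEL",
    "parse_location_string",
    "format_location_string",
    "read_locus_table",
    "write_locus_table",
    "read_fasta",
    "write_fasta",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_bed_loci",
    "write_bed_loci",
    "read_hits_tabular",
    "write_hits_tabular",
]

INTRON_SENTINEL = "Intron"

_VALID_BASES = set("ACGTN")
_CLEAN_TABLE = str.maketrans(
    {c: ("N" if c not in _VALID_BASES else c) for c in map(chr, range(256))}
)
# en dash, hyphen, figure dash, em dash all accepted between coordinates
_LOCATION_RE = re.compile(r"^(?P<contig>.+)_(?P<start>\d+)[–\-‒—](?P<end>\d+)$")
_STRANDS = {"+": "+", "-": "-", "−": "-"}


class ParseError(ValueError):
    """Malformed record in an input file; message names the offending row."""


@dataclass(frozen=True)
class Contig:
    """One genomic sequence over the alphabet {A, C, G, T, N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be nonempty")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"contig {self.id}: invalid letters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LocusTableRow:
    """One printed locus-table row; span stored 0-based half-open.

    ``location_field`` is either a nonnegative distance in bp or the literal
    intron sentinel.  Duplicate rows in a table are preserved as distinct
    records.
    """

    id: str
    contig: str
    start: int
    end: int
    strand: str
    location_field: "int | str"
    neighbor: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"row {self.id}: empty span")
        if self.strand not in ("+", "-"):
            raise ValueError(f"row {self.id}: bad strand {self.strand!r}")
        if isinstance(self.location_field, str):
            if self.location_field != INTRON_SENTINEL:
                raise ValueError(
                    f"row {self.id}: location field must be a distance or "
                    f"{INTRON_SENTINEL!r}, got {self.location_field!r}"
                )
        elif self.location_field < 0:
            raise ValueError(f"row {self.id}: negative distance")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_intron(self) -> bool:
        return self.location_field == INTRON_SENTINEL

    def to_locus(self, rna_class: str | None = None) -> SncRnaLocus:
        return SncRnaLocus(
            id=self.id,
            rna_class=rna_class or infer_rna_class(self.id),
            contig=self.contig,
            start=self.start,
            end=self.end,
            strand=self.strand,
        )


def parse_location_string(s: str) -> tuple[str, int, int]:
    """Split ``<contig>_<start>–<end>`` into its parts (1-based inclusive).

    The contig id is everything left of the rightmost underscore, so ids
    like ``scaffold_59`` survive intact.
    """
    m = _LOCATION_RE.match(s.strip())
    if m is None:
        raise ParseError(f"malformed location string {s!r}")
    start, end = int(m.group("start")), int(m.group("end"))
    if start > end:
        raise ParseError(f"location {s!r}: start > end")
    return m.group("contig"), start, end


def format_location_string(contig: str, start1: int, end1: int) -> str:
    """Inverse of :func:`parse_location_string` (emits the en-dash dialect)."""
    return f"{contig}_{start1}–{end1}"


_LOCUS_HEADER = "ID\tLocation\tStrand\tDistance to gene boundary\tNeighbor"


def read_locus_table(path: "str | Path") -> list[LocusTableRow]:
    """Read a printed-dialect locus table (optional header line)."""
    rows: list[LocusTableRow] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if lineno == 1 and line.split("\t")[0].strip().upper() == "ID":
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 5:
                raise ParseError(
                    f"{path}, line {lineno}: expected 5 columns, got {len(fields)}"
                )
            locus_id, location, strand, distance, neighbor = (
                f.strip() for f in fields
            )
            try:
                contig, start1, end1 = parse_location_string(location)
            except ParseError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
            if strand not in _STRANDS:
                raise ParseError(f"{path}, line {lineno}: bad strand {strand!r}")
            loc_field: int | str
            if distance.lower() == INTRON_SENTINEL.lower():
                loc_field = INTRON_SENTINEL
            else:
                try:
                    loc_field = int(distance)
                except ValueError:
                    raise ParseError(
                        f"{path}, line {lineno}: distance {distance!r} is neither "
                        f"an integer nor {INTRON_SENTINEL!r}"
                    ) from None
            rows.append(
                LocusTableRow(
                    id=locus_id,
                    contig=contig,
                    start=start1 - 1,
                    end=end1,
                    strand=_STRANDS[strand],
                    location_field=loc_field,
                    neighbor=neighbor,
                )
            )
    return rows


def write_locus_table(rows: Iterable[LocusTableRow], path: "str | Path") -> None:
    """Write rows in the printed dialect (en-dash, U+2212 minus strand)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_LOCUS_HEADER + "\n")
        for row in rows:
            strand = "−" if row.strand == "-" else "+"
            fh.write(
                "\t".join(
                    (
                        row.id,
                        format_location_string(row.contig, row.start + 1, row.end),
                        strand,
                        str(row.location_field),
                        row.neighbor,
                    )
                )
                + "\n"
            )


def read_fasta(path: "str | Path") -> list[Contig]:
    """Read FASTA; lowercase is uppercased, non-ACGTN letters become N."""
    contigs: list[Contig] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ParseError(f"{path}: duplicate contig id {record.id!r}")
        seen.add(record.id)
        seq = str(record.seq).upper().translate(_CLEAN_TABLE)
        contigs.append(Contig(id=record.id, sequence=seq))
    if not contigs:
        raise ParseError(f"{path}: no FASTA records")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: "str | Path") -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gff3_genes(path: "str | Path") -> list[GeneModel]:
    """Build gene models from GFF3 gene/mRNA/CDS features.

    One model per gene id: the ORF span is [min CDS start, max CDS end] and
    coding exons are the CDS intervals.  Overlapping CDS within one gene or
    CDS without a gene ancestor are errors.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    gene_ids = set()
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gene_ids.add(gene.id)
        cds = sorted(
            db.children(gene, featuretype="CDS"), key=lambda f: (f.start, f.end)
        )
        if not cds:
            raise ParseError(f"gene {gene.id}: no CDS features")
        exons: list[tuple[int, int]] = []
        for f in cds:
            iv = (f.start - 1, f.end)
            if exons and iv[0] < exons[-1][1]:
                raise ParseError(f"gene {gene.id}: overlapping CDS intervals")
            exons.append(iv)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand if gene.strand in ("+", "-") else "+",
                start=exons[0][0],
                end=exons[-1][1],
                exons=tuple(exons),
            )
        )
    for f in db.features_of_type("CDS"):
        if not any(p.id in gene_ids for p in db.parents(f)):
            raise ParseError(f"CDS at {f.seqid}:{f.start}-{f.end} has no parent gene")
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path: "str | Path") -> None:
    """Write gene models as GFF3 gene/mRNA/CDS features (1-based inclusive)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tsncrnakit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.contig}\tsncrnakit\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.contig}\tsncrnakit\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f"0\tID={g.gene_id}.cds{i};Parent={g.gene_id}.t1\n"
                )


def read_bed_loci(path: "str | Path") -> list[SncRnaLocus]:
    """Read sncRNA loci from BED6 (0-based half-open, native convention)."""
    loci: list[SncRnaLocus] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}, line {lineno}: BED6 needs 6 columns")
            contig, start, end, name, _score, strand = fields[:6]
            if strand not in _STRANDS:
                raise ParseError(f"{path}, line {lineno}: bad strand {strand!r}")
            loci.append(
                SncRnaLocus(
                    id=name,
                    rna_class=infer_rna_class(name),
                    contig=contig,
                    start=int(start),
                    end=int(end),
                    strand=_STRANDS[strand],
                )
            )
    return loci


def write_bed_loci(loci: Iterable[SncRnaLocus], path: "str | Path") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for locus in loci:
            fh.write(
                f"{locus.contig}\t{locus.start}\t{locus.end}\t{locus.id}\t0\t"
                f"{locus.strand}\n"
            )


def read_hits_tabular(path: "str | Path") -> list[HomologyHit]:
    """Read BLAST-style 12-column tabular hits.

    Columns: query, subject, %identity, alignment length, mismatches, gap
    opens, qstart, qend, sstart, send, evalue, bitscore (all coordinates
    1-based inclusive).  The subject strand is inferred from sstart > send.
    """
    hits: list[HomologyHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}, line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                identity = float(fields[2])
                aln_len = int(fields[3])
                mismatches = int(fields[4])
                gap_opens = int(fields[5])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                score = float(fields[11])
            except ValueError:
                raise ParseError(
                    f"{path}, line {lineno}: non-numeric value in numeric column"
                ) from None
            if sstart <= send:
                strand, s_start, s_end = "+", sstart - 1, send
            else:
                strand, s_start, s_end = "-", send - 1, sstart
            hits.append(
                HomologyHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    identity=identity,
                    aln_len=aln_len,
                    mismatches=mismatches,
                    gap_opens=gap_opens,
                    q_start=qstart - 1,
                    q_end=qend,
                    s_start=s_start,
                    s_end=s_end,
                    strand=strand,
                    evalue=evalue,
                    score=score,
                )
            )
    return hits


def write_hits_tabular(hits: Iterable[HomologyHit], path: "str | Path") -> None:
    """Write hits in the 12-column tabular dialect (round-trips exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            if h.strand == "+":
                sstart, send = h.s_start + 1, h.s_end
            else:
                sstart, send = h.s_end, h.s_start + 1
            fh.write(
                "\t".join(
                    (
                        h.query_id,
                        h.subject_id,
                        f"{h.identity:.2f}",
                        str(h.aln_len),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start + 1),
                        str(h.q_end),
                        str(sstart),
                        str(send),
                        repr(h.evalue),
                        repr(h.score),
                    )
                )
                + "\n"
            )
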