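"""File-format readers and writers for the pipeline's minimal dialects.

FASTA goes through Biopython and is normalized to upper case on read.
SAM is the minimal six-column dialect the pipeline needs (QNAME, FLAG,
RNAME, POS, MAPQ, CIGAR); optional columns are tolerated and ignored.
GFF3 parsing covers exactly the feature rows the feature summaries
consume (CDS/tRNA/rRNA/tmRNA with product / translation attributes).
"""

from __future__ import annotations

import dataclasses
import io as _stdio
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# FASTA


@dataclass
class FastaRecord:
    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[FastaRecord]:
    """Read FASTA records, upper-casing sequences.

    Raises ``ValueError`` on duplicate ids or empty sequences.
    """
    records: list[FastaRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA id: {rec.id}")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(FastaRecord(rec.id, seq, desc))
    return records


def write_fasta(records: Iterable[FastaRecord], path, width: int = 80) -> None:
    seqs = []
    for r in records:
        if not r.sequence:
            raise ValueError(f"refusing to write empty sequence: {r.id}")
        seqs.append(SeqRecord(Seq(r.sequence.upper()), id=r.id, description=r.description))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def parse_header_fields(description: str) -> dict[str, str]:
    """Parse ``key=value`` pairs from a FASTA description line."""
    return dict(m.groups() for m in re.finditer(r"(\w+)=(\S+)", description))


# ---------------------------------------------------------------------------
# SAM (minimal dialect)

CIGAR_OPS = set("MIDNSH=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


@dataclass
class AlignmentRecord:
    """One alignment line: the six leading SAM columns the pipeline uses."""

    query_name: str
    flag: int
    reference_name: str
    position: int  # 1-based leftmost reference coordinate
    cigar: list[tuple[int, str]]
    sequence: str | None = None

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED) or self.reference_name == "*"

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    def reference_length(self) -> int:
        """Reference bases consumed (M/=/X/D/N)."""
        return sum(n for n, op in self.cigar if op in "M=XDN")

    def query_length(self) -> int:
        """Query bases consumed (M/=/X/I/S)."""
        return sum(n for n, op in self.cigar if op in "M=XIS")

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for n, op in self.cigar)


def parse_cigar(text: str) -> list[tuple[int, str]]:
    if text == "*":
        return []
    ops = _CIGAR_RE.findall(text)
    if "".join(f"{n}{op}" for n, op in ops) != text:
        raise ValueError(f"malformed CIGAR: {text!r}")
    return [(int(n), op) for n, op in ops]


def read_alignments(path) -> list[AlignmentRecord]:
    """Parse a SAM body. Header (@) lines skipped; '*' CIGAR records skipped.

    Only columns 1-6 are required; column 10 (SEQ) is kept when present.
    Records with a sequence are checked for CIGAR/sequence length agreement.
    """
    records: list[AlignmentRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"line {ln}: fewer than 6 SAM columns")
            cigar_text = cols[5]
            if cigar_text == "*":
                n_skipped += 1
                continue
            cigar = parse_cigar(cigar_text)
            seq = None
            if len(cols) >= 10 and cols[9] not in ("*", ""):
                seq = cols[9].upper()
            rec = AlignmentRecord(cols[0], int(cols[1]), cols[2], int(cols[3]), cigar, seq)
            if rec.position < 1 and not rec.is_unmapped:
                raise ValueError(f"line {ln}: POS must be >= 1")
            if seq is not None and rec.query_length() != len(seq):
                raise ValueError(
                    f"line {ln}: CIGAR consumes {rec.query_length()} query bases "
                    f"but SEQ has {len(seq)}"
                )
            records.append(rec)
    read_alignments.last_skipped = n_skipped  # type: ignore[attr-defined]
    return records


def write_alignments(records: Iterable[AlignmentRecord], path,
                     reference_lengths: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        if reference_lengths:
            for name, length in reference_lengths.items():
                fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in records:
            seq = r.sequence if r.sequence else "*"
            fh.write(
                f"{r.query_name}\t{r.flag}\t{r.reference_name}\t{r.position}\t60\t"
                f"{r.cigar_string()}\t*\t0\t0\t{seq}\t*\n"
            )


# ---------------------------------------------------------------------------
# GFF3 (minimal)


@dataclass
class GeneModel:
    """One annotated feature; coordinates are 1-based inclusive."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    feature_class: str  # CDS | tRNA | rRNA | tmRNA
    product: str = ""
    translation: str | None = None
    partial: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    def length(self) -> int:
        return self.end - self.start + 1


_FEATURE_CLASSES = {"CDS", "tRNA", "rRNA", "tmRNA"}


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, val = part.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_gff3(path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"line {ln}: GFF3 needs 9 columns")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in _FEATURE_CLASSES:
                continue
            a = _parse_attributes(attrs)
            gid = a.get("ID") or a.get("locus_tag") or f"feature_{ln}"
            genes.append(GeneModel(
                gene_id=gid, contig_id=contig, start=int(start), end=int(end),
                strand=strand if strand in "+-" else "+",
                feature_class=ftype, product=a.get("product", ""),
                translation=a.get("translation"),
                partial=a.get("partial", "false").lower() == "true",
            ))
    return genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}"]
            if g.product:
                attrs.append(f"product={g.product}")
            if g.translation:
                attrs.append(f"translation={g.translation}")
            if g.partial:
                attrs.append("partial=true")
            fh.write(
                f"{g.contig_id}\tendomine\t{g.feature_class}\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\t{';'.join(attrs)}\n"
            )


# ---------------------------------------------------------------------------
# BED / TSV segment output (used by anatomy)


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path) -> None:
    """Write (chrom, start_1based, end_1based, name) as 0-based half-open BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# gene -> GO tables


def read_gene2go(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, GO_id), one association per line."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, go = line.split("\t")[:2]
            table.setdefault(gene, set()).add(go)
    return table


def write_gene2go(table: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(table):
            for go in sorted(table[gene]):
                fh.write(f"{gene}\t{go}\n")
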