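"""Readers and writers for the standard formats the pipeline touches.

Internally every coordinate is 0-based half-open; conversion to and from
1-based conventions (SAM, RepeatMasker .out, VCF) happens only here, at the
format boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from io import StringIO

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_ALPHABET = frozenset("ACGTN")

_CIGAR_OPS = "MIDNSHP=X"
_SUPPORTED_CIGAR = frozenset("MIDS")
# ops that consume query sequence
_QUERY_OPS = frozenset("MIS=X")


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass
class SequenceRecord:
    """A named uppercase DNA sequence."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence id must be nonempty")
        if len(self.seq) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self):
        return len(self.seq)


@dataclass
class GenomicInterval:
    """0-based half-open interval with a name and strand."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise FormatError("interval start must be >= 0")
        if self.end <= self.start:
            raise FormatError(
                f"interval end must exceed start ({self.chrom}:{self.start}-{self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"bad strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AlignedRead:
    """The SAM fields the pipeline interprets (a deliberate subset)."""

    qname: str
    chrom: str | None  # None when unmapped
    pos: int  # 0-based leftmost; -1 when unmapped
    strand: str
    cigar: str
    mapq: int
    seq: str
    mate_chrom: str | None = None
    mate_pos: int = -1
    mate_strand: str = "."
    is_proper_pair: bool = False
    insert_size: int = 0
    is_read1: bool = True

    @property
    def is_unmapped(self) -> bool:
        return self.chrom is None

    @property
    def end(self) -> int:
        """Rightmost reference coordinate (exclusive) of the alignment."""
        if self.is_unmapped:
            return -1
        span = 0
        for n, op in _split_cigar(self.cigar):
            if op in "MD":
                span += n
        return self.pos + span


def _split_cigar(cigar: str):
    if cigar in ("*", ""):
        return []
    return [(int(n), op) for n, op in re.findall(r"(\d+)([A-Z=])", cigar)]


def _check_cigar(cigar: str, seqlen: int, qname: str):
    ops = _split_cigar(cigar)
    qlen = 0
    for n, op in ops:
        if op not in _SUPPORTED_CIGAR:
            raise FormatError(f"read {qname!r}: unsupported CIGAR op {op!r}")
        if op in _QUERY_OPS:
            qlen += n
    if ops and qlen != seqlen:
        raise FormatError(
            f"read {qname!r}: CIGAR consumes {qlen} bases but SEQ has {seqlen}"
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into uppercase DNA records.

    Empty files yield an empty list; illegal residues (anything outside
    A/C/G/T/N after uppercasing) are an error.
    """
    records = []
    with open(path) as fh:
        first = fh.read(1)
        if first == "":
            return []
        if first != ">":
            raise FormatError(f"{path}: not FASTA (expected '>' header)")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records, path, wrap: int = 60) -> None:
    """Write records as wrapped FASTA; inverse of :func:`read_fasta`."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Intervals (BED6 and RepeatMasker .out)


def read_intervals(path, dialect: str = "bed", name_filter: str | None = None):
    """Read genomic intervals from BED6 or RepeatMasker .out.

    BED coordinates pass through unchanged; RepeatMasker's 1-based inclusive
    begin/end are converted to 0-based half-open. ``name_filter`` keeps only
    rows whose name contains the substring (e.g. ``"CfERVF1"``).
    """
    if dialect == "bed":
        intervals = _read_bed(path)
    elif dialect == "repeatmasker_out":
        intervals = _read_rm_out(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if name_filter is not None:
        intervals = [iv for iv in intervals if name_filter in iv.name]
    return intervals


def _read_bed(path):
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            name = cols[3] if len(cols) > 3 else "."
            strand = cols[5] if len(cols) > 5 else "."
            out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2]), name, strand))
    return out


def _read_rm_out(path):
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            # the two header lines start with the literal column labels
            if stripped.startswith(("SW", "score")):
                continue
            cols = stripped.split()
            if len(cols) < 11:
                raise FormatError(
                    f"{path}:{lineno}: RepeatMasker row has {len(cols)} columns, expected >= 11"
                )
            chrom, begin, end = cols[4], int(cols[5]), int(cols[6])
            strand = "-" if cols[8] == "C" else "+"
            name = cols[9]
            out.append(GenomicInterval(chrom, begin - 1, end, name, strand))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# SAM subset


def read_sam_subset(path) -> list[AlignedRead]:
    """Read a header-bearing SAM file into :class:`AlignedRead` records.

    Only M/I/D/S CIGAR ops are accepted; coordinates become 0-based.
    Unmapped reads are retained with ``chrom=None``.
    """
    reads = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        try:
            iterator = list(sam.fetch(until_eof=True))
        except (OSError, ValueError) as exc:  # htslib-level parse failure
            raise FormatError(f"{path}: {exc}") from exc
        for aln in iterator:
            seq = aln.query_sequence or ""
            cigar = aln.cigarstring or "*"
            if not aln.is_unmapped:
                _check_cigar(cigar, len(seq), aln.query_name)
            reads.append(
                AlignedRead(
                    qname=aln.query_name,
                    chrom=None if aln.is_unmapped else aln.reference_name,
                    pos=-1 if aln.is_unmapped else aln.reference_start,
                    strand="-" if aln.is_reverse else "+",
                    cigar="*" if aln.is_unmapped else cigar,
                    mapq=min(60, aln.mapping_quality),
                    seq=seq.upper(),
                    mate_chrom=(
                        None if aln.mate_is_unmapped or aln.next_reference_id < 0
                        else aln.next_reference_name
                    ),
                    mate_pos=aln.next_reference_start,
                    mate_strand="-" if aln.mate_is_reverse else "+",
                    is_proper_pair=aln.is_proper_pair,
                    insert_size=aln.template_length,
                    is_read1=not aln.is_read2,
                )
            )
    return reads


def write_sam_subset(reads, references: dict, path) -> None:
    """Write :class:`AlignedRead` records as SAM (the mapper's output format).

    ``references`` maps chromosome name to length for the @SQ header.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in reads:
            flag = 1  # paired
            flag |= 64 if r.is_read1 else 128
            if r.is_proper_pair:
                flag |= 2
            if r.is_unmapped:
                flag |= 4
            if r.mate_chrom is None:
                flag |= 8
            if r.strand == "-":
                flag |= 16
            if r.mate_strand == "-":
                flag |= 32
            rname = r.chrom if r.chrom else "*"
            pos = r.pos + 1 if not r.is_unmapped else 0
            if r.mate_chrom is None:
                rnext, pnext = "*", 0
            elif r.mate_chrom == r.chrom:
                rnext, pnext = "=", r.mate_pos + 1
            else:
                rnext, pnext = r.mate_chrom, r.mate_pos + 1
            fh.write(
                f"{r.qname}\t{flag}\t{rname}\t{pos}\t{r.mapq}\t{r.cigar}\t"
                f"{rnext}\t{pnext}\t{r.insert_size}\t{r.seq}\t*\n"
            )


# ---------------------------------------------------------------------------
# VCF


def write_vcf(calls, samples, reference_name, path) -> None:
    """Write genotype calls as VCF 4.2 with symbolic mobile-element alleles.

    ``calls`` maps ``locus`` (an object with ``locus_id``, ``chrom``, ``pos``,
    ``is_reference`` and optional ``tsd``/``form`` attributes) to a dict of
    ``sample_id -> GenotypeCall``-like objects carrying ``gt``, ``gl``, ``ad``.
    Samples absent from a locus's call set are emitted as missing ("./.").
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        fh.write('##ALT=<ID=INS:ME:ERV,Description="ERV insertion">\n')
        fh.write('##ALT=<ID=DEL:ME:ERV,Description="ERV excision relative to reference">\n')
        fh.write('##INFO=<ID=TSD,Number=1,Type=String,Description="Target site duplication">\n')
        fh.write('##INFO=<ID=FORM,Number=1,Type=String,Description="Allele form (solo_ltr/provirus)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GL,Number=3,Type=Float,Description="Log10 genotype likelihoods">\n')
        fh.write('##FORMAT=<ID=AD,Number=2,Type=Integer,Description="Ref,alt supporting read pairs">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for locus in sorted(calls, key=lambda l: (l.chrom, l.pos)):
            sample_calls = calls[locus]
            alt = "<DEL:ME:ERV>" if getattr(locus, "is_reference", False) else "<INS:ME:ERV>"
            info = []
            tsd = getattr(locus, "tsd", None)
            if tsd:
                info.append(f"TSD={tsd}")
            form = getattr(locus, "form", None)
            if form:
                info.append(f"FORM={form}")
            info_str = ";".join(info) if info else "."
            fields = []
            for s in samples:
                call = sample_calls.get(s)
                if call is None or call.gt == "./.":
                    fields.append("./.")
                else:
                    gl = ",".join(f"{x:.2f}" for x in call.gl)
                    fields.append(f"{call.gt}:{gl}:{call.ad[0]},{call.ad[1]}")
            fh.write(
                f"{locus.chrom}\t{locus.pos + 1}\t{locus.locus_id}\tN\t{alt}\t.\t.\t"
                f"{info_str}\tGT:GL:AD\t" + "\t".join(fields) + "\n"
            )


def read_population_table(path) -> dict:
    """Read a two-column sample_id<TAB>population table."""
    table = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            table[cols[0]] = cols[1]
    return table


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return str(Seq(seq).reverse_complement())
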