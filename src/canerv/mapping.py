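"""A minimal exact-seed read mapper.

This is deliberately simple plumbing: reads are anchored by exact k-mer
seeds and scored by mismatch count against the reference. It exists so the
whole pipeline runs at desk scale without an external aligner; SAM from any
real mapper is the alternative entry point for every downstream stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .formats import AlignedRead, revcomp


@dataclass
class Hit:
    chrom: str
    pos: int
    strand: str
    score: int
    mapq: int


class ReferenceIndex:
    """Exact k-mer index over a set of reference chromosomes."""

    def __init__(self, records, k: int = 20, max_hits_per_kmer: int = 64):
        self.k = k
        self.seqs = {rec.id: rec.seq for rec in records}
        self.lengths = {rec.id: len(rec.seq) for rec in records}
        self.max_hits = max_hits_per_kmer
        index: dict = {}
        for chrom, seq in self.seqs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                lst = index.get(kmer)
                if lst is None:
                    index[kmer] = [(chrom, i)]
                elif len(lst) < max_hits_per_kmer:
                    lst.append((chrom, i))
        self._index = index

    def seed_hits(self, kmer: str):
        return self._index.get(kmer, ())


def _mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def map_read(read_seq: str, index: ReferenceIndex, min_seed: int = 20):
    """Map one read; returns the best :class:`Hit` or ``None`` if unmapped.

    Candidate placements come from exact seeds at three offsets on both
    strands; each is scored ``len - 2 x mismatches``. The mapping-quality
    proxy is ``min(60, round(-10 log10(second_best/best)))``, 60 for unique
    hits and 0 for perfect ties.
    """
    k = index.k
    L = len(read_seq)
    if L < k or L < min_seed:
        return None
    max_mm = max(3, L // 8)  # placements worse than this cannot score > 0 usefully
    offsets = (0, (L - k) // 2, L - k)
    candidates = {}
    for strand in "+-":
        s = read_seq if strand == "+" else revcomp(read_seq)
        for off in offsets:
            for chrom, pos in index.seed_hits(s[off : off + k]):
                start = pos - off
                if start < 0 or start + L > index.lengths[chrom]:
                    continue
                key = (chrom, start, strand)
                if key in candidates:
                    continue
                mm = _mismatches(s, index.seqs[chrom][start : start + L], max_mm)
                candidates[key] = L - 2 * mm
    if not candidates:
        return None
    ranked = sorted(candidates.items(), key=lambda kv: (-kv[1], kv[0]))
    (chrom, start, strand), best = ranked[0]
    if best <= 0:
        return None
    if len(ranked) == 1 or ranked[1][1] <= 0:
        mapq = 60
    else:
        ratio = max(1e-6, ranked[1][1] / best)
        mapq = min(60, round(-10 * math.log10(ratio)))
    return Hit(chrom, start, strand, best, mapq)


def map_pair(name, seq1, seq2, index: ReferenceIndex, max_proper_insert: int = 100_000):
    """Map a read pair, returning two :class:`AlignedRead` records.

    A pair is flagged proper when both mates map to the same chromosome in
    FR orientation with a positive outer insert below ``max_proper_insert``
    (a deliberately loose bound: insert-size outliers are detected
    downstream, not here).
    """
    h1 = map_read(seq1, index)
    h2 = map_read(seq2, index)
    reads = []
    insert = 0
    proper = False
    if h1 and h2 and h1.chrom == h2.chrom and h1.strand != h2.strand:
        left, right = (h1, h2) if h1.pos <= h2.pos else (h2, h1)
        outer = right.pos + (len(seq2) if right is h2 else len(seq1)) - left.pos
        if left.strand == "+" and 0 < outer < max_proper_insert:
            proper = True
            insert = outer
    for is_read1, seq, hit, mate in ((True, seq1, h1, h2), (False, seq2, h2, h1)):
        if hit is None:
            reads.append(
                AlignedRead(
                    qname=name, chrom=None, pos=-1, strand=".", cigar="*", mapq=0,
                    seq=seq,
                    mate_chrom=mate.chrom if mate else None,
                    mate_pos=mate.pos if mate else -1,
                    mate_strand=mate.strand if mate else ".",
                    is_proper_pair=False, insert_size=0, is_read1=is_read1,
                )
            )
        else:
            sign = 0
            if proper:
                sign = insert if hit.pos <= mate.pos else -insert
            reads.append(
                AlignedRead(
                    qname=name, chrom=hit.chrom, pos=hit.pos, strand=hit.strand,
                    cigar=f"{len(seq)}M", mapq=hit.mapq, seq=seq,
                    mate_chrom=mate.chrom if mate else None,
                    mate_pos=mate.pos if mate else -1,
                    mate_strand=mate.strand if mate else ".",
                    is_proper_pair=proper, insert_size=sign, is_read1=is_read1,
                )
            )
    return reads


def map_pairs(pairs, index: ReferenceIndex):
    """Map an iterable of ``(name, seq1, seq2)`` tuples."""
    out = []
    for name, s1, s2 in pairs:
        out.extend(map_pair(name, s1, s2, index))
    return out
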