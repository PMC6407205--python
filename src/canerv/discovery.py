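"""Discovery of ERV insertions from paired-end read evidence.

Two complementary detectors:

* Non-reference insertions: read pairs with one mate on the reference and
  the other matching ERV consensus (anchor pairs) are clustered; reads
  around each candidate are assembled into contigs by a greedy
  overlap-layout-consensus step; contigs containing an LTR-genome junction
  are remapped to the reference for precise breakpoint and target-site
  duplication (TSD) identification.
* Unfixed reference insertions: read pairs whose insert size exceeds
  median + k x MAD indicate a deletion relative to the reference; calls
  intersecting annotated elements and sized like a solo LTR (400-500 bp)
  or a provirus (7-9 kb) are reported.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import edlib

from .formats import AlignedRead, GenomicInterval, revcomp
from .mapping import ReferenceIndex, map_read


@dataclass
class AnchorPair:
    """A reference-mapped read whose mate matches ERV consensus."""

    anchor: AlignedRead
    erv_part: str  # 'ltr' or 'internal'
    identity: float
    aligned_bp: int
    mate_seq: str


@dataclass
class CandidateLocus:
    chrom: str
    start: int
    end: int
    support_pairs: int
    anchors: list = field(default_factory=list)
    near_known_erv: bool = False
    dropped_reason: str | None = None


@dataclass
class JunctionContig:
    """An assembled contig spanning an LTR-genome junction.

    The contig is normalized so the LTR matches the consensus in forward
    orientation; ``ltr_span``/``genomic_span`` are half-open intervals on
    the contig, and ``right_genomic_span`` is set for full-LTR contigs that
    carry genomic sequence on both sides.
    """

    contig_seq: str
    ltr_span: tuple
    genomic_span: tuple
    side: str  # five_prime | three_prime | full_ltr
    ltr_match: tuple = (0, 0)  # matched interval on the LTR consensus
    right_genomic_span: tuple | None = None
    mapped_breakpoint: tuple | None = None  # (chrom, pos, strand)


@dataclass(eq=False)
class InsertionLocus:
    """A located non-reference insertion with breakpoint and TSD."""

    locus_id: str
    chrom: str
    breakpoint: int  # leftmost TSD start, forward strand
    orientation: str
    tsd: str | None
    sides: tuple = ()
    flags: tuple = ()
    support_pairs: int = 0

    @property
    def pos(self):
        return self.breakpoint

    is_reference: bool = False
    form: str | None = None


@dataclass
class ReferenceDeletionCall:
    chrom: str
    start: int
    end: int
    size: float
    size_class: str  # solo_ltr | provirus | other
    support_pairs: int


# ---------------------------------------------------------------------------
# Anchor pairs and clustering


def _erv_identity(seq: str, consensus: str):
    """Best full-query identity of ``seq`` against a consensus (either strand)."""
    best = -1.0
    for s in (seq, revcomp(seq)):
        res = edlib.align(s, consensus, mode="HW", task="distance")
        ident = 1.0 - res["editDistance"] / len(s)
        if ident > best:
            best = ident
    return best


def find_anchor_pairs(alignments, erv_consensus, min_identity=0.9, min_bp=30):
    """Identify pairs with one reference-mapped mate and one ERV-matching mate.

    ``erv_consensus`` maps part name ('ltr', 'internal') to its consensus
    sequence. Pairs where both mates map to the reference are excluded; the
    unmapped mate must align to a consensus at >= ``min_identity`` over at
    least ``min_bp`` bases (here: over its full length).
    """
    by_name: dict = {}
    for r in alignments:
        by_name.setdefault(r.qname, []).append(r)
    anchors = []
    for name, reads in by_name.items():
        if len(reads) != 2:
            continue
        mapped = [r for r in reads if not r.is_unmapped]
        if len(mapped) != 1:
            continue
        anchor = mapped[0]
        mate = reads[0] if reads[1] is anchor else reads[1]
        if len(mate.seq) < min_bp:
            continue
        best_part, best_ident = None, min_identity
        for part, consensus in erv_consensus.items():
            ident = _erv_identity(mate.seq, consensus)
            if ident >= best_ident:
                best_part, best_ident = part, ident
        if best_part is not None:
            anchors.append(
                AnchorPair(anchor, best_part, best_ident, len(mate.seq), mate.seq)
            )
    return anchors


def cluster_candidates(
    anchors,
    known_erv_intervals=(),
    min_support: int = 2,
    exclusion_bp: int = 500,
    window_bp: int = 200,
):
    """Single-linkage clustering of anchor positions into candidate loci.

    Clusters with fewer than ``min_support`` pairs are not emitted; clusters
    whose window, padded by ``exclusion_bp``, touches an annotated element
    are returned with ``dropped_reason`` set (rediscovery of a known locus).
    """
    by_chrom: dict = {}
    for a in anchors:
        by_chrom.setdefault(a.anchor.chrom, []).append(a)
    out = []
    for chrom, members in by_chrom.items():
        members.sort(key=lambda a: a.anchor.pos)
        cluster = [members[0]]
        for a in members[1:]:
            if a.anchor.pos - cluster[-1].anchor.pos <= window_bp:
                cluster.append(a)
            else:
                out.extend(_emit(chrom, cluster, known_erv_intervals,
                                 min_support, exclusion_bp))
                cluster = [a]
        out.extend(_emit(chrom, cluster, known_erv_intervals,
                         min_support, exclusion_bp))
    return out


def _emit(chrom, cluster, known, min_support, exclusion_bp):
    if len(cluster) < min_support:
        return []
    start = min(a.anchor.pos for a in cluster)
    end = max(a.anchor.end for a in cluster)
    cand = CandidateLocus(chrom, start, end, len(cluster), cluster)
    padded = GenomicInterval(chrom, max(0, start - exclusion_bp), end + exclusion_bp)
    for iv in known:
        if padded.overlaps(iv):
            cand.near_known_erv = True
            cand.dropped_reason = f"within {exclusion_bp} bp of known ERV {iv.name}"
            break
    return [cand]


# ---------------------------------------------------------------------------
# Greedy overlap-layout-consensus assembly


class _Contig:
    """A contig as per-column base counts with a cached consensus."""

    __slots__ = ("columns", "_consensus")

    def __init__(self, columns):
        self.columns = columns
        self._consensus = None

    @classmethod
    def from_read(cls, seq):
        return cls([{b: 1} for b in seq])

    @property
    def consensus(self):
        if self._consensus is None:
            # majority base; ties broken alphabetically
            self._consensus = "".join(
                min(col, key=lambda b: (-col[b], b)) for col in self.columns
            )
        return self._consensus

    def revcomp(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        cols = [
            {comp[b]: n for b, n in col.items()} for col in reversed(self.columns)
        ]
        return _Contig(cols)

    def __len__(self):
        return len(self.columns)


def _best_overlap(a: str, b: str, min_overlap: int, min_identity: float):
    """Best suffix(a)->prefix(b) overlap, seeded by exact 12-mers of b's start.

    Returns ``(score, olen)`` or ``None``; score = overlap length minus
    mismatches, requiring identity >= ``min_identity``.
    """
    best = None
    seen = set()
    for seed_off in (0, 6):
        seed = b[seed_off : seed_off + 12]
        if len(seed) < 12:
            continue
        idx = a.find(seed)
        while idx != -1:
            olen = len(a) - idx + seed_off
            idx = a.find(seed, idx + 1)
            if olen in seen or olen < min_overlap or olen > min(len(a), len(b)):
                continue
            seen.add(olen)
            allowed = int(olen * (1 - min_identity))
            mm = 0
            for x, y in zip(a[len(a) - olen :], b[:olen]):
                if x != y:
                    mm += 1
                    if mm > allowed:
                        break
            if mm <= allowed:
                cand = (olen - mm, olen)
                if best is None or cand > best:
                    best = cand
    return best


def _merge(a: _Contig, b: _Contig, olen: int) -> _Contig:
    cols = [dict(c) for c in a.columns[: len(a) - olen]]
    for ca, cb in zip(a.columns[len(a) - olen :], b.columns[:olen]):
        merged = dict(ca)
        for base, n in cb.items():
            merged[base] = merged.get(base, 0) + n
        cols.append(merged)
    cols.extend(dict(c) for c in b.columns[olen:])
    return _Contig(cols)


def _pair_overlap(cons_a, cons_b, rc_b, min_overlap, min_identity):
    """Best merge of contig b (either orientation) onto contig a's suffix."""
    best = None  # (score, olen, flip)
    hit = _best_overlap(cons_a, cons_b, min_overlap, min_identity)
    if hit:
        best = (*hit, False)
    hit = _best_overlap(cons_a, rc_b, min_overlap, min_identity)
    if hit and (best is None or hit > (best[0], best[1])):
        best = (*hit, True)
    return best


def assemble_junction(reads_in_window, min_overlap=25, min_overlap_identity=0.95,
                      max_reads=200):
    """Greedy overlap-layout-consensus assembly of window reads.

    Iteratively merges the highest-scoring suffix-prefix overlap of length
    >= ``min_overlap`` at identity >= ``min_overlap_identity``, considering
    reverse complements; consensus is the per-column majority. Input order
    does not affect the result (ties break on the contig consensus
    strings, which are order-independent). Returns consensus strings,
    longest first.
    """
    # canonical, order-invariant starting set; dedupe identical reads
    unique = sorted(set(reads_in_window))
    if len(unique) > max_reads:
        step = len(unique) / max_reads
        unique = [unique[int(i * step)] for i in range(max_reads)]
    contigs: dict = {}
    cons: dict = {}
    rc_cons: dict = {}
    for cid, read in enumerate(unique):
        contigs[cid] = _Contig.from_read(read)
        cons[cid] = read
        rc_cons[cid] = revcomp(read)
    candidates: dict = {}

    def refresh(a, b):
        hit = _pair_overlap(cons[a], cons[b], rc_cons[b], min_overlap,
                            min_overlap_identity)
        if hit:
            candidates[(a, b)] = hit
        else:
            candidates.pop((a, b), None)

    ids = list(contigs)
    for a in ids:
        for b in ids:
            if a != b:
                refresh(a, b)
    next_id = len(unique)
    while candidates:
        # deterministic, order-invariant argmax: score, overlap, sequences
        (a, b), (score, olen, flip) = max(
            candidates.items(),
            key=lambda kv: (kv[1][0], kv[1][1], cons[kv[0][0]], cons[kv[0][1]],
                            not kv[1][2]),
        )
        other = contigs[b].revcomp() if flip else contigs[b]
        merged = _merge(contigs[a], other, olen)
        for cid in (a, b):
            del contigs[cid], cons[cid], rc_cons[cid]
        candidates = {k: v for k, v in candidates.items()
                      if a not in k and b not in k}
        nid = next_id
        next_id += 1
        contigs[nid] = merged
        cons[nid] = merged.consensus
        rc_cons[nid] = revcomp(merged.consensus)
        for cid in list(contigs):
            if cid != nid:
                refresh(nid, cid)
                refresh(cid, nid)
    return sorted((c.consensus for c in contigs.values()), key=lambda s: (-len(s), s))


# ---------------------------------------------------------------------------
# Junction classification and breakpoint mapping


def _find_ltr_segment(contig: str, ltr: str, probe_len: int = 40,
                      max_probe_dist: int = 5):
    """Locate the LTR-derived segment of a contig by its terminal probes.

    The LTR's first and last ``probe_len`` bases are searched as infixes of
    the contig; their hit coordinates delimit the LTR-derived span
    precisely. Returns ``(c_start, c_end, l_start, l_end, score)`` on the
    contig/LTR or ``None`` when neither terminus is present.
    """
    res5 = edlib.align(ltr[:probe_len], contig, mode="HW", task="locations")
    res3 = edlib.align(ltr[-probe_len:], contig, mode="HW", task="locations")
    have5 = 0 <= res5["editDistance"] <= max_probe_dist
    have3 = 0 <= res3["editDistance"] <= max_probe_dist
    if have5 and have3:
        c_start = res5["locations"][0][0]
        c_end = res3["locations"][0][1] + 1
        span = c_end - c_start
        if 0.8 * len(ltr) <= span <= 1.2 * len(ltr):
            score = span - 2 * (res5["editDistance"] + res3["editDistance"])
            return (c_start, c_end, 0, len(ltr), score)
        # inconsistent probe pair: fall through preferring the better probe
        if res5["editDistance"] <= res3["editDistance"]:
            have3 = False
        else:
            have5 = False
    if have5:
        # genome | LTR 5' end: LTR-derived sequence runs to the contig end
        c_start = res5["locations"][0][0]
        seg = contig[c_start:]
        chk = edlib.align(seg, ltr, mode="SHW", task="distance")
        if chk["editDistance"] > 0.12 * len(seg):
            return None
        return (c_start, len(contig), 0, min(len(seg), len(ltr)),
                len(seg) - 2 * chk["editDistance"])
    if have3:
        # LTR 3' end | genome: LTR-derived sequence starts the contig
        c_end = res3["locations"][0][1] + 1
        seg = contig[:c_end]
        chk = edlib.align(seg[::-1], ltr[::-1], mode="SHW", task="distance")
        if chk["editDistance"] > 0.12 * len(seg):
            return None
        return (0, c_end, max(0, len(ltr) - len(seg)), len(ltr),
                len(seg) - 2 * chk["editDistance"])
    return None


def classify_junction(contig: str, ltr_consensus: str, min_junction_bp: int = 30,
                      min_contig: int = 60):
    """Classify a contig as an LTR-genome junction, or reject.

    Requires >= ``min_junction_bp`` of assembled LTR-derived and genomic
    sequence. Returns a :class:`JunctionContig` normalized to forward-LTR
    orientation, or a string reason for rejection.
    """
    if len(contig) < min_contig:
        return "contig too short"
    best = None
    for oriented in (contig, revcomp(contig)):
        span = _find_ltr_segment(oriented, ltr_consensus)
        if span is not None and (best is None or span[4] > best[1][4]):
            best = (oriented, span)
    if best is None:
        return "no LTR-derived sequence"
    seq, (c_start, c_end, l_start, l_end, _) = best
    if c_end - c_start < min_junction_bp:
        return "LTR-derived span < minimum"
    left, right = c_start, len(seq) - c_end
    full_ltr = l_start == 0 and l_end == len(ltr_consensus) and c_end < len(seq)
    if full_ltr and left >= min_junction_bp and right >= min_junction_bp:
        return JunctionContig(
            seq, (c_start, c_end), (0, c_start), "full_ltr",
            (l_start, l_end), right_genomic_span=(c_end, len(seq)),
        )
    if left >= min_junction_bp and l_start == 0:
        return JunctionContig(seq, (c_start, c_end), (0, c_start), "five_prime",
                              (l_start, l_end))
    if right >= min_junction_bp and l_end == len(ltr_consensus):
        return JunctionContig(seq, (c_start, c_end), (c_end, len(seq)),
                              "three_prime", (l_start, l_end))
    if left < min_junction_bp and right < min_junction_bp:
        return "genomic span < minimum"
    return "LTR segment does not reach an LTR terminus"


def _map_unique(seq: str, index: ReferenceIndex, min_mapq: int = 20):
    hit = map_read(seq, index)
    if hit is None or hit.mapq < min_mapq:
        return None
    return hit


def locate_breakpoint_tsd(junctions, index: ReferenceIndex, ltr_consensus: str,
                          tsd_length: int = 5, window: int = 40,
                          max_window_divergence: float = 0.08):
    """Map junction contigs to the reference; derive breakpoint, TSD, strand.

    Genomic spans are placed on the reference; because a junction boundary
    is ambiguous wherever the reference and the LTR terminus share bases
    (micro-homology), the breakpoint is refined by scoring candidate
    positions against junction templates built from the reference and the
    LTR consensus, taking the leftmost best-scoring position. When both
    the element-left and element-right genome junctions are evidenced, the
    duplicated ``tsd_length``-mer starting at the breakpoint is the TSD;
    templates that fit no candidate well yield ``tsd=None`` with a
    mismatch flag. Returns ``(chrom, breakpoint, tsd, orientation, flags,
    sides)`` or ``None`` when no junction places uniquely.
    """
    evidence = []  # (genome_kind, role, strand, contig, c_pos, b_guess)
    chrom = None
    orientation = None
    flags = []
    sides = []
    for j in junctions:
        # for a forward-LTR-normalized contig the sequence left of the LTR
        # is the element-5' genomic flank ('left' role), right is 3'
        span_roles = []
        if j.side in ("five_prime", "full_ltr"):
            span_roles.append((j.genomic_span, "left"))
        if j.side == "three_prime":
            span_roles.append((j.genomic_span, "right"))
        if j.side == "full_ltr" and j.right_genomic_span:
            span_roles.append((j.right_genomic_span, "right"))
        placed_any = False
        for (g0, g1), role in span_roles:
            seq = j.contig_seq[g0:g1]
            hit = _map_unique(seq, index)
            if hit is None:
                flags.append("unplaced_junction")
                continue
            if chrom is None:
                chrom = hit.chrom
            elif chrom != hit.chrom:
                flags.append("junctions_on_different_chromosomes")
                continue
            placed_any = True
            glen = g1 - g0
            # forward-strand mapping keeps the contig's left/right meaning;
            # reverse-strand mapping swaps it and flips element orientation
            if (role == "left") == (hit.strand == "+"):
                # genome-left junction: flank | element, ends at b + tsd
                kind, b_guess = "e5", hit.pos + glen - tsd_length
            else:
                # genome-right junction: element | flank, resumes at b
                kind, b_guess = "s3", hit.pos
            # the contig is normalized to forward LTR, so the flank's
            # mapping strand is the element's orientation in the genome
            orient = hit.strand
            c_pos = j.ltr_span[0] if role == "left" else j.ltr_span[1]
            evidence.append((kind, role, hit.strand, j.contig_seq, c_pos, b_guess))
            if orientation is None:
                orientation = orient
            elif orientation != orient:
                flags.append("orientation_conflict")
        if placed_any:
            sides.append(j.side)
    if chrom is None or not evidence:
        return None
    ref = index.seqs[chrom]
    candidates = set()
    for kind, _, _, _, _, b_guess in evidence:
        for d in range(-6, 7):
            b = b_guess + d
            if tsd_length + window <= b <= len(ref) - tsd_length - window:
                candidates.add(b)
    if not candidates:
        return None
    ltr = ltr_consensus

    def junction_score(b, ev):
        _, role, strand, contig, c_pos, _ = ev
        lw = min(window, c_pos)
        rw = min(window, len(contig) - c_pos)
        contig_win = contig[c_pos - lw : c_pos + rw]
        if role == "left":
            if strand == "+":
                template = ref[b + tsd_length - lw : b + tsd_length] + ltr[:rw]
            else:
                template = revcomp(ref[b : b + lw]) + ltr[:rw]
        else:
            if strand == "+":
                template = ltr[len(ltr) - lw :] + ref[b : b + rw]
            else:
                template = ltr[len(ltr) - lw :] + revcomp(
                    ref[b + tsd_length - rw : b + tsd_length]
                )
        return edlib.align(contig_win, template, mode="NW",
                           task="distance")["editDistance"], len(contig_win)

    best = None
    for b in sorted(candidates):
        total = 0
        sizes = 0
        per_junction_ok = True
        for ev in evidence:
            d, size = junction_score(b, ev)
            total += d
            sizes += size
            if d > max_window_divergence * size:
                per_junction_ok = False
        cand = (total, b, per_junction_ok)
        if best is None or (cand[0], cand[1]) < (best[0], best[1]):
            best = cand
    total, breakpoint, fits = best
    kinds = {ev[0] for ev in evidence}
    if kinds == {"e5", "s3"} and fits:
        tsd = ref[breakpoint : breakpoint + tsd_length]
    else:
        tsd = None
        if kinds == {"e5", "s3"}:
            flags.append("tsd_mismatch")
    return (chrom, breakpoint, tsd, (orientation or "+"),
            tuple(sorted(set(flags))), tuple(sides))


# ---------------------------------------------------------------------------
# Reference deletion scan


def scan_reference_deletions(
    alignments,
    known_erv_intervals,
    mad_cutoff: float = 7.0,
    min_mapq: int = 20,
    solo_size_range=(400, 500),
    provirus_size_range=(7000, 9000),
    min_support: int = 2,
    min_pairs_for_distribution: int = 200,
):
    """Detect unfixed reference insertions from insert-size outliers.

    The library insert distribution (median, MAD) is estimated from proper
    pairs; pairs with both mates at mapq >= ``min_mapq`` and insert size
    above median + ``mad_cutoff`` x MAD support a deletion. Overlapping
    supports merge into calls whose implied size is the median supporting
    insert minus the expected insert. Only calls intersecting a known ERV
    annotation are returned, size-classified as solo LTR, provirus, or
    other.
    """
    pairs: dict = {}
    for r in alignments:
        pairs.setdefault(r.qname, []).append(r)
    proper_inserts = []
    spans = []  # (chrom, inner_start, inner_end, insert, min_mapq)
    for name, reads in pairs.items():
        if len(reads) != 2:
            continue
        r1, r2 = reads
        if r1.is_unmapped or r2.is_unmapped or r1.chrom != r2.chrom:
            continue
        if not (r1.is_proper_pair and r2.is_proper_pair):
            continue
        insert = abs(r1.insert_size)
        if insert <= 0:
            continue
        proper_inserts.append(insert)
        left, right = (r1, r2) if r1.pos <= r2.pos else (r2, r1)
        spans.append(
            (r1.chrom, left.end, right.pos, insert, min(r1.mapq, r2.mapq))
        )
    if len(proper_inserts) < min_pairs_for_distribution:
        raise ValueError(
            f"need >= {min_pairs_for_distribution} proper pairs to estimate "
            f"the insert-size distribution, got {len(proper_inserts)}"
        )
    med = statistics.median(proper_inserts)
    mad = statistics.median(abs(x - med) for x in proper_inserts)
    cutoff = med + mad_cutoff * mad
    supports = [
        s for s in spans if s[4] >= min_mapq and s[3] > cutoff and s[2] > s[1]
    ]
    supports.sort(key=lambda s: (s[0], s[1]))
    calls = []
    cluster: list = []
    for s in supports:
        if cluster and s[0] == cluster[-1][0] and s[1] < max(c[2] for c in cluster):
            cluster.append(s)
        else:
            if cluster:
                calls.append(_deletion_call(cluster, med))
            cluster = [s]
    if cluster:
        calls.append(_deletion_call(cluster, med))
    out = []
    for call in calls:
        if call.support_pairs < min_support:
            continue
        region = GenomicInterval(call.chrom, call.start, max(call.end, call.start + 1))
        if not any(region.overlaps(iv) for iv in known_erv_intervals):
            continue
        lo, hi = solo_size_range
        plo, phi = provirus_size_range
        if lo <= call.size <= hi:
            call.size_class = "solo_ltr"
        elif plo <= call.size <= phi:
            call.size_class = "provirus"
        out.append(call)
    return out


def _deletion_call(cluster, expected_insert):
    chrom = cluster[0][0]
    start = min(c[1] for c in cluster)
    end = max(c[2] for c in cluster)
    size = statistics.median(c[3] for c in cluster) - expected_insert
    return ReferenceDeletionCall(chrom, start, end, size, "other", len(cluster))
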