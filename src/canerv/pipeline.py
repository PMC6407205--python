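"""End-to-end orchestration: discovery and genotyping over a cohort.

Glues the stage modules together the way a full run uses them: pooled
alignments feed non-reference discovery; per-sample reads are then
remapped to reconstructed alleles for genotyping. Also provides the fully
synthetic round-trip (simulate -> discover -> genotype) used to validate
the pipeline against known truth.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .discovery import (
    InsertionLocus,
    JunctionContig,
    assemble_junction,
    classify_junction,
    cluster_candidates,
    find_anchor_pairs,
    locate_breakpoint_tsd,
)
from .genotyping import cohort_genotype, reconstruct_alleles
from .mapping import ReferenceIndex, map_pairs
from .synthetic import (
    make_ltr_consensus,
    make_reference,
    make_truth_insertions,
    random_dna,
    sample_haplotypes,
    simulate_cohort,
    simulate_reads,
    INTERNAL_LENGTH,
)


def discover_insertions(alignments, index: ReferenceIndex, erv_consensus: dict,
                        known_erv_intervals=(), config: RunConfig | None = None):
    """Non-reference insertion discovery from pooled alignments.

    Returns ``(loci, rejects)``: located :class:`InsertionLocus` records and
    a list of (candidate-or-description, reason) rejects.
    """
    config = config or RunConfig()
    anchors = find_anchor_pairs(alignments, erv_consensus)
    candidates = cluster_candidates(
        anchors,
        known_erv_intervals,
        min_support=config.min_support_pairs,
        exclusion_bp=config.known_erv_exclusion_bp,
        window_bp=config.assembly_window_bp,
    )
    # position index of mapped reads + pair lookup for window collection
    by_chrom: dict = {}
    by_name: dict = {}
    for r in alignments:
        by_name.setdefault(r.qname, []).append(r)
        if not r.is_unmapped:
            by_chrom.setdefault(r.chrom, []).append((r.pos, r.qname))
    for lst in by_chrom.values():
        lst.sort()
    loci, rejects = [], []
    seen = []
    for cand in candidates:
        if cand.dropped_reason:
            rejects.append((cand, cand.dropped_reason))
            continue
        # breakpoint guess: forward anchors end left of the junction,
        # reverse anchors start right of it
        plus = [a.anchor.end for a in cand.anchors if a.anchor.strand == "+"]
        minus = [a.anchor.pos for a in cand.anchors if a.anchor.strand == "-"]
        if plus and minus:
            guess = (max(plus) + min(minus)) // 2
        else:
            guess = max(plus) if plus else min(minus)
        aw = max(config.assembly_window_bp, 300)
        lo, hi = guess - aw, guess + aw
        names = set()
        positions = by_chrom.get(cand.chrom, [])
        i = bisect_left(positions, (cand.start - 500, ""))
        while i < len(positions) and positions[i][0] <= cand.end + 500:
            names.add(positions[i][1])
            i += 1
        # junction-crossing and element-derived reads are unmapped; mapped
        # reads contribute only near the guessed breakpoint
        window_reads = []
        for name in names:
            for r in by_name[name]:
                if r.is_unmapped or (lo <= r.pos and r.end <= hi):
                    window_reads.append(r.seq)
        contigs = assemble_junction(window_reads, max_reads=250)
        junctions = []
        for contig in contigs[:8]:
            j = classify_junction(contig, erv_consensus["ltr"],
                                  min_junction_bp=config.min_junction_bp)
            if isinstance(j, JunctionContig):
                junctions.append(j)
        if not junctions:
            rejects.append((cand, "no junction contig assembled"))
            continue
        located = locate_breakpoint_tsd(junctions, index, erv_consensus["ltr"],
                                        tsd_length=config.tsd_length)
        if located is None:
            rejects.append((cand, "junction unplaced on reference"))
            continue
        chrom, breakpoint, tsd, orientation, flags, sides = located
        if any(abs(breakpoint - b) <= 10 and chrom == c for c, b in seen):
            continue  # same insertion reached from an adjacent cluster
        seen.append((chrom, breakpoint))
        form = "provirus" if any(a.erv_part == "internal" for a in cand.anchors) \
            else "solo_ltr"
        loci.append(
            InsertionLocus(
                locus_id=f"nr_{chrom}_{breakpoint}",
                chrom=chrom,
                breakpoint=breakpoint,
                orientation=orientation,
                tsd=tsd,
                sides=sides,
                flags=flags,
                support_pairs=cand.support_pairs,
                form=form,
            )
        )
    return loci, rejects


class CohortReadStore:
    """Per-sample read pairs indexed by mapped position for locus lookup."""

    def __init__(self):
        self._pairs: dict = {}  # sample -> {name: (s1, s2)}
        self._index: dict = {}  # sample -> {chrom: sorted [(pos, name)]}
        self._mapq: dict = {}  # sample -> {name: min mapq of mapped mates}

    def add_sample(self, sample_id, pairs, alignments):
        self._pairs[sample_id] = {name: (s1, s2) for name, s1, s2 in pairs}
        idx: dict = {}
        mapq: dict = {}
        for r in alignments:
            if r.is_unmapped:
                continue
            idx.setdefault(r.chrom, []).append((r.pos, r.qname))
            mapq[r.qname] = min(mapq.get(r.qname, 60), r.mapq)
        for lst in idx.values():
            lst.sort()
        self._index[sample_id] = idx
        self._mapq[sample_id] = mapq

    def near(self, sample_id, chrom, lo, hi):
        """Pairs with a mapped mate in [lo, hi); returns (pairs, mapqs)."""
        positions = self._index.get(sample_id, {}).get(chrom, [])
        names = set()
        i = bisect_left(positions, (lo, ""))
        while i < len(positions) and positions[i][0] < hi:
            names.add(positions[i][1])
            i += 1
        pairs = [(n, *self._pairs[sample_id][n]) for n in sorted(names)]
        mapqs = {n: self._mapq[sample_id].get(n, 60) for n in names}
        return pairs, mapqs


def genotype_cohort_at_loci(loci, store: CohortReadStore, reference,
                            population_table: dict, erv_consensus: dict,
                            config: RunConfig | None = None):
    """Reconstruct alleles for discovered loci and genotype every sample.

    Elements at discovered non-reference loci are filled from consensus:
    the LTR alone for solo-LTR-like loci, LTR+internal+LTR for loci with
    internal-sequence support.
    """
    config = config or RunConfig()
    ref_seqs = {rec.id: rec.seq for rec in reference}
    provirus_consensus = (
        erv_consensus["ltr"] + erv_consensus.get("internal", "") + erv_consensus["ltr"]
    )
    pairs = []
    for locus in loci:
        element = (
            provirus_consensus if locus.form == "provirus" else erv_consensus["ltr"]
        )
        allele_pair = reconstruct_alleles(
            locus,
            ref_seqs,
            element_seq=element,
            flank_bp=config.flank_bp,
            tsd_length=config.tsd_length,
            ltr_length=config.ltr_length,
        )
        pairs.append((locus, allele_pair))
    margin = config.flank_bp + 300

    def reads_for(sample_id, locus):
        return store.near(sample_id, locus.chrom,
                          locus.breakpoint - margin, locus.breakpoint + margin)

    return cohort_genotype(pairs, reads_for, population_table)


@dataclass
class SyntheticRunResult:
    truth: list
    cohort: object
    discovered: list
    rejects: list
    matches: dict  # truth locus_id -> discovered InsertionLocus
    recall: float
    tsd_exact: bool
    calls: dict
    frequency_table: object
    concordance: float


def run_synthetic_cohort(
    seed: int = 0,
    chrom_lengths=(50_000, 50_000),
    n_loci: int = 6,
    n_samples: int = 12,
    coverage: float = 20.0,
    base_error: float = 0.001,
    provirus_fraction: float = 0.3,
    config: RunConfig | None = None,
) -> SyntheticRunResult:
    """Simulate a cohort, rediscover and genotype its insertions.

    The full round trip the pipeline is built for: implant a truth set on a
    random reference, simulate diploid samples and paired-end reads, map
    them back, discover non-reference insertions from pooled alignments,
    and genotype every sample at the discovered loci. Breakpoint recall is
    judged at +/- 5 bp; concordance compares called genotypes with truth.
    """
    config = config or RunConfig(seed=seed)
    rng = np.random.default_rng(seed)
    reference = make_reference(int(rng.integers(2**31)), list(chrom_lengths))
    ltr = make_ltr_consensus(int(rng.integers(2**31)))
    internal = random_dna(np.random.default_rng(int(rng.integers(2**31))),
                          INTERNAL_LENGTH)
    populations = ("popA", "popB")
    truth = make_truth_insertions(
        reference, n_loci, populations, int(rng.integers(2**31)),
        ltr_consensus=ltr, internal_consensus=internal,
        provirus_fraction=provirus_fraction, freq_range=(0.25, 0.75),
        tsd_length=config.tsd_length, flank_bp=config.flank_bp,
    )
    samples = [(f"s{i:02d}", populations[i % 2]) for i in range(n_samples)]
    cohort = simulate_cohort(truth, samples, int(rng.integers(2**31)))
    population_table = dict(samples)
    index = ReferenceIndex(reference)
    store = CohortReadStore()
    pooled = []
    for sample_id, _pop in samples:
        haps = sample_haplotypes(reference, truth, cohort, sample_id)
        pairs = simulate_reads(
            haps, coverage, base_error=base_error,
            seed=int(rng.integers(2**31)), name_prefix=sample_id,
        )
        alignments = map_pairs(pairs, index)
        store.add_sample(sample_id, pairs, alignments)
        pooled.extend(alignments)
    erv_consensus = {"ltr": ltr, "internal": internal}
    discovered, rejects = discover_insertions(pooled, index, erv_consensus,
                                              config=config)
    matches = {}
    for t in truth:
        for loc in discovered:
            if loc.chrom == t.chrom and abs(loc.breakpoint - t.breakpoint) <= 5:
                matches[t.locus_id] = loc
                break
    recall = len(matches) / len(truth)
    tsd_exact = all(
        matches[tid].tsd == t.tsd
        for t in truth
        for tid in [t.locus_id]
        if tid in matches and matches[tid].tsd is not None
    ) and all(m.tsd is not None for m in matches.values())
    calls, freq, _skipped = genotype_cohort_at_loci(
        list(matches.values()), store, reference, population_table,
        erv_consensus, config,
    )
    loc_to_truth = {loc.locus_id: tid for tid, loc in matches.items()}
    agree = total = 0
    copies = {"0/0": 0, "0/1": 1, "1/1": 2}
    for locus, per_sample in calls.items():
        tid = loc_to_truth[locus.locus_id]
        for sample_id, call in per_sample.items():
            if call.gt == "./.":
                continue
            total += 1
            if copies[call.gt] == cohort.genotypes[(sample_id, tid)]:
                agree += 1
    concordance = agree / total if total else float("nan")
    return SyntheticRunResult(
        truth, cohort, discovered, rejects, matches, recall, tsd_exact,
        calls, freq, concordance,
    )
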