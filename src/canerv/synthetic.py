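"""Synthetic genomes, ERV insertion truth sets, diploid cohorts, and reads.

The generator reproduces the statistical structure the downstream analysis
assumes: integration creates a 5-bp target-site duplication (TSD); an
occupied locus carries either a solo LTR or a full provirus between the two
TSD copies; the two LTRs of a provirus start identical and accrue
substitutions under a neutral clock; diploid samples draw insertion alleles
per population under Hardy-Weinberg; paired-end reads follow a
fragment-size and uniform base-error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats import SequenceRecord, revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class TruthInsertion:
    """Ground truth for one implanted ERV integration site.

    ``breakpoint`` is the 0-based position of the TSD start in the
    pre-insertion reference (the leftmost insertion breakpoint on the
    forward strand, irrespective of element orientation).
    """

    locus_id: str
    chrom: str
    breakpoint: int
    orientation: str  # '+' or '-'
    form: str  # 'solo_ltr' or 'provirus'
    tsd: str
    element_seq: str  # forward-strand element (5'LTR..3'LTR for provirus)
    true_age_years: float = 0.0
    pop_freqs: dict = field(default_factory=dict)


@dataclass
class CohortTruth:
    """Simulated diploid cohort: genotypes and per-haplotype alleles."""

    samples: list  # list of (sample_id, population)
    genotypes: dict  # (sample_id, locus_id) -> 0/1/2
    haplotype_alleles: dict  # (sample_id, locus_id) -> (bool, bool)


def make_reference(seed, chrom_lengths, gc: float = 0.41) -> list[SequenceRecord]:
    """Generate i.i.d. random chromosomes at the given GC content.

    ``chrom_lengths`` maps chromosome name to length (or is a list of
    lengths, auto-named chr1..chrN).
    """
    rng = np.random.default_rng(seed)
    if not isinstance(chrom_lengths, dict):
        chrom_lengths = {f"chr{i + 1}": n for i, n in enumerate(chrom_lengths)}
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records = []
    for name, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome length must be positive, got {length}")
        seq = "".join(rng.choice(_BASES, size=length, p=p))
        records.append(SequenceRecord(name, seq))
    return records


def random_dna(rng, length: int, gc: float = 0.41) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def mutate_ltr_pair(ltr_seq: str, age_years: float, rate: float, seed) -> tuple:
    """Age an initially identical LTR pair under the neutral clock.

    Draws ``D ~ Poisson(age x rate x len(ltr_seq))`` total substitutions and
    scatters each uniformly over the pair: a random site in a randomly
    chosen LTR is substituted to a different base. Returns
    ``(ltr5, ltr3, D)`` with the realized draw. This is the exact inverse of
    the divergence dating formula, which divides the change count by a
    single LTR length (no factor of two).
    """
    if age_years < 0:
        raise ValueError("age must be non-negative")
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    n = rng.poisson(age_years * rate * len(ltr_seq))
    pair = [list(ltr_seq), list(ltr_seq)]
    for _ in range(n):
        which = rng.integers(2)
        pos = rng.integers(len(ltr_seq))
        current = pair[which][pos]
        options = [b for b in "ACGT" if b != current]
        pair[which][pos] = options[rng.integers(3)]
    return "".join(pair[0]), "".join(pair[1]), int(n)


def implant_insertions(reference, truth_list, min_end_distance: int = 600):
    """Build the occupied haplotype carrying every truth insertion.

    For a breakpoint ``b`` with TSD length ``t`` the occupied chromosome is
    ``ref[:b+t] + element + ref[b:]`` — the TSD 5-mer appears once on each
    side of the element. Reverse-orientation elements are inserted
    reverse-complemented. Returns a list of :class:`SequenceRecord`, one per
    reference chromosome (unchanged when it has no insertions).
    """
    by_chrom = {}
    for t in truth_list:
        by_chrom.setdefault(t.chrom, []).append(t)
    out = []
    for rec in reference:
        inserts = sorted(by_chrom.get(rec.id, []), key=lambda t: t.breakpoint)
        seq = rec.seq
        # apply right-to-left so earlier breakpoints stay valid
        for t in reversed(inserts):
            b = t.breakpoint
            tlen = len(t.tsd)
            if b < min_end_distance or b + tlen + min_end_distance > len(seq):
                raise ValueError(
                    f"breakpoint {t.locus_id} within {min_end_distance} bp of chromosome end"
                )
            if rec.seq[b : b + tlen] != t.tsd:
                raise ValueError(f"TSD of {t.locus_id} does not match reference")
            element = t.element_seq if t.orientation == "+" else revcomp(t.element_seq)
            seq = seq[: b + tlen] + element + seq[b:]
        out.append(SequenceRecord(rec.id, seq))
    return out


def simulate_cohort(truth_list, samples, seed) -> CohortTruth:
    """Draw diploid genotypes per sample under Hardy-Weinberg.

    Each haplotype carries the insertion allele at a locus with the
    population's insertion frequency; the genotype is the sum over the two
    haplotypes, so copies ~ Binomial(2, freq).
    """
    rng = np.random.default_rng(seed)
    genotypes, hap_alleles = {}, {}
    for sample_id, population in samples:
        for t in truth_list:
            if population not in t.pop_freqs:
                raise ValueError(
                    f"no frequency for population {population!r} at {t.locus_id}"
                )
            freq = t.pop_freqs[population]
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"frequency {freq} outside [0,1]")
            a1 = bool(rng.random() < freq)
            a2 = bool(rng.random() < freq)
            hap_alleles[(sample_id, t.locus_id)] = (a1, a2)
            genotypes[(sample_id, t.locus_id)] = int(a1) + int(a2)
    return CohortTruth(list(samples), genotypes, hap_alleles)


def sample_haplotypes(reference, truth_list, cohort: CohortTruth, sample_id):
    """The two haplotype genomes of one simulated sample."""
    haps = []
    for hap_idx in range(2):
        carried = [
            t
            for t in truth_list
            if cohort.haplotype_alleles[(sample_id, t.locus_id)][hap_idx]
        ]
        haps.append(implant_insertions(reference, carried))
    return haps


def simulate_reads(
    haplotype_pair,
    coverage: float,
    read_len: int = 100,
    frag_mean: float = 400.0,
    frag_sd: float = 50.0,
    base_error: float = 0.001,
    seed=0,
    name_prefix: str = "frag",
):
    """Simulate FR paired-end reads from a diploid haplotype pair.

    ``coverage`` is the sequencing depth per haplotype; each haplotype
    contributes ``coverage x length / (2 x read_len)`` fragments placed
    uniformly, so a pair of 50-kb haplotypes at coverage 20 yields ~10,000
    read pairs. Base errors are uniform substitutions at rate
    ``base_error``. Returns a list of ``(name, seq1, seq2)`` tuples; mate
    names gain /1 and /2 when written as FASTQ.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if frag_mean <= read_len:
        raise ValueError("fragment mean must exceed read length")
    rng = np.random.default_rng(seed)
    pairs = []
    counter = 0
    for hap_idx, hap in enumerate(haplotype_pair):
        for rec in hap:
            L = len(rec.seq)
            n_pairs = int(round(coverage * L / (2 * read_len)))
            frag_lens = rng.normal(frag_mean, frag_sd, size=n_pairs)
            frag_lens = np.clip(np.round(frag_lens), read_len, L).astype(int)
            starts = rng.integers(0, np.maximum(1, L - frag_lens + 1))
            for fl, st in zip(frag_lens, starts):
                frag = rec.seq[st : st + fl]
                r1 = frag[:read_len]
                r2 = revcomp(frag[-read_len:])
                if base_error > 0:
                    r1 = _add_errors(r1, base_error, rng)
                    r2 = _add_errors(r2, base_error, rng)
                pairs.append((f"{name_prefix}:{hap_idx}:{counter}", r1, r2))
                counter += 1
    return pairs


def _add_errors(seq: str, rate: float, rng) -> str:
    n_err = rng.poisson(rate * len(seq))
    if n_err == 0:
        return seq
    chars = list(seq)
    for pos in rng.integers(0, len(seq), size=n_err):
        options = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = options[rng.integers(3)]
    return "".join(chars)


def write_fastq_pair(pairs, path1, path2) -> None:
    """Write simulated pairs as two FASTQ files with /1 and /2 suffixes."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for name, s1, s2 in pairs:
            f1.write(f"@{name}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{'I' * len(s2)}\n")


# ---------------------------------------------------------------------------
# Element consensus models


#: Canonical element geometry (bp): a 457-bp LTR and a 6971-bp internal
#: region give the ~7.9-kb provirus typical of this gammaretroviral family.
LTR_LENGTH = 457
INTERNAL_LENGTH = 6971

#: Gene intervals on the proviral consensus, 0-based half-open. gag, pol and
#: env are sense-oriented ORFs within the internal region; lengths roughly
#: follow the family's organisation (env ~1.73 kb near the 3' LTR).
GENE_LAYOUT = {
    "gag": (780, 2973),
    "pol": (3000, 5685),
    "env": (5689, 7420),
}

_STOPS = {"TAA", "TAG", "TGA"}


def _random_orf(rng, n_codons: int) -> str:
    """ATG + random sense codons + TAA, ``n_codons`` codons in total."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def make_ltr_consensus(seed, length: int = LTR_LENGTH) -> str:
    """A random LTR consensus sequence of canonical length."""
    rng = np.random.default_rng(seed)
    return random_dna(rng, length)


def make_proviral_consensus(seed):
    """Build a full proviral consensus with clean gag/pol/env ORFs.

    Returns ``(consensus_seq, gene_intervals, ltr_intervals)`` where the
    intervals are 0-based half-open on the consensus. Both LTRs are
    identical (a newly integrated element); the three genes are
    ATG-initiated, stop-terminated open reading frames free of internal
    stops, so any premature stop found in a derived provirus was introduced
    by mutation.
    """
    rng = np.random.default_rng(seed)
    ltr = make_ltr_consensus(rng.integers(2**31))
    total = 2 * LTR_LENGTH + INTERNAL_LENGTH
    seq = list(random_dna(rng, total))
    seq[:LTR_LENGTH] = list(ltr)
    seq[total - LTR_LENGTH :] = list(ltr)
    for gene, (start, end) in GENE_LAYOUT.items():
        n_codons = (end - start) // 3
        seq[start:end] = list(_random_orf(rng, n_codons))
    ltr_intervals = [(0, LTR_LENGTH), (total - LTR_LENGTH, total)]
    return "".join(seq), dict(GENE_LAYOUT), ltr_intervals


def make_truth_insertions(
    reference,
    n_loci: int,
    populations,
    seed,
    ltr_consensus: str | None = None,
    internal_consensus: str | None = None,
    provirus_fraction: float = 0.3,
    age_range_years=(0.5e6, 10e6),
    rate: float = 1.33e-9,
    freq_range=(0.1, 0.9),
    tsd_length: int = 5,
    flank_bp: int = 600,
    min_spacing: int = 3000,
):
    """Place a truth set of insertions on a reference.

    Breakpoints are uniform with at least ``min_spacing`` between loci and
    ``flank_bp`` clearance from chromosome ends; the TSD is read from the
    reference. A fraction of loci are full proviruses whose LTR pair is
    aged under the clock; the rest are solo LTRs. Per-population insertion
    allele frequencies are uniform in ``freq_range``.
    """
    rng = np.random.default_rng(seed)
    if ltr_consensus is None:
        ltr_consensus = make_ltr_consensus(rng.integers(2**31))
    if internal_consensus is None:
        internal_consensus = random_dna(rng, INTERNAL_LENGTH)
    chroms = [(rec.id, len(rec.seq), rec.seq) for rec in reference]
    total = sum(c[1] for c in chroms)
    placed = {c[0]: [] for c in chroms}
    truths = []
    attempts = 0
    while len(truths) < n_loci:
        attempts += 1
        if attempts > 1000 * n_loci:
            raise ValueError("could not place loci with required spacing")
        r = rng.integers(total)
        for name, length, seq in chroms:
            if r < length:
                chrom, chrom_len, chrom_seq = name, length, seq
                break
            r -= length
        b = int(rng.integers(flank_bp, chrom_len - flank_bp - tsd_length))
        if any(abs(b - p) < min_spacing for p in placed[chrom]):
            continue
        locus_id = f"locus{len(truths) + 1}"
        form = "provirus" if rng.random() < provirus_fraction else "solo_ltr"
        age = float(rng.uniform(*age_range_years))
        if form == "provirus":
            ltr5, ltr3, _ = mutate_ltr_pair(
                ltr_consensus, age, rate, rng.integers(2**31)
            )
            element = ltr5 + internal_consensus + ltr3
        else:
            element = ltr_consensus
        truths.append(
            TruthInsertion(
                locus_id=locus_id,
                chrom=chrom,
                breakpoint=b,
                orientation="+" if rng.random() < 0.5 else "-",
                form=form,
                tsd=chrom_seq[b : b + tsd_length],
                element_seq=element,
                true_age_years=age,
                pop_freqs={p: float(rng.uniform(*freq_range)) for p in populations},
            )
        )
        placed[chrom].append(b)
    return truths


def write_truth_table(truth_list, path) -> None:
    """Serialize a truth set as TSV (one row per locus, freqs as pop=f)."""
    with open(path, "w") as fh:
        fh.write("locus_id\tchrom\tbreakpoint\torientation\tform\ttsd\tage_years\tpop_freqs\n")
        for t in truth_list:
            freqs = ",".join(f"{p}={f:.4f}" for p, f in sorted(t.pop_freqs.items()))
            fh.write(
                f"{t.locus_id}\t{t.chrom}\t{t.breakpoint}\t{t.orientation}\t"
                f"{t.form}\t{t.tsd}\t{t.true_age_years:.1f}\t{freqs}\n"
            )
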