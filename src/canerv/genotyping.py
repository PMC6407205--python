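"""In silico genotyping of ERV insertion loci.

For every locus the insertion and pre-insertion alleles are reconstructed
from the reference flanks (accounting for the TSD pair), sample reads are
remapped competitively to both alleles, and genotype likelihoods are
computed per sample from mapping-quality-derived error probabilities.
Population allele frequencies summarize the calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .formats import revcomp


@dataclass
class AllelePair:
    """Reference-matching and alternate allele sequences for one locus.

    Both alleles share identical outer flanks; ``*_junctions`` are the
    discriminating coordinates on each allele (a supporting read must
    overlap one by at least a base). ``internal_interval`` marks the
    element's internal (non-LTR) portion on whichever allele carries the
    element; pairs wholly inside it are excluded from genotyping.
    """

    locus_id: str
    ref_allele_seq: str
    alt_allele_seq: str
    ref_junctions: tuple
    alt_junctions: tuple
    internal_interval: tuple | None = None
    internal_on: str = "alt"  # which allele carries the element
    element_filled: bool = False


@dataclass
class GenotypeCall:
    sample_id: str
    locus_id: str
    gl: tuple  # log10 likelihoods (hom_ref, het, hom_alt)
    gt: str  # 0/0, 0/1, 1/1, ./.
    ad: tuple  # (ref_pairs, alt_pairs)


def reconstruct_alleles(
    locus,
    reference: dict,
    element_seq: str | None = None,
    consensus: str | None = None,
    flank_bp: int = 600,
    tsd_length: int = 5,
    ltr_length: int = 457,
    element_interval: tuple | None = None,
) -> AllelePair:
    """Recreate insertion and pre-insertion alleles around a breakpoint.

    Non-reference locus (``locus.is_reference`` false): the reference
    carries the pre-insertion allele; the alternate allele inserts the
    element between a duplicated TSD. Reference locus: the assembly carries
    the insertion (``element_interval`` gives the element span on the
    reference, TSDs just outside it); the alternate allele is the excision
    leaving a single TSD copy.

    When ``element_seq`` is None the element's interior is unresolved; it
    is substituted from ``consensus`` (``element_filled=True``), or an
    "unfillable" error is raised if no consensus is supplied.
    """
    chrom_seq = reference[locus.chrom] if isinstance(reference, dict) else None
    if chrom_seq is None:
        chrom_seq = {rec.id: rec.seq for rec in reference}[locus.chrom]
    filled = False
    if not getattr(locus, "is_reference", False):
        if element_seq is None:
            if consensus is None:
                raise ValueError(f"{locus.locus_id}: unfillable (no element, no consensus)")
            element_seq = consensus
            filled = True
        b = locus.breakpoint
        if b < flank_bp or b + tsd_length + flank_bp > len(chrom_seq):
            raise ValueError(f"{locus.locus_id}: breakpoint within {flank_bp} bp of chromosome end")
        element = element_seq if getattr(locus, "orientation", "+") == "+" else revcomp(element_seq)
        ref_allele = chrom_seq[b - flank_bp : b + tsd_length + flank_bp]
        alt_allele = (
            chrom_seq[b - flank_bp : b + tsd_length]
            + element
            + chrom_seq[b : b + tsd_length + flank_bp]
        )
        ref_junctions = (flank_bp + tsd_length,)
        alt_junctions = (
            flank_bp + tsd_length,
            flank_bp + tsd_length + len(element),
        )
        internal_on = "alt"
        elem_start = flank_bp + tsd_length
        elem_len = len(element)
        carrier_len = len(alt_allele)
    else:
        if element_interval is None:
            raise ValueError(f"{locus.locus_id}: reference locus needs element_interval")
        s, e = element_interval
        if s - tsd_length - flank_bp < 0 or e + tsd_length + flank_bp > len(chrom_seq):
            raise ValueError(f"{locus.locus_id}: element within {flank_bp} bp of chromosome end")
        # reference allele carries [TSD][element][TSD]
        ref_allele = chrom_seq[s - tsd_length - flank_bp : e + tsd_length + flank_bp]
        alt_allele = chrom_seq[s - tsd_length - flank_bp : s] + chrom_seq[e + tsd_length : e + tsd_length + flank_bp]
        ref_junctions = (
            flank_bp + tsd_length,
            flank_bp + tsd_length + (e - s),
        )
        alt_junctions = (flank_bp + tsd_length,)
        internal_on = "ref"
        elem_start = flank_bp + tsd_length
        elem_len = e - s
        carrier_len = len(ref_allele)
    internal = None
    if elem_len > 2 * ltr_length + 50:
        internal = (elem_start + ltr_length, elem_start + elem_len - ltr_length)
    return AllelePair(
        locus_id=locus.locus_id,
        ref_allele_seq=ref_allele,
        alt_allele_seq=alt_allele,
        ref_junctions=ref_junctions,
        alt_junctions=alt_junctions,
        internal_interval=internal,
        internal_on=internal_on,
        element_filled=filled,
    )


def _best_placement(seq: str, allele: str):
    """Best infix placement of a read on an allele (either strand).

    Returns ``(score, start, end)`` with score = len - 2 x edit distance.
    """
    best = (-(10 ** 9), 0, 0)
    for s in (seq, revcomp(seq)):
        res = edlib.align(s, allele, mode="HW", task="locations")
        d = res["editDistance"]
        score = len(s) - 2 * d
        if score > best[0]:
            start, end = res["locations"][0]
            best = (score, start, end + 1)
    return best


def assign_reads(read_pairs, allele_pair: AllelePair, mapqs=None,
                 max_divergence: float = 0.1):
    """Competitively assign read pairs to the two alleles of a locus.

    Each pair supports the allele with the higher summed alignment score;
    ties are uninformative. Both mates must place on the supported allele
    within ``max_divergence`` edit distance (reads from outside the allele
    windows place arbitrarily and would otherwise vote by noise). Pairs
    with both mates wholly inside the element's internal portion are
    dropped, and a supporting pair must have at least one read overlapping
    a discriminating junction of its allele by >= 1 base. ``mapqs``
    optionally maps pair name to a mapping quality (default 60) carried
    into the likelihood model.

    Returns a list of ``(name, 'ref'|'alt', mapq)``.
    """
    mapqs = mapqs or {}
    out = []
    for name, s1, s2 in read_pairs:
        ref1 = _best_placement(s1, allele_pair.ref_allele_seq)
        ref2 = _best_placement(s2, allele_pair.ref_allele_seq)
        alt1 = _best_placement(s1, allele_pair.alt_allele_seq)
        alt2 = _best_placement(s2, allele_pair.alt_allele_seq)
        ref_score = ref1[0] + ref2[0]
        alt_score = alt1[0] + alt2[0]
        if ref_score == alt_score:
            continue  # uninformative
        if ref_score > alt_score:
            allele, places, junctions = "ref", (ref1, ref2), allele_pair.ref_junctions
        else:
            allele, places, junctions = "alt", (alt1, alt2), allele_pair.alt_junctions
        min_scores = (
            len(s1) - 2 * max_divergence * len(s1),
            len(s2) - 2 * max_divergence * len(s2),
        )
        if places[0][0] < min_scores[0] or places[1][0] < min_scores[1]:
            continue  # a mate does not genuinely align to the supported allele
        if allele == allele_pair.internal_on and allele_pair.internal_interval:
            lo, hi = allele_pair.internal_interval
            if all(lo <= p[1] and p[2] <= hi for p in places):
                continue  # internal-internal pair: non-specific
        if not any(p[1] < j < p[2] for p in places for j in junctions):
            continue  # does not span the discriminating breakpoint
        out.append((name, allele, mapqs.get(name, 60)))
    return out


def genotype_likelihoods(ref_reads: int, alt_reads: int, mapqs,
                         sample_id: str = "", locus_id: str = "") -> GenotypeCall:
    """Genotype one sample at one locus from supporting read-pair counts.

    Each supporting read pair contributes, with error probability
    ``e = 10^(-mapq/10)``: ``1 - e`` under the homozygous genotype matching
    its allele, ``e`` under the opposite homozygote, and ``1/2`` under the
    heterozygote. Likelihoods are log10 sums; the call is the maximum
    (no prior). Zero informative reads yield a missing call ("./.").
    """
    if len(mapqs) != ref_reads + alt_reads:
        raise ValueError("mapq list length must equal read count")
    if ref_reads + alt_reads == 0:
        return GenotypeCall(sample_id, locus_id, (0.0, 0.0, 0.0), "./.", (0, 0))
    gl = [0.0, 0.0, 0.0]
    for i, q in enumerate(mapqs):
        eps = max(1e-10, 10 ** (-q / 10))
        p_match, p_other = 1 - eps, eps
        if i < ref_reads:  # ref-supporting
            gl[0] += math.log10(p_match)
            gl[2] += math.log10(p_other)
        else:
            gl[0] += math.log10(p_other)
            gl[2] += math.log10(p_match)
        gl[1] += math.log10(0.5)
    gt = ("0/0", "0/1", "1/1")[int(np.argmax(gl))]
    return GenotypeCall(sample_id, locus_id, tuple(gl), gt, (ref_reads, alt_reads))


def genotype_sample(read_pairs, allele_pair: AllelePair, sample_id: str,
                    mapqs=None) -> GenotypeCall:
    """Assign a sample's candidate reads and genotype the locus."""
    assigned = sorted(assign_reads(read_pairs, allele_pair, mapqs),
                      key=lambda a: a[1] != "ref")
    ref_n = sum(1 for a in assigned if a[1] == "ref")
    alt_n = len(assigned) - ref_n
    return genotype_likelihoods(ref_n, alt_n, [a[2] for a in assigned],
                                sample_id, allele_pair.locus_id)


_SKIP_FLAGS = {"tsd_mismatch", "single_junction", "encompassing_duplication",
               "orientation_conflict"}


def cohort_genotype(loci, reads_for, population_table: dict,
                    skip_overrides: dict | None = None):
    """Genotype a cohort over a set of loci and summarize frequencies.

    ``loci`` is a list of ``(locus, AllelePair)``; ``reads_for(sample_id,
    locus)`` returns the candidate ``(name, seq1, seq2)`` pairs (and may
    also return ``(pairs, mapqs)``). Loci flagged unsuitable (mismatched
    TSD, single junction, encompassing duplication) are skipped with a
    reason unless overridden via ``skip_overrides[locus_id] = False``.

    Returns ``(calls, frequency_table, skipped)`` where ``calls`` maps
    locus -> {sample -> GenotypeCall} and ``frequency_table`` is a
    DataFrame with one row per locus x population (plus an ALL row):
    alt_allele_count, total_alleles, frequency.
    """
    skip_overrides = skip_overrides or {}
    calls: dict = {}
    skipped = []
    samples = list(population_table)
    for locus, allele_pair in loci:
        flags = set(getattr(locus, "flags", ()))
        sides = getattr(locus, "sides", ())
        if sides and not any(s in ("full_ltr",) for s in sides) and len(set(sides)) < 2:
            flags.add("single_junction")
        bad = flags & _SKIP_FLAGS
        if bad and skip_overrides.get(locus.locus_id, True):
            skipped.append((locus.locus_id, ",".join(sorted(bad))))
            continue
        per_sample = {}
        for sample_id in samples:
            if sample_id not in population_table:
                raise ValueError(f"sample {sample_id!r} absent from population table")
            got = reads_for(sample_id, locus)
            if isinstance(got, tuple):
                pairs, mapqs = got
            else:
                pairs, mapqs = got, None
            per_sample[sample_id] = genotype_sample(pairs, allele_pair, sample_id, mapqs)
        calls[locus] = per_sample
    freq = frequency_table(calls, population_table)
    return calls, freq, skipped


def frequency_table(calls, population_table: dict) -> pd.DataFrame:
    """Per-population insertion allele frequencies over genotyped samples.

    Samples with missing calls ("./.") at a locus are excluded from that
    locus's denominator.
    """
    rows = []
    copies = {"0/0": 0, "0/1": 1, "1/1": 2}
    for locus, per_sample in calls.items():
        groups: dict = {}
        for sample_id, call in per_sample.items():
            if call.gt == "./.":
                continue
            pop = population_table[sample_id]
            for key in (pop, "ALL"):
                alt, tot = groups.get(key, (0, 0))
                groups[key] = (alt + copies[call.gt], tot + 2)
        for pop, (alt, tot) in sorted(groups.items()):
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "population": pop,
                    "alt_allele_count": alt,
                    "total_alleles": tot,
                    "frequency": alt / tot if tot else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["locus_id", "population", "alt_allele_count",
                                       "total_alleles", "frequency"])
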