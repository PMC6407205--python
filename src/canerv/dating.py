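"""Molecular-clock dating of proviruses from LTR divergence.

The two LTRs of a provirus are identical at integration and diverge
neutrally afterwards, so the number of changes between them, divided by
the LTR length and the neutral substitution rate, estimates the formation
time. Gap runs longer than 2 bp are treated as single mutational events.
For groups of identical LTR haplotypes (which imply a common recent
source) the age is bounded by the waiting time for one substitution over
the concatenated length of the group's LTRs.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .config import CANINE_RATE


@dataclass
class LtrPairAlignment:
    """A gapped 5'/3' LTR alignment with its change count."""

    aligned_5p: str
    aligned_3p: str
    n_changes: int
    effective_length: int  # ungapped 5' LTR length


@dataclass
class AgeEstimate:
    locus_id: str
    n_changes: int
    effective_length: int
    rate: float
    age_years: float
    method: str  # 'ltr_pair' or 'cluster'


@dataclass
class HaplotypeCluster:
    """Two or more loci sharing an identical LTR haplotype."""

    cluster_id: str
    member_ids: tuple
    haplotype: str

    @property
    def total_length(self) -> int:
        return len(self.haplotype) * len(self.member_ids)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -0.5
    return aligner


def align_ltr_pair(ltr5: str, ltr3: str) -> LtrPairAlignment:
    """Globally align a 5'/3' LTR pair and count changes under the gap rule.

    Scoring: match +1, mismatch -1, gap open -4, extend -0.5; mismatches
    are therefore preferred over gaps wherever either explains the data.
    """
    if not ltr5 or not ltr3:
        raise ValueError("both LTR sequences must be nonempty")
    alignment = _aligner().align(ltr5.upper(), ltr3.upper())[0]
    a5, a3 = str(alignment[0]), str(alignment[1])
    aln = LtrPairAlignment(a5, a3, 0, len(ltr5))
    aln.n_changes = count_ltr_changes(aln)
    return aln


def count_ltr_changes(alignment: LtrPairAlignment) -> int:
    """Count changes: mismatched columns plus gap events.

    Gap runs of 1-2 bp count one change per column; runs longer than 2 bp
    count as a single change (one insertion/deletion event).
    """
    a, b = alignment.aligned_5p, alignment.aligned_3p
    if len(a) != len(b):
        raise ValueError("aligned strings must be equal length")
    changes = 0
    run = 0  # current gap-run length
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            raise ValueError("gap aligned to gap: invalid alignment")
        if x == "-" or y == "-":
            run += 1
            continue
        if run:
            changes += run if run <= 2 else 1
            run = 0
        if x != y:
            changes += 1
    if run:
        changes += run if run <= 2 else 1
    return changes


def age_from_divergence(n_changes: int, length: int,
                        rate: float = CANINE_RATE) -> float:
    """Formation-time estimate in years: (D / L) / rate, no factor of two.

    One change over a 457-bp LTR at the canine rate gives ~1.645 My — the
    resolution floor of single-provirus dating.
    """
    if length <= 0 or rate <= 0:
        raise ValueError("length and rate must be positive")
    return n_changes / (length * rate)


def date_ltr_pair(locus_id: str, ltr5: str, ltr3: str,
                  rate: float = CANINE_RATE) -> AgeEstimate:
    """Align an LTR pair and convert its divergence to an age."""
    aln = align_ltr_pair(ltr5, ltr3)
    age = age_from_divergence(aln.n_changes, aln.effective_length, rate)
    return AgeEstimate(locus_id, aln.n_changes, aln.effective_length, rate,
                       age, "ltr_pair")


def cluster_identical_ltrs(ltr_sequences: dict):
    """Group loci whose LTR sequences are exactly identical.

    ``ltr_sequences`` maps locus_id -> ungapped uppercase sequence.
    Returns ``(clusters, singletons)``: clusters of size >= 2 as
    :class:`HaplotypeCluster`, remaining locus ids as singletons.
    """
    groups: dict = {}
    for locus_id, seq in ltr_sequences.items():
        groups.setdefault(seq.upper(), []).append(locus_id)
    clusters, singletons = [], []
    n = 0
    for seq in sorted(groups, key=lambda s: (-len(groups[s]), s)):
        ids = sorted(groups[seq])
        if len(ids) >= 2:
            n += 1
            clusters.append(HaplotypeCluster(f"cluster{n}", tuple(ids), seq))
        else:
            singletons.extend(ids)
    return clusters, singletons


def age_cluster(cluster: HaplotypeCluster, rate: float = CANINE_RATE) -> AgeEstimate:
    """Age bound for an identical-LTR cluster.

    The members show no change over their concatenated length ``T``, so the
    formation time is bounded by the waiting time for a single substitution
    across ``T``: ``1 / (T x rate)``.
    """
    total = cluster.total_length
    if total <= 0:
        raise ValueError("cluster total length must be positive")
    age = 1.0 / (total * rate)
    return AgeEstimate(cluster.cluster_id, 1, total, rate, age, "cluster")


def write_age_table(estimates, path) -> None:
    """Serialize age estimates as TSV (id, D, L, rate, age_years, method)."""
    with open(path, "w") as fh:
        fh.write("id\tn_changes\tlength\trate\tage_years\tmethod\n")
        for e in estimates:
            fh.write(
                f"{e.locus_id}\t{e.n_changes}\t{e.effective_length}\t"
                f"{e.rate:g}\t{e.age_years:.1f}\t{e.method}\n"
            )


def percent_identity(seq_a: str, seq_b: str, decimals: int = 1) -> float:
    """Percent identity over comparable (non-gap) aligned columns.

    Accepts equal-length (optionally gapped) strings; columns where either
    sequence has a gap are excluded from the denominator.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be equal length or pre-aligned")
    comparable = matches = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x == y:
            matches += 1
    if comparable == 0:
        raise ValueError("no comparable columns")
    return round(100.0 * matches / comparable, decimals)
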