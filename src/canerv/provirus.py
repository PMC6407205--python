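"""Proviral consensus building, defect cataloging, and Nei-Gojobori dN/dS.

A majority-rule consensus summarizes a set of aligned proviruses; each
provirus is then compared back to the consensus to catalog inactivating
changes (premature stops, frameshift and in-frame indels, large deletions)
in consensus coordinates. Defects identical across proviruses are inherited
from a shared source — the signature of proliferation by complementation —
including the recurrent ~1-kb env deletion that defines a subgroup.
Selective pressure on intact reading frames is quantified with the
Nei-Gojobori (1986) pathway-counting dN/dS with Jukes-Cantor correction.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

import edlib
import numpy as np

# standard genetic code, codon order TTT, TTC, TTA, TTG, TCT, ... (T,C,A,G)
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_ORDER = "TCAG"
GENETIC_CODE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_ORDER)
    for j, b in enumerate(_ORDER)
    for k, c in enumerate(_ORDER)
}
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))


@dataclass
class ConsensusModel:
    """A proviral consensus with gene and LTR intervals (0-based internal)."""

    consensus_seq: str
    gene_intervals: dict  # gene -> (start, end), 0-based half-open
    ltr_intervals: tuple = ()
    tie_columns: tuple = ()  # columns where the majority base was tied


@dataclass
class DefectRecord:
    """An inactivating change located in consensus coordinates.

    ``consensus_pos`` is 1-based bp from the consensus start — the
    convention used when reporting shared defects (e.g. "bp 882").
    """

    provirus_id: str
    kind: str  # premature_stop | frameshift_indel | inframe_indel | large_deletion
    consensus_pos: int
    gene: str
    length: int = 0  # indel length; 0 for stops
    inserted: bool = False
    truncated: bool = False


@dataclass
class SharedDefectGroup:
    kind: str
    gene: str
    consensus_pos: int  # anchor member's position, 1-based
    length: int
    member_ids: tuple


@dataclass
class DnDsResult:
    pair: tuple
    Sd: float
    Nd: float
    S: float
    N: float
    pS: float
    pN: float
    dS: float  # nan when undefined
    dN: float
    ratio: float  # dN/dS; nan when undefined
    z: float = float("nan")
    p_value: float = float("nan")
    flags: tuple = ()


# ---------------------------------------------------------------------------
# Consensus


def build_consensus(aligned_proviruses, gene_intervals=None, ltr_intervals=()):
    """Majority-rule consensus of a multiple alignment.

    Per column the most frequent non-gap residue wins; ties break
    alphabetically (A<C<G<T) and are logged in ``tie_columns``; columns
    where the gap is a strict majority are dropped. ``gene_intervals`` are
    annotation on the resulting consensus, supplied by the caller.
    """
    if len(aligned_proviruses) < 2:
        raise ValueError("need >= 2 aligned sequences")
    length = len(aligned_proviruses[0])
    if any(len(s) != length for s in aligned_proviruses):
        raise ValueError("ragged alignment")
    out = []
    ties = []
    for col in range(length):
        counts: dict = {}
        for s in aligned_proviruses:
            b = s[col].upper()
            counts[b] = counts.get(b, 0) + 1
        gaps = counts.pop("-", 0)
        if not counts or gaps > sum(counts.values()):
            continue
        best = max(counts.values())
        winners = sorted(b for b, n in counts.items() if n == best)
        if len(winners) > 1:
            ties.append(len(out))
        out.append(winners[0])
    return ConsensusModel(
        "".join(out), dict(gene_intervals or {}), tuple(ltr_intervals), tuple(ties)
    )


# ---------------------------------------------------------------------------
# ORFs


def find_orfs(seq: str, min_aa: int = 100):
    """ATG-initiated, stop-terminated ORFs in the three forward frames.

    Returns ``(start, end, frame, aa_length)`` tuples (0-based half-open
    nucleotide span including the stop codon; ``aa_length`` counts encoded
    residues including the initial Met, excluding the stop). Overlapping
    ORFs in different frames are all reported.
    """
    seq = seq.upper()
    orfs = []
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                aa = (i - start) // 3
                if aa >= min_aa:
                    orfs.append((start, i + 3, frame, aa))
                start = None
    return sorted(orfs)


# ---------------------------------------------------------------------------
# Defect catalog


def _consensus_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


def _align_to_consensus(provirus_seq: str, consensus_seq: str):
    """Affine-gap global alignment; returns per-base coordinate maps.

    Affine gap costs keep a single biological indel as one gap run instead
    of scattering it. ``prov2cons[i]`` is the consensus coordinate aligned
    to provirus base i (the insertion point for inserted bases);
    ``cons2prov[j]`` the provirus coordinate for consensus base j, or -1
    where deleted.
    """
    aln = _consensus_aligner().align(provirus_seq, consensus_seq)[0]
    ap, ac = str(aln[0]), str(aln[1])
    prov2cons = np.empty(len(provirus_seq), dtype=int)
    cons2prov = np.full(len(consensus_seq), -1, dtype=int)
    pi = ci = 0
    for x, y in zip(ap, ac):
        if x != "-" and y != "-":
            prov2cons[pi] = ci
            cons2prov[ci] = pi
            pi += 1
            ci += 1
        elif x != "-":  # present in provirus, absent from consensus
            prov2cons[pi] = min(ci, len(consensus_seq) - 1)
            pi += 1
        else:
            ci += 1
    return prov2cons, cons2prov


def catalog_defects(provirus_seq: str, consensus: ConsensusModel,
                    large_deletion_bp: int = 100):
    """Catalog stops and indels of one provirus against the consensus.

    Within each annotated gene: deletions and insertions are classified by
    length (frameshift when not a multiple of 3; ``large_deletion`` at
    >= ``large_deletion_bp``); premature stops are in-frame stop codons of
    the provirus's gene sequence upstream of the consensus stop. After a
    frameshift, only the first resulting (abortive) stop is reported.
    Positions are 1-based consensus bp. A provirus covering < 50% of the
    consensus is flagged truncated and cataloged where it aligns.
    """
    provirus_seq = provirus_seq.upper()
    cons_seq = consensus.consensus_seq.upper()
    prov2cons, cons2prov = _align_to_consensus(provirus_seq, cons_seq)
    truncated = len(provirus_seq) < 0.5 * len(cons_seq)
    pid = ""
    records = []
    # genome-wide indel runs, assigned to genes by their consensus start
    indels = _collect_indels(cons2prov, prov2cons)
    for gene, (gs, ge) in consensus.gene_intervals.items():
        gene_indels = []
        for cpos, length, inserted in indels:
            if inserted:
                if gs <= cpos < ge:
                    gene_indels.append((cpos, length, True))
            else:
                # deletions are intervals; clip to the gene
                lo, hi = max(cpos, gs), min(cpos + length, ge)
                if lo < hi:
                    gene_indels.append((lo, hi - lo, False))
        for cpos, length, inserted in sorted(gene_indels):
            if not inserted and length >= large_deletion_bp:
                kind = "large_deletion"
            elif length % 3:
                kind = "frameshift_indel"
            else:
                kind = "inframe_indel"
            records.append(DefectRecord(pid, kind, cpos + 1, gene, length,
                                        inserted, truncated))
        records.extend(
            _premature_stops(provirus_seq, prov2cons, cons2prov, gene, gs, ge,
                             gene_indels, truncated)
        )
    return records


def _collect_indels(cons2prov, prov2cons):
    runs = []
    n_cons = len(cons2prov)
    j = 0
    while j < n_cons:
        if cons2prov[j] == -1:
            start = j
            while j < n_cons and cons2prov[j] == -1:
                j += 1
            runs.append((start, j - start, False))
        else:
            j += 1
    i = 0
    n_prov = len(prov2cons)
    seen_cons = set()
    while i < n_prov:
        j0 = int(prov2cons[i])
        k = i + 1
        while k < n_prov and prov2cons[k] == j0:
            k += 1
        if k - i > 1 and j0 not in seen_cons:
            # one aligned base plus (k-i-1) inserted bases share coordinate j0
            runs.append((j0, k - i - 1, True))
            seen_cons.add(j0)
        i = k
    return runs


def _premature_stops(prov, prov2cons, cons2prov, gene, gs, ge, gene_indels,
                     truncated):
    # provirus span of the gene
    start_idx = next((int(cons2prov[j]) for j in range(gs, ge) if cons2prov[j] >= 0),
                     None)
    if start_idx is None:
        return []
    end_idx = next((int(cons2prov[j]) + 1 for j in range(ge - 1, gs - 1, -1)
                    if cons2prov[j] >= 0), start_idx)
    gene_seq = prov[start_idx:end_idx]
    # consensus positions of frameshifting indels, to stop after the abortive stop
    shift_points = sorted(cp for cp, length, _ in gene_indels if length % 3)
    records = []
    cons_stop_start = ge - 3
    for ci in range(len(gene_seq) // 3):
        codon = gene_seq[3 * ci : 3 * ci + 3]
        if codon not in STOP_CODONS:
            continue
        cpos = int(prov2cons[start_idx + 3 * ci])
        if cpos >= cons_stop_start:
            break
        records.append(DefectRecord("", "premature_stop", cpos + 1, gene, 0,
                                    False, truncated))
        if any(sp <= cpos for sp in shift_points):
            break  # abortive stop after a frameshift: downstream is noise
    return records


def find_shared_defects(catalogs: dict, pos_tolerance: int = 3):
    """Group identical defects carried by two or more proviruses.

    Defects match when kind, gene, and indel length are equal and the
    consensus positions lie within ``pos_tolerance`` bp of the group
    anchor. ``catalogs`` maps provirus_id -> list of DefectRecord.
    Singletons are excluded; groups are sorted by position.
    """
    entries = []
    for pid, records in catalogs.items():
        for r in records:
            entries.append((r.kind, r.gene, r.length, r.consensus_pos, pid))
    entries.sort()
    groups = []
    by_key: dict = {}
    for kind, gene, length, pos, pid in entries:
        by_key.setdefault((kind, gene, length), []).append((pos, pid))
    for (kind, gene, length), members in by_key.items():
        members.sort()
        cluster = [members[0]]
        for m in members[1:]:
            if abs(m[0] - cluster[0][0]) <= pos_tolerance:
                cluster.append(m)
            else:
                if len({p for _, p in cluster}) >= 2:
                    groups.append(_group(kind, gene, length, cluster))
                cluster = [m]
        if len({p for _, p in cluster}) >= 2:
            groups.append(_group(kind, gene, length, cluster))
    return sorted(groups, key=lambda g: g.consensus_pos)


def _group(kind, gene, length, cluster):
    return SharedDefectGroup(
        kind, gene, cluster[0][0], length,
        tuple(sorted({pid for _, pid in cluster})),
    )


def detect_env_deletion(catalogs: dict, expected_len: int = 1073, tol: int = 10):
    """Proviruses carrying the recurrent env deletion of ~``expected_len`` bp."""
    members = []
    for pid, records in catalogs.items():
        for r in records:
            if (
                r.gene == "env"
                and r.kind == "large_deletion"
                and not r.inserted
                and abs(r.length - expected_len) <= tol
            ):
                members.append(pid)
                break
    return sorted(members)


# ---------------------------------------------------------------------------
# Nei-Gojobori dN/dS


def _syn_fraction_sites(codon: str) -> float:
    """Synonymous site count of one codon (mutations to stops count as
    nonsynonymous)."""
    aa = GENETIC_CODE[codon]
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[alt] == aa and alt not in STOP_CODONS:
                syn += 1
    return syn / 3.0


_SITE_CACHE = {c: _syn_fraction_sites(c) for c in SENSE_CODONS}
_PAIR_CACHE: dict = {}


def _pathway_counts(a: str, b: str):
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    All orderings of the differing positions are enumerated; pathways
    passing through a stop codon are skipped (all pathways are used if
    every one is blocked). Steps between codons of equal amino acid are
    synonymous.
    """
    key = (a, b)
    if key in _PAIR_CACHE:
        return _PAIR_CACHE[key]
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        _PAIR_CACHE[key] = (0.0, 0.0)
        return 0.0, 0.0
    valid = []
    blocked = []
    for order in itertools.permutations(diff):
        current = a
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if GENETIC_CODE[current] == GENETIC_CODE[nxt] and nxt not in STOP_CODONS \
                    and current not in STOP_CODONS:
                sd += 1
            else:
                nd += 1
            if nxt in STOP_CODONS:
                hit_stop = True
            current = nxt
        (blocked if hit_stop else valid).append((sd, nd))
    use = valid if valid else blocked
    sd = sum(x for x, _ in use) / len(use)
    nd = sum(y for _, y in use) / len(use)
    _PAIR_CACHE[key] = (sd, nd)
    return sd, nd


def _jc_correct(p: float):
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_dnds(codon_seq_a: str, codon_seq_b: str, n_bootstrap: int = 1000,
              seed: int = 0) -> DnDsResult:
    """Nei-Gojobori (1986) dN/dS for a pair of aligned coding sequences.

    Site counts average the two sequences; differences are averaged over
    all minimal mutational pathways (stop-passing pathways skipped);
    proportions are Jukes-Cantor corrected. Significance of dN - dS comes
    from a codon bootstrap (``n_bootstrap`` resamples) of
    ``Z = (dN - dS)/se`` against a standard normal.
    """
    a, b = codon_seq_a.upper(), codon_seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be equal length")
    if len(a) % 3:
        raise ValueError("length must be a multiple of 3")
    n_codons = len(a) // 3
    codons_a = [a[3 * i : 3 * i + 3] for i in range(n_codons)]
    codons_b = [b[3 * i : 3 * i + 3] for i in range(n_codons)]
    for c in itertools.chain(codons_a, codons_b):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c}")
        if c not in GENETIC_CODE:
            raise ValueError(f"invalid codon {c!r}")
    S_i = np.array([
        (_SITE_CACHE[ca] + _SITE_CACHE[cb]) / 2.0
        for ca, cb in zip(codons_a, codons_b)
    ])
    N_i = 3.0 - S_i
    sd_i = np.empty(n_codons)
    nd_i = np.empty(n_codons)
    for i, (ca, cb) in enumerate(zip(codons_a, codons_b)):
        sd_i[i], nd_i[i] = _pathway_counts(ca, cb)
    S, N = float(S_i.sum()), float(N_i.sum())
    Sd, Nd = float(sd_i.sum()), float(nd_i.sum())
    pS = Sd / S if S > 0 else float("nan")
    pN = Nd / N if N > 0 else float("nan")
    dS, dN = _jc_correct(pS), _jc_correct(pN)
    flags = []
    if math.isnan(dS):
        flags.append("dS_undefined")
    if math.isnan(dN):
        flags.append("dN_undefined")
    ratio = float("nan")
    if not math.isnan(dS) and not math.isnan(dN) and dS > 0:
        ratio = dN / dS
    elif dS == 0 or math.isnan(dS):
        flags.append("ratio_undefined")
    z = p_value = float("nan")
    if n_bootstrap > 0 and n_codons > 1 and not math.isnan(dS) and not math.isnan(dN):
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_codons, size=(n_bootstrap, n_codons))
        with np.errstate(invalid="ignore", divide="ignore"):
            ps = sd_i[idx].sum(axis=1) / S_i[idx].sum(axis=1)
            pn = nd_i[idx].sum(axis=1) / N_i[idx].sum(axis=1)
            ds = -0.75 * np.log(1 - 4 * ps / 3)
            dn = -0.75 * np.log(1 - 4 * pn / 3)
        diffs = dn - ds
        diffs = diffs[np.isfinite(diffs)]
        se = float(diffs.std(ddof=1)) if len(diffs) > 1 else float("nan")
        if se and se > 0 and not math.isnan(se):
            from scipy.stats import norm

            z = (dN - dS) / se
            p_value = float(2 * norm.sf(abs(z)))
    return DnDsResult((0, 1), Sd, Nd, S, N, pS, pN, dS, dN, ratio, z, p_value,
                      tuple(flags))


def average_dnds(results) -> float:
    """Cohort average of pairwise dN/dS over pairs where both rates are
    defined and dS > 0 (undefined pairs are excluded)."""
    ratios = [r.ratio for r in results if not math.isnan(r.ratio)]
    if not ratios:
        return float("nan")
    return float(np.mean(ratios))
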