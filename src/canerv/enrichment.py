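"""Gene-proximity counts and the permutation test for genic depletion.

Insertions are intersected with gene models at a ladder of window sizes;
significance of depletion is assessed by shuffling insertion positions
uniformly over the genome and asking how often a shuffled set intersects
as few or fewer genes than observed (a one-sided lower-tail test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class WindowCounts:
    window_kb: float
    n_insertions_with_gene: int
    n_total_insertions: int


@dataclass
class PermutationResult:
    window_kb: float
    observed: int
    permuted_counts: np.ndarray
    p_depletion: float

    @property
    def p_report(self) -> str:
        """Printable p: '< 1/n' when no permutation was as extreme."""
        n = len(self.permuted_counts)
        return f"< {1 / n:g}" if self.p_depletion == 0 else f"{self.p_depletion:g}"


def _merged_intervals(genes):
    """Merge gene intervals per chromosome into sorted disjoint arrays."""
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = (
            np.array([s for s, _ in out]),
            np.array([e for _, e in out]),
        )
    return merged


def _count_near(positions_by_chrom: dict, merged: dict, pad: int) -> int:
    """Number of positions within ``pad`` of any interval."""
    total = 0
    for chrom, pos in positions_by_chrom.items():
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        pos = np.asarray(pos)
        # position p hits interval i iff starts[i] - pad <= p < ends[i] + pad
        idx = np.searchsorted(starts - pad, pos, side="right") - 1
        hit = np.zeros(len(pos), dtype=bool)
        valid = idx >= 0
        hit[valid] = pos[valid] < (ends + pad)[idx[valid]]
        # an earlier interval may still reach p when intervals differ in pad reach;
        # merged intervals are disjoint but padded ones can nest, so also check idx-1
        prev = idx - 1
        v2 = prev >= 0
        hit[v2] |= pos[v2] < (ends + pad)[prev[v2]]
        total += int(hit.sum())
    return total


def _positions_by_chrom(insertions):
    by_chrom: dict = {}
    for ins in insertions:
        pos = ins.pos if hasattr(ins, "pos") else ins[1]
        chrom = ins.chrom if hasattr(ins, "chrom") else ins[0]
        by_chrom.setdefault(chrom, []).append(pos)
    return by_chrom


def gene_window_counts(insertions, genes, windows_kb=(0, 5, 10, 25, 50, 100)):
    """Count insertions with >= 1 gene within each window size.

    An insertion counts for window ``w`` when some gene interval, expanded
    by ``w`` kb on both sides, contains its breakpoint; window 0 is strict
    overlap. Insertions on chromosomes absent from the gene set count as
    gene-free.
    """
    merged = _merged_intervals(genes)
    pos = _positions_by_chrom(insertions)
    n_total = sum(len(v) for v in pos.values())
    return [
        WindowCounts(w, _count_near(pos, merged, int(w * 1000)), n_total)
        for w in windows_kb
    ]


def shuffle_insertions(insertions, chrom_lengths: dict, seed):
    """Place the same number of insertions uniformly over the genome.

    ``insertions`` may be a list of insertions or a plain count; ``seed``
    may be an int or a numpy Generator. Chromosomes are chosen proportional
    to length; returns a dict chromosome -> array of positions.
    """
    n_insertions = insertions if isinstance(insertions, int) else len(insertions)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in names], dtype=float)
    choice = rng.choice(len(names), size=n_insertions, p=lengths / lengths.sum())
    out: dict = {}
    for i, name in enumerate(names):
        n = int((choice == i).sum())
        if n:
            out[name] = rng.integers(0, chrom_lengths[name], size=n)
    return out


def depletion_pvalue(observed: int, permuted_counts) -> float:
    """One-sided depletion p: fraction of permuted sets with count <= observed."""
    permuted_counts = np.asarray(permuted_counts)
    if permuted_counts.size == 0:
        raise ValueError("permuted_counts must be nonempty")
    return float((permuted_counts <= observed).sum() / permuted_counts.size)


def run_depletion_test(
    insertions,
    genes,
    chrom_lengths: dict,
    windows_kb=(0, 5, 10, 25, 50, 100),
    n_perm: int = 1000,
    seed: int = 0,
):
    """Observed gene-window counts plus permutation p-values per window."""
    rng = np.random.default_rng(seed)
    merged = _merged_intervals(genes)
    obs_pos = _positions_by_chrom(insertions)
    n = sum(len(v) for v in obs_pos.values())
    pads = [int(w * 1000) for w in windows_kb]
    observed = [_count_near(obs_pos, merged, pad) for pad in pads]
    permuted = np.zeros((len(windows_kb), n_perm), dtype=int)
    for p in range(n_perm):
        shuffled = shuffle_insertions(n, chrom_lengths, rng)
        for wi, pad in enumerate(pads):
            permuted[wi, p] = _count_near(shuffled, merged, pad)
    return [
        PermutationResult(w, obs, permuted[wi], depletion_pvalue(obs, permuted[wi]))
        for wi, (w, obs) in enumerate(zip(windows_kb, observed))
    ]


def write_depletion_table(results, path) -> None:
    """Serialize permutation results as TSV (one row per window)."""
    with open(path, "w") as fh:
        fh.write("window_kb\tobserved\tmean_permuted\tp_depletion\tp_report\n")
        for r in results:
            fh.write(
                f"{r.window_kb:g}\t{r.observed}\t"
                f"{float(np.mean(r.permuted_counts)):.2f}\t"
                f"{r.p_depletion:g}\t{r.p_report}\n"
            )
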