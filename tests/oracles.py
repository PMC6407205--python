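"""Independent brute-force oracles used to freeze expected test values.

These deliberately avoid the package's own code paths: translation goes
through Biopython, pathway enumeration through itertools, and arithmetic
is written from the method definitions.
"""

from itertools import permutations

from Bio.Seq import Seq


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def syn_sites_oracle(codon: str) -> float:
    """Synonymous site count of a codon by explicit neighbor enumeration."""
    aa = translate(codon)
    syn = 0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if translate(alt) == aa and translate(alt) != "*":
                syn += 1
    return syn / 3.0


def pathway_oracle(a: str, b: str):
    """Pathway-averaged (syn, nonsyn) difference counts for a codon pair."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    valid, blocked = [], []
    for order in permutations(diff):
        cur, sd, nd, hit_stop = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if (
                translate(cur) == translate(nxt)
                and translate(nxt) != "*"
                and translate(cur) != "*"
            ):
                sd += 1
            else:
                nd += 1
            if translate(nxt) == "*":
                hit_stop = True
            cur = nxt
        (blocked if hit_stop else valid).append((sd, nd))
    use = valid or blocked
    return (
        sum(x for x, _ in use) / len(use),
        sum(y for _, y in use) / len(use),
    )


def ng86_oracle(seq_a: str, seq_b: str):
    """Whole-pair NG86 counts (Sd, Nd, S, N) from the oracles above."""
    Sd = Nd = S = N = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        s = (syn_sites_oracle(ca) + syn_sites_oracle(cb)) / 2.0
        S += s
        N += 3.0 - s
        sd, nd = pathway_oracle(ca, cb)
        Sd += sd
        Nd += nd
    return Sd, Nd, S, N
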