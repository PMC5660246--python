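"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: translation goes
through Biopython's Seq.translate and adjacency counting enumerates
directed pairs explicitly.
"""

from Bio.Seq import Seq

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate(table=5))


def ng86_oracle_sites(codon: str) -> tuple[float, float]:
    aa = _aa(codon)
    syn = 0.0
    for pos in range(3):
        outcomes = []
        for base in BASES:
            if base == codon[pos]:
                continue
            alt_aa = _aa(codon[:pos] + base + codon[pos + 1 :])
            if alt_aa == "*":
                continue
            outcomes.append(alt_aa == aa)
        if outcomes:
            syn += sum(outcomes) / len(outcomes)
    return syn, 3.0 - syn


def ng86_oracle_paths(c1: str, c2: str) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) step counts over stop-free
    orderings of single-base steps; None when every ordering is blocked."""

    def walk(cur, remaining):
        if not remaining:
            return [(0.0, 0.0)]
        results = []
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                continue
            syn_step = _aa(cur) == _aa(nxt)
            for s, n in walk(nxt, [p for p in remaining if p != pos]):
                results.append((s + syn_step, n + (not syn_step)))
        return results

    diff = [i for i in range(3) if c1[i] != c2[i]]
    counts = walk(c1, diff)
    if not counts:
        return None
    return (
        sum(s for s, _ in counts) / len(counts),
        sum(n for _, n in counts) / len(counts),
    )


def breakpoint_oracle(perm_a, perm_b) -> int:
    """Signed circular breakpoints by direct enumeration of directed
    adjacencies in both reading directions."""

    def adjacencies(perm):
        n = len(perm)
        flip = {"J": "N", "N": "J"}
        out = set()
        for i in range(n):
            (ga, sa), (gb, sb) = perm[i], perm[(i + 1) % n]
            sa, sb = getattr(sa, "value", sa), getattr(sb, "value", sb)
            out.add((ga, sa, gb, sb))
            out.add((gb, flip[sb], ga, flip[sa]))
        return out

    a, b = adjacencies(perm_a), adjacencies(perm_b)
    return len(a - b) // 2
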