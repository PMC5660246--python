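"""Genome architecture: gene order and rearrangements, gene junctions,
control-region localization, and tandem-repeat detection.

Gene-order comparison uses strand-signed adjacencies on the circle: two
arrangements are identical iff they share all adjacencies (breakpoint
count 0), and each adjacency lost relative to a reference counts one
breakpoint.  No rearrangement scenario (inversion/translocation sorting)
is reconstructed.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from .genome_io import (
    AnnotatedGenome,
    FeatureClass,
    GeneFeature,
    Strand,
    ancestral_gene_order,
)

__all__ = [
    "GeneOrder",
    "RearrangementReport",
    "Junction",
    "JunctionReport",
    "TandemRepeat",
    "RepeatConfig",
    "gene_order",
    "ancestral_order",
    "compare_orders",
    "junctions",
    "locate_control_region",
    "find_tandem_repeats",
]


# ---------------------------------------------------------------------------
# Gene order and breakpoints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneOrder:
    """Signed circular gene order, linearized at ``anchor``."""

    anchor: str
    entries: tuple[tuple[str, Strand], ...]

    def rotated(self, anchor: str) -> "GeneOrder":
        names = [g for g, _ in self.entries]
        if anchor not in names:
            raise ValueError(
                f"anchor {anchor!r} absent; available: {', '.join(names)}"
            )
        i = names.index(anchor)
        return GeneOrder(anchor, self.entries[i:] + self.entries[:i])

    def signed(self) -> tuple[int | str, ...]:
        # +gene for J, -gene encoded as ("-", gene)
        return tuple(
            (g if s is Strand.J else "-" + g) for g, s in self.entries
        )


@dataclass
class RearrangementReport:
    breakpoint_count: int
    shared_adjacencies: list[tuple[str, str]]
    differing_blocks: list[tuple[tuple[str, ...], tuple[str, ...]]]


def gene_order(genome: AnnotatedGenome, anchor: str = "trnI") -> GeneOrder:
    """Walk the J-strand 5'->3' around the circle and list (gene, strand).

    The control region and unmappable features are excluded.  The order is
    rotated so that ``anchor`` comes first.
    """
    feats = [
        f
        for f in sorted(genome.features, key=lambda f: f.start)
        if f.feature_class is not FeatureClass.CR
        and f.canonical_name != "unknown"
    ]
    if not feats:
        raise ValueError(f"{genome.accession}: no gene features")
    order = GeneOrder(
        feats[0].canonical_name,
        tuple((f.canonical_name, f.strand) for f in feats),
    )
    names = [g for g, _ in order.entries]
    if anchor not in names:
        raise ValueError(
            f"anchor {anchor!r} absent from {genome.accession}; "
            f"available: {', '.join(names)}"
        )
    return order.rotated(anchor)


def ancestral_order(anchor: str = "trnI") -> GeneOrder:
    """The bundled ancestral insect reference order."""
    entries = tuple(ancestral_gene_order())
    return GeneOrder("trnI", entries).rotated(anchor)


def _signed_adjacencies(order: GeneOrder) -> set[tuple[str, str]]:
    """Strand-signed circular adjacencies, orientation-normalized.

    The adjacency (x, y) read on the J strand equals (-y, -x) read on the
    other strand; the lexicographically smaller spelling is kept so that
    comparison is orientation-free.
    """
    sig = order.signed()
    n = len(sig)
    out = set()
    for i in range(n):
        x, y = sig[i], sig[(i + 1) % n]
        flipped = (_neg(y), _neg(x))
        out.add(min((x, y), flipped))
    return out


def _neg(g: str) -> str:
    return g[1:] if g.startswith("-") else "-" + g


def compare_orders(
    observed: GeneOrder, reference: GeneOrder
) -> RearrangementReport:
    """Breakpoint comparison of two signed circular gene orders.

    Genes absent from either order are dropped from both (with a warning)
    before adjacencies are formed.  The breakpoint count is the number of
    observed adjacencies missing from the reference; by circularity it
    equals the count in the other direction, so the comparison is symmetric.
    """
    obs_names = {g for g, _ in observed.entries}
    ref_names = {g for g, _ in reference.entries}
    common = obs_names & ref_names
    if not common:
        raise ValueError("gene orders share no genes")
    if common != obs_names | ref_names:
        missing = sorted((obs_names | ref_names) - common)
        warnings.warn(f"genes dropped from comparison: {', '.join(missing)}")
    obs = GeneOrder(
        observed.anchor,
        tuple(e for e in observed.entries if e[0] in common),
    )
    ref = GeneOrder(
        reference.anchor,
        tuple(e for e in reference.entries if e[0] in common),
    )
    a_obs = _signed_adjacencies(obs)
    a_ref = _signed_adjacencies(ref)
    shared = a_obs & a_ref
    breakpoints = len(a_obs - a_ref)
    blocks = _differing_blocks(obs, ref, shared)
    return RearrangementReport(
        breakpoint_count=breakpoints,
        shared_adjacencies=sorted(shared),
        differing_blocks=blocks,
    )


def _differing_blocks(
    obs: GeneOrder, ref: GeneOrder, shared: set[tuple[str, str]]
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Maximal runs of genes bounded by non-shared adjacencies, paired with
    the corresponding gene run of the reference."""
    sig = obs.signed()
    n = len(sig)
    broken = [
        min((sig[i], sig[(i + 1) % n]),
            (_neg(sig[(i + 1) % n]), _neg(sig[i]))) not in shared
        for i in range(n)
    ]
    if not any(broken):
        return []
    blocks: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    # walk runs of consecutive broken junctions
    i = 0
    while i < n:
        if broken[i]:
            j = i
            while j + 1 < n and broken[j + 1]:
                j += 1
            genes = tuple(
                obs.entries[k % n][0] for k in range(i, j + 2)
            )
            ref_names = [g for g, _ in ref.entries]
            idx = sorted(ref_names.index(g) for g in genes if g in ref_names)
            ref_run = tuple(ref_names[k] for k in range(idx[0], idx[-1] + 1))
            blocks.append((ref_run, genes))
            i = j + 1
        i += 1
    return blocks


# ---------------------------------------------------------------------------
# Junctions: overlaps and intergenic spacers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Junction:
    gene_a: str
    gene_b: str
    length: int  # bp of overlap or spacer
    kind: str  # overlap | spacer | abutting | control_region


@dataclass
class JunctionReport:
    overlaps: list[Junction]
    spacers: list[Junction]
    control_region_span: Junction | None
    totals: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.totals = {
            "overlap_bp": sum(j.length for j in self.overlaps),
            "overlap_junctions": len(self.overlaps),
            "spacer_bp": sum(j.length for j in self.spacers),
            "spacer_count": len(self.spacers),
        }

    @property
    def longest_spacer(self) -> Junction | None:
        return max(self.spacers, key=lambda j: j.length, default=None)

    def overlap(self, gene_a: str, gene_b: str) -> int | None:
        for j in self.overlaps:
            if {j.gene_a, j.gene_b} == {gene_a, gene_b}:
                return j.length
        return None


def junctions(genome: AnnotatedGenome) -> JunctionReport:
    """Walk consecutive features around the circle, tallying overlaps and
    spacers.  Spacers adjacent to the control region (or the unannotated
    rrnS-trnI span that holds it) are reported separately, not in totals.
    """
    feats = sorted(genome.features, key=lambda f: f.start)
    if len(feats) < 2:
        raise ValueError("need at least two features")
    n = len(genome.sequence)
    overlaps: list[Junction] = []
    spacers: list[Junction] = []
    cr_span: Junction | None = None
    has_cr = any(f.feature_class is FeatureClass.CR for f in feats)
    for i, cur in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        if i + 1 < len(feats):
            gap = nxt.start - cur.end
        else:
            gap = (nxt.start + n) - cur.end
            if cur.wraps:  # last feature already wraps past the origin
                gap = nxt.start - cur.intervals[-1][1]
        cr_adjacent = FeatureClass.CR in (cur.feature_class, nxt.feature_class)
        if gap < 0:
            overlaps.append(
                Junction(cur.canonical_name, nxt.canonical_name, -gap,
                         "overlap")
            )
        elif gap > 0:
            j = Junction(cur.canonical_name, nxt.canonical_name, gap, "spacer")
            if (
                not has_cr
                and cur.canonical_name == "rrnS"
                and nxt.canonical_name == "trnI"
            ):
                cr_span = Junction(cur.canonical_name, nxt.canonical_name,
                                   gap, "control_region")
            elif not cr_adjacent:
                spacers.append(j)
    return JunctionReport(overlaps, spacers, cr_span)


# ---------------------------------------------------------------------------
# Control region
# ---------------------------------------------------------------------------

def locate_control_region(genome: AnnotatedGenome) -> GeneFeature:
    """The control region: annotated coordinates when present, else the
    unannotated span between the end of rrnS and the start of trnI on the
    J-strand walk (wrapping the origin when needed)."""
    for f in genome.features:
        if f.feature_class is FeatureClass.CR:
            return f
    if not (genome.has("rrnS") and genome.has("trnI")):
        raise ValueError("rrnS and trnI are required to infer the CR")
    n = len(genome.sequence)
    start = genome.get("rrnS").end % n
    end = genome.get("trnI").start
    if start == end:
        raise ValueError("no gap between rrnS and trnI")
    if start < end:
        intervals: tuple[tuple[int, int], ...] = ((start, end),)
    else:
        intervals = tuple(
            iv for iv in ((start, n), (0, end)) if iv[0] < iv[1]
        )
    cr = GeneFeature("CR", FeatureClass.CR, Strand.J, intervals, inferred=True)
    _warn_if_longer_gap(genome, cr.length)
    return cr


def _warn_if_longer_gap(genome: AnnotatedGenome, cr_length: int) -> None:
    feats = sorted(genome.features, key=lambda f: f.start)
    n = len(genome.sequence)
    for i, cur in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        gap = (nxt.start - cur.end) % n if i + 1 == len(feats) else nxt.start - cur.end
        if gap > cr_length and not (
            cur.canonical_name == "rrnS" and nxt.canonical_name == "trnI"
        ):
            warnings.warn(
                f"unannotated span {cur.canonical_name}-{nxt.canonical_name} "
                f"({gap} bp) exceeds the inferred control region"
            )


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatConfig:
    min_period: int = 10
    min_copies: float = 1.8
    min_identity: float = 0.80
    seed_k: int = 12
    min_seed_votes: int = 2
    max_candidates: int = 30


@dataclass(frozen=True)
class TandemRepeat:
    start: int  # 0-based offset within the searched region
    period: int
    copies: float
    identity: float
    consensus: str

    @property
    def end(self) -> int:
        return self.start + int(round(self.period * self.copies))

    @property
    def score(self) -> float:
        return self.identity * self.copies * self.period


def find_tandem_repeats(
    region: str, config: RepeatConfig = RepeatConfig()
) -> list[TandemRepeat]:
    """Detect tandem repeats in a nucleotide region.

    Candidate periods are seeded from exact k-mer recurrence distances;
    each candidate period is scored by self-alignment of the region against
    itself shifted by the period, maximal segments above the identity
    threshold become repeat calls, the fundamental period is recovered by
    divisor reduction, and overlapping calls are resolved greedily by
    identity x copies x period.
    """
    region = region.upper()
    L = len(region)
    if L < 2 * config.min_period:
        return []
    candidates = _candidate_periods(region, config)
    calls: list[TandemRepeat] = []
    for p in candidates:
        calls.extend(_calls_for_period(region, p, config))
    calls.sort(key=lambda r: (-r.score, r.period, r.start))
    chosen: list[TandemRepeat] = []
    for r in calls:
        if all(_overlap_frac(r, c) <= 0.5 for c in chosen):
            chosen.append(r)
    chosen.sort(key=lambda r: r.start)
    return chosen


def _candidate_periods(region: str, config: RepeatConfig) -> list[int]:
    k = min(config.seed_k, max(3, config.min_period))
    last_seen: dict[str, int] = {}
    votes: Counter[int] = Counter()
    for i in range(len(region) - k + 1):
        kmer = region[i : i + k]
        if "N" in kmer:
            continue
        if kmer in last_seen:
            d = i - last_seen[kmer]
            if config.min_period <= d <= len(region) // 2 + 1:
                votes[d] += 1
        last_seen[kmer] = i
    ranked = [
        p for p, v in votes.most_common() if v >= config.min_seed_votes
    ]
    return ranked[: config.max_candidates]


def _calls_for_period(
    region: str, period: int, config: RepeatConfig
) -> list[TandemRepeat]:
    L = len(region)
    match = [region[i] == region[i + period] for i in range(L - period)]
    calls = []
    for seg_start, seg_end, ident in _segments(match, config.min_identity):
        total = seg_end - seg_start + period
        copies = total / period
        if copies < config.min_copies:
            continue
        p, ident2 = _reduce_period(region, seg_start, total, period, config)
        copies = total / p
        if copies < config.min_copies:
            continue
        consensus = _consensus(region, seg_start, total, p)
        calls.append(TandemRepeat(seg_start, p, round(copies, 2), round(ident2, 4),
                                  consensus))
    return calls


def _segments(
    match: list[bool], min_identity: float
) -> list[tuple[int, int, float]]:
    """Maximal segments whose mean match rate is at least ``min_identity``.

    Kadane-style scan over x[i] = match[i] - threshold: any positive-sum
    segment has identity above the threshold.
    """
    out = []
    best_sum = 0.0
    cur = 0.0
    start = 0
    best_end = -1
    best_at = 0.0
    i = 0
    n = len(match)
    while i <= n:
        done = i == n
        if not done:
            cur += (1.0 if match[i] else 0.0) - min_identity
        if done or cur < 0:
            if best_end >= start:
                seg = match[start : best_end + 1]
                ident = sum(seg) / len(seg)
                out.append((start, best_end + 1, ident))
            cur = 0.0
            start = i + 1
            best_end = -1
            best_at = 0.0
        elif cur > best_at:
            best_at = cur
            best_end = i
        i += 1
    return out


def _reduce_period(
    region: str, start: int, total: int, period: int, config: RepeatConfig
) -> tuple[int, float]:
    """Reduce a detected period to its fundamental divisor when the region
    also repeats at the divisor with acceptable identity."""
    best = period
    ident_best = _identity_at(region, start, total, period)
    for q in range(config.min_period, period):
        if period % q:
            continue
        ident = _identity_at(region, start, total, q)
        if ident >= config.min_identity:
            return q, ident
    return best, ident_best


def _identity_at(region: str, start: int, total: int, period: int) -> float:
    end = min(start + total, len(region))
    pairs = [
        region[i] == region[i + period]
        for i in range(start, end - period)
    ]
    return sum(pairs) / len(pairs) if pairs else 0.0


def _consensus(region: str, start: int, total: int, period: int) -> str:
    cols: list[Counter[str]] = [Counter() for _ in range(period)]
    for off in range(total):
        i = start + off
        if i < len(region):
            cols[off % period][region[i]] += 1
    return "".join(c.most_common(1)[0][0] if c else "N" for c in cols)


def _overlap_frac(a: TandemRepeat, b: TandemRepeat) -> float:
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    if hi <= lo:
        return 0.0
    return (hi - lo) / min(a.end - a.start, b.end - b.start)
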