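"""Pairwise sequence divergence: uncorrected p-distances, closed-form GTR
distances, substitution-saturation regressions, and nonsynonymous divergence
(Ka) by Nei-Gojobori (1986) counting under the invertebrate mitochondrial
code.

The GTR distance is the deterministic matrix-logarithm estimator: with F the
symmetrized divergence-proportion matrix of a sequence pair and Pi the
diagonal of its marginal base frequencies,

    d = -trace(Pi * log(Pi^-1 F)).

A non-positive eigenvalue in the log marks the pair as saturated and the
distance as undefined (returned as None, never an exception).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .codon_analysis import CODON_TO_AA, STOP_CODONS
from .genome_io import Alignment, FeatureClass

__all__ = [
    "DistanceMatrix",
    "SaturationResult",
    "KaResult",
    "p_distance",
    "gtr_distance",
    "distance_matrix",
    "saturation_analysis",
    "pooled_class_alignments",
    "ng86_codon_sites",
    "ng86_pair_counts",
    "ka",
    "ka_from_alignments",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_EIG_TOL = 1e-12


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _comparable(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays over columns where both rows hold an unambiguous base
    (pairwise deletion of gaps and N)."""
    xa = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    xb = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    if xa.size != xb.size:
        raise ValueError("sequences have unequal lengths")
    lut = np.full(256, -1, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        lut[ord(base)] = i
    ia, ib = lut[xa], lut[xb]
    keep = (ia >= 0) & (ib >= 0)
    return ia[keep], ib[keep]


def p_distance(a: str, b: str) -> float | None:
    """Proportion of differing sites, pairwise deletion; None if no
    comparable sites."""
    ia, ib = _comparable(a, b)
    if ia.size == 0:
        return None
    return float(np.mean(ia != ib))


def gtr_distance(a: str, b: str) -> float | None:
    """Closed-form general time-reversible distance; None when undefined.

    Bases absent from both sequences are dropped from the matrices so that
    reduced-alphabet pairs remain well defined.
    """
    ia, ib = _comparable(a, b)
    if ia.size < 4:
        return None
    F = np.zeros((4, 4))
    np.add.at(F, (ia, ib), 1.0)
    F /= ia.size
    F = (F + F.T) / 2.0
    pi = F.sum(axis=1)
    present = pi > 0
    F = F[np.ix_(present, present)]
    pi = pi[present]
    d_half = np.diag(pi ** -0.5)
    B = d_half @ F @ d_half
    w, U = np.linalg.eigh((B + B.T) / 2.0)
    if np.any(w <= _EIG_TOL):
        return None
    weights = (np.sqrt(pi)[:, None] * U) ** 2  # pi-weighted eigvec loadings
    d = -float(np.sum(np.log(w) * weights.sum(axis=0)))
    return max(d, 0.0)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray  # square; np.nan where undefined
    defined_mask: np.ndarray

    def pair(self, a: str, b: str) -> float | None:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[i, j]) if self.defined_mask[i, j] else None


def distance_matrix(
    rows: dict[str, str], metric: str = "p"
) -> DistanceMatrix:
    """All-pairs distance matrix over aligned rows; ``metric`` is "p" or
    "gtr"."""
    fn = {"p": p_distance, "gtr": gtr_distance}[metric]
    taxa = list(rows)
    n = len(taxa)
    values = np.zeros((n, n))
    mask = np.ones((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        d = fn(rows[taxa[i]], rows[taxa[j]])
        if d is None:
            values[i, j] = values[j, i] = np.nan
            mask[i, j] = mask[j, i] = False
        else:
            values[i, j] = values[j, i] = d
    return DistanceMatrix(taxa, values, mask)


# ---------------------------------------------------------------------------
# Saturation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaturationResult:
    position_class: str  # pos1 | pos2 | pos3 | rRNA
    slope: float
    intercept: float
    pearson_r: float
    mean_gtr: float
    n_pairs_used: int
    n_pairs_undefined: int


def pooled_class_alignments(
    pcg_alignments: list[Alignment],
    rrna_alignments: list[Alignment] | None = None,
) -> dict[str, dict[str, str]]:
    """Pool PCG columns by gene-local codon position (pos1/pos2/pos3) and
    rRNA columns into one row set per class, keyed by taxon."""
    classes: dict[str, dict[str, str]] = {}
    taxa: list[str] = []
    for aln in pcg_alignments:
        for t in aln.rows:
            if t not in taxa:
                taxa.append(t)
    for pos in range(3):
        rows: dict[str, str] = {}
        for t in taxa:
            parts = []
            for aln in pcg_alignments:
                seq = aln.rows.get(t, "-" * aln.column_count)
                parts.append(seq[pos::3])
            rows[t] = "".join(parts)
        classes[f"pos{pos + 1}"] = rows
    if rrna_alignments:
        rtaxa: list[str] = []
        for aln in rrna_alignments:
            for t in aln.rows:
                if t not in rtaxa:
                    rtaxa.append(t)
        rows = {
            t: "".join(
                aln.rows.get(t, "-" * aln.column_count)
                for aln in rrna_alignments
            )
            for t in rtaxa
        }
        classes["rRNA"] = rows
    return classes


def saturation_analysis(
    pcg_alignments: list[Alignment],
    rrna_alignments: list[Alignment] | None = None,
    through_origin: bool = False,
) -> list[SaturationResult]:
    """Regress uncorrected p-distance on GTR distance per position class.

    A shallow slope indicates saturation: observed differences no longer
    track true divergence.  Pairs whose GTR distance is undefined are
    excluded and counted.
    """
    classes = pooled_class_alignments(pcg_alignments, rrna_alignments)
    results = []
    for label, rows in classes.items():
        taxa = list(rows)
        if len(taxa) < 3:
            raise ValueError(f"{label}: fewer than 3 taxa")
        xs, ys = [], []
        undefined = 0
        for a, b in itertools.combinations(taxa, 2):
            g = gtr_distance(rows[a], rows[b])
            p = p_distance(rows[a], rows[b])
            if g is None or p is None:
                undefined += 1
                continue
            xs.append(g)
            ys.append(p)
        if len(xs) < 3:
            raise ValueError(f"{label}: fewer than 3 defined pairs")
        x = np.asarray(xs)
        y = np.asarray(ys)
        if through_origin:
            slope = float(x @ y / (x @ x))
            intercept = 0.0
            r = float(stats.pearsonr(x, y).statistic)
        else:
            fit = stats.linregress(x, y)
            slope, intercept, r = (
                float(fit.slope), float(fit.intercept), float(fit.rvalue)
            )
        results.append(
            SaturationResult(label, slope, intercept, r, float(np.mean(x)),
                             len(xs), undefined)
        )
    return results


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) nonsynonymous divergence
# ---------------------------------------------------------------------------

def ng86_codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes one site, split by the fraction of its
    possible single-base changes that are synonymous; changes creating a
    stop codon are excluded from consideration.
    """
    if codon in STOP_CODONS or codon not in CODON_TO_AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        s = tot = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            tot += 1
            if CODON_TO_AA[alt] == aa:
                s += 1
        syn += s / tot if tot else 0.0
    return syn, 3.0 - syn


def ng86_pair_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense
    codons, averaged over all orderings of single-base steps; pathways
    passing through a stop codon are excluded (all pathways are used if
    every ordering is blocked)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            # a step touching a stop codon counts as nonsynonymous in the
            # all-paths-blocked fallback; '*' never equals a sense aa
            if CODON_TO_AA.get(cur, "*") == CODON_TO_AA.get(nxt, "**"):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, sd, nd))
    valid = [(s, n) for b, s, n in paths if not b]
    if not valid:
        valid = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


@dataclass(frozen=True)
class KaResult:
    focal_taxon: str
    reference_taxon: str
    ka: float | None  # None when pn >= 3/4 (undefined)
    ks: float | None
    pn: float
    ps: float
    sites_n: float
    sites_s: float
    nd: float
    sd: float
    codons_used: int


def ka(
    focal: str,
    reference: str,
    focal_taxon: str = "focal",
    reference_taxon: str = "reference",
) -> KaResult:
    """NG86 nonsynonymous divergence of a codon-aligned sequence pair.

    Site counts are averaged over the two sequences; codons containing a
    gap, N or stop in either sequence are skipped; pn = Nd/N is corrected
    with the Jukes-Cantor formula ka = -(3/4) ln(1 - (4/3) pn).
    """
    if len(focal) != len(reference):
        raise ValueError("sequences have unequal lengths")
    if len(focal) % 3:
        raise ValueError("alignment length not divisible by 3")
    S = N = sd = nd = 0.0
    used = 0
    for i in range(0, len(focal), 3):
        ca, cb = focal[i : i + 3], reference[i : i + 3]
        if ca not in CODON_TO_AA or cb not in CODON_TO_AA:
            continue  # gap, ambiguity or stop
        sa, na = ng86_codon_sites(ca)
        sb, nb = ng86_codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        ds, dn = ng86_pair_counts(ca, cb)
        sd += ds
        nd += dn
        used += 1
    if used == 0:
        raise ValueError("no comparable codons")
    pn = nd / N if N else 0.0
    ps = sd / S if S else 0.0
    return KaResult(
        focal_taxon=focal_taxon,
        reference_taxon=reference_taxon,
        ka=_jc(pn),
        ks=_jc(ps),
        pn=pn,
        ps=ps,
        sites_n=N,
        sites_s=S,
        nd=nd,
        sd=sd,
        codons_used=used,
    )


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ka_from_alignments(
    pcg_alignments: list[Alignment], focal_taxon: str, reference_taxon: str
) -> KaResult:
    """Concatenate codon-aligned PCGs for two taxa and run :func:`ka`."""
    fparts, rparts = [], []
    for aln in pcg_alignments:
        if aln.feature_class is not FeatureClass.PCG:
            raise ValueError(f"{aln.gene_name}: not a PCG alignment")
        if focal_taxon in aln.rows and reference_taxon in aln.rows:
            fparts.append(aln.rows[focal_taxon])
            rparts.append(aln.rows[reference_taxon])
    if not fparts:
        raise ValueError("no shared gene alignments for the pair")
    return ka("".join(fparts), "".join(rparts), focal_taxon, reference_taxon)
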