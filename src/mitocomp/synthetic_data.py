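"""Synthetic annotated mitogenomes and diverged sequence pairs with known
ground truth.

The genome generator realizes a 37-gene circular mitogenome in the
ancestral insect arrangement (optionally permuted), with controllable A+T
content and strand skews, per-gene start/stop codons (including incomplete
stops), planted gene overlaps, and a control region carrying planted tandem
repeats.  The sequence evolver draws an ancestor from the stationary
distribution of a GTR model and evolves a descendant by the exact
transition probabilities exp(Qt) per site, so that pairwise-distance
estimators can be checked against a known branch length.

All randomness flows from the ``seed`` carried by GenomeSpec / EvolModel,
so every output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .codon_analysis import STOP_CODONS
from .genome_io import (
    AnnotatedGenome,
    FeatureClass,
    GeneFeature,
    Strand,
    ancestral_gene_order,
    reverse_complement,
    rotate_genome,
)

__all__ = [
    "DEFAULT_GENE_LENGTHS",
    "CRSpec",
    "GenomeSpec",
    "EvolModel",
    "generate_genome",
    "evolve_pair",
    "jc_model",
    "random_gtr_model",
]

_BASES = "ACGT"

#: Typical insect mitogenome gene lengths (bp).
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "cox1": 1536, "cox2": 684, "cox3": 786, "cob": 1137,
    "nad1": 927, "nad2": 978, "nad3": 351, "nad4": 1341,
    "nad4l": 291, "nad5": 1719, "nad6": 495, "atp6": 672, "atp8": 156,
    "rrnL": 1217, "rrnS": 745,
}
for _t in [f"trn{x}" for x in "ACDEFGHIKMNPQRTVWY"] + [
    "trnL1", "trnL2", "trnS1", "trnS2"
]:
    DEFAULT_GENE_LENGTHS[_t] = 66

#: Start/stop defaults mirroring a typical leafhopper pattern: ATN starts
#: except nad5 (TTG); complete TAA stops except nad5 (TAG) and an
#: incomplete T on cox2 and nad1.
DEFAULT_START_STOP: dict[str, tuple[str, str]] = {
    g: ("ATG", "TAA")
    for g in ("atp6", "atp8", "cox1", "cox3", "cob",
              "nad2", "nad3", "nad4", "nad4l", "nad6")
}
DEFAULT_START_STOP["nad5"] = ("TTG", "TAG")
DEFAULT_START_STOP["cox2"] = ("ATG", "T")
DEFAULT_START_STOP["nad1"] = ("ATA", "T")

DEFAULT_OVERLAPS: tuple[tuple[str, str, int], ...] = (
    ("atp8", "atp6", 7),
    ("nad4", "nad4l", 7),
    ("trnW", "trnC", 8),
)


@dataclass(frozen=True)
class CRSpec:
    """Control-region layout: total length and one planted tandem repeat.

    ``copies`` may be fractional; the partial copy is placed at the start
    of the region (as a suffix of the repeat unit) so the array is
    uninterrupted.
    """

    length: int = 908
    period: int = 239
    copies: float = 2.75
    noise: float = 0.02


@dataclass
class GenomeSpec:
    """Blueprint for one synthetic annotated mitogenome."""

    gene_order: list[tuple[str, Strand]] = field(
        default_factory=ancestral_gene_order
    )
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS)
    )
    at_target: float = 0.78
    at_skew_target: float = 0.05
    gc_skew_target: float = -0.20
    cr_spec: CRSpec | None = field(default_factory=CRSpec)
    overlap_spec: tuple[tuple[str, str, int], ...] = DEFAULT_OVERLAPS
    spacer_spec: tuple[tuple[str, str, int], ...] = ()
    start_stop_spec: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_START_STOP)
    )
    annotate_cr: bool = True
    origin_offset: int = 0
    accession: str = "SYN0001"
    taxon: str = "synthetic mitogenome"
    seed: int = 0

    def base_frequencies(self) -> np.ndarray:
        at, ats, gcs = self.at_target, self.at_skew_target, self.gc_skew_target
        fa = at / 2 * (1 + ats)
        ft = at / 2 * (1 - ats)
        fg = (1 - at) / 2 * (1 + gcs)
        fc = (1 - at) / 2 * (1 - gcs)
        return np.array([fa, fc, fg, ft])


def _draw(rng: np.random.Generator, freqs: np.ndarray, n: int) -> str:
    return "".join(_BASES[i] for i in rng.choice(4, size=n, p=freqs))


def _draw_codons(rng: np.random.Generator, freqs: np.ndarray, n: int) -> str:
    """n random sense (non-stop) codons."""
    out = []
    while len(out) < n:
        c = _draw(rng, freqs, 3)
        if c not in STOP_CODONS:
            out.append(c)
    return "".join(out)


def _complement_freqs(freqs: np.ndarray) -> np.ndarray:
    """Base frequencies seen after reverse complement (A<->T, C<->G)."""
    fa, fc, fg, ft = freqs
    return np.array([ft, fg, fc, fa])


def _core_sequence(
    gene: str,
    length: int,
    spec: GenomeSpec,
    rng: np.random.Generator,
    freqs: np.ndarray,
) -> tuple[str, int]:
    """Coding-sense sequence of one gene and its annotated length.

    ``freqs`` are coding-sense frequencies (already complemented for
    N-strand genes so the J-strand meets the composition targets).
    """
    is_pcg = gene in spec.start_stop_spec or gene.startswith(
        ("cox", "nad", "atp", "cob")
    )
    if not is_pcg:
        return _draw(rng, freqs, length), length
    start, stop = spec.start_stop_spec.get(gene, ("ATG", "TAA"))
    ann_length = length - (3 - len(stop)) if len(stop) < 3 else length
    inner = (ann_length - 3 - len(stop)) // 3
    if inner < 1:
        raise ValueError(f"{gene}: length {length} too short for a CDS")
    body = _draw_codons(rng, freqs, inner)
    # guard the codon straddling nothing: start + body + stop is in frame
    return start + body + stop, ann_length


def _cr_sequence(
    cr: CRSpec, rng: np.random.Generator, freqs: np.ndarray
) -> tuple[str, dict]:
    unit = _draw(rng, freqs, cr.period)
    total = int(round(cr.period * cr.copies))
    if total > cr.length:
        raise ValueError("repeat array longer than the control region")
    partial = total - cr.period * int(cr.copies)
    array = unit[cr.period - partial :] if partial else ""
    array += unit * int(cr.copies)
    chars = list(array)
    n_noise = 0
    for i in range(len(chars)):
        if rng.random() < cr.noise:
            chars[i] = rng.choice([b for b in _BASES if b != chars[i]])
            n_noise += 1
    array = "".join(chars)
    pad = _draw(rng, freqs, cr.length - total)
    truth = {
        "period": cr.period,
        "copies": round(total / cr.period, 4),
        "repeat_start": 0,
        "repeat_length": total,
        "noise_bases": n_noise,
        "consensus": unit,
    }
    return array + pad, truth


def generate_genome(spec: GenomeSpec) -> tuple[AnnotatedGenome, dict]:
    """Realize a GenomeSpec into an annotated genome plus a truth record.

    Composition control is two-pass: the genome is first generated at the
    nominal target frequencies, the realized whole-genome composition is
    measured, and the genome is regenerated once with the targets reflected
    about the measurement.  This cancels the first-order bias introduced by
    stop-codon rejection in coding genes, so the J-strand composition meets
    the targets in expectation.
    """
    genome, truth, measured = _generate_once(spec, spec.base_frequencies())
    adjusted = _reflect_targets(spec, measured)
    genome, truth, _ = _generate_once(spec, adjusted)
    return genome, truth


def _reflect_targets(spec: GenomeSpec, measured: np.ndarray) -> np.ndarray:
    at_m = measured[0] + measured[3]
    ats_m = (measured[0] - measured[3]) / at_m if at_m else 0.0
    gc_m = measured[2] + measured[1]
    gcs_m = (measured[2] - measured[1]) / gc_m if gc_m else 0.0
    at = float(np.clip(2 * spec.at_target - at_m, 0.02, 0.98))
    ats = float(np.clip(2 * spec.at_skew_target - ats_m, -0.95, 0.95))
    gcs = float(np.clip(2 * spec.gc_skew_target - gcs_m, -0.95, 0.95))
    fa = at / 2 * (1 + ats)
    ft = at / 2 * (1 - ats)
    fg = (1 - at) / 2 * (1 + gcs)
    fc = (1 - at) / 2 * (1 - gcs)
    return np.array([fa, fc, fg, ft])


def _generate_once(
    spec: GenomeSpec, freqs: np.ndarray
) -> tuple[AnnotatedGenome, dict, np.ndarray]:
    rng = np.random.default_rng(spec.seed)
    if not np.isclose(freqs.sum(), 1.0) or np.any(freqs < 0):
        raise ValueError("composition targets yield invalid base frequencies")
    order = list(spec.gene_order)
    names = [g for g, _ in order]
    overlap_at: dict[str, int] = {}
    for a, b, k in spec.overlap_spec:
        if a not in names or b not in names:
            continue
        if names[(names.index(a) + 1) % len(names)] != b:
            raise ValueError(f"overlap {a}-{b}: genes are not adjacent")
        if k >= min(spec.gene_lengths[a], spec.gene_lengths[b]):
            raise ValueError(f"overlap {a}-{b}: longer than a gene")
        overlap_at[b] = k
    spacer_at: dict[str, int] = {}
    for a, b, k in spec.spacer_spec:
        if a not in names or b not in names:
            continue
        if names[(names.index(a) + 1) % len(names)] != b:
            raise ValueError(f"spacer {a}-{b}: genes are not adjacent")
        if b in overlap_at:
            raise ValueError(f"{a}-{b}: both spacer and overlap specified")
        spacer_at[b] = k

    buffer: list[str] = []
    constrained: dict[int, str] = {}
    features: list[GeneFeature] = []
    pos = 0

    def write(at: int, base: str, constraint: bool) -> None:
        while len(buffer) <= at:
            buffer.append("")
        if buffer[at] and not constraint:
            return  # earlier feature owns this base
        if constraint and at in constrained and constrained[at] != base:
            raise ValueError(f"conflicting codon constraints at position {at}")
        buffer[at] = base
        if constraint:
            constrained[at] = base

    for gene, strand in order:
        length = spec.gene_lengths[gene]
        sense_freqs = freqs if strand is Strand.J else _complement_freqs(freqs)
        core, ann_length = _core_sequence(gene, length, spec, rng, sense_freqs)
        jseq = core if strand is Strand.J else reverse_complement(core)
        for off, base in enumerate(_draw(rng, freqs, spacer_at.get(gene, 0))):
            write(pos + off, base, False)
        pos += spacer_at.get(gene, 0)
        start = pos - overlap_at.get(gene, 0)
        cpos = _constrained_positions(gene, spec, strand, start, ann_length)
        for off, base in enumerate(jseq):
            write(start + off, base, (start + off) in cpos)
        features.append(
            GeneFeature(
                gene,
                _feature_class(gene),
                strand,
                ((start, start + ann_length),),
            )
        )
        pos = start + ann_length

    cr_truth: dict | None = None
    if spec.cr_spec is not None:
        cr_seq, cr_truth = _cr_sequence(spec.cr_spec, rng, freqs)
        cr_start = pos
        for off, base in enumerate(cr_seq):
            write(cr_start + off, base, False)
        cr_truth["cr_start"] = cr_start
        if spec.annotate_cr:
            features.append(
                GeneFeature("CR", FeatureClass.CR, Strand.J,
                            ((cr_start, cr_start + len(cr_seq)),))
            )
        pos = cr_start + len(cr_seq)

    sequence = _repair_internal_stops(
        "".join(buffer), features, set(constrained), rng, freqs
    )
    genome = AnnotatedGenome(spec.accession, spec.taxon, sequence, features)
    if spec.origin_offset:
        genome = rotate_genome(genome, spec.origin_offset)
    measured = np.array(
        [sequence.count(b) for b in _BASES], dtype=float
    )
    measured /= measured.sum()
    truth = {
        "seed": spec.seed,
        "genome_length": len(sequence),
        "gene_order": [(g, s.value) for g, s in order],
        "at_target": spec.at_target,
        "at_skew_target": spec.at_skew_target,
        "gc_skew_target": spec.gc_skew_target,
        "overlaps": [
            (a, b, k) for a, b, k in spec.overlap_spec
            if a in names and b in names
        ],
        "spacers": [
            (a, b, k) for a, b, k in spec.spacer_spec
            if a in names and b in names
        ],
        "start_stop": dict(spec.start_stop_spec),
        "gene_lengths": {f.canonical_name: f.length for f in features},
        "control_region": cr_truth,
    }
    return genome, truth, measured


def _feature_class(gene: str) -> FeatureClass:
    if gene.startswith("trn"):
        return FeatureClass.tRNA
    if gene.startswith("rrn"):
        return FeatureClass.rRNA
    return FeatureClass.PCG


def _constrained_positions(
    gene: str, spec: GenomeSpec, strand: Strand, start: int, ann_length: int
) -> set[int]:
    """J-strand positions carrying the start/stop codons of a PCG."""
    if _feature_class(gene) is not FeatureClass.PCG:
        return set()
    _, stop = spec.start_stop_spec.get(gene, ("ATG", "TAA"))
    head = range(start, start + 3)
    tail = range(start + ann_length - len(stop), start + ann_length)
    if strand is Strand.J:
        return set(head) | set(tail)
    return set(range(start, start + len(stop))) | set(
        range(start + ann_length - 3, start + ann_length)
    )


def _repair_internal_stops(
    sequence: str,
    features: list[GeneFeature],
    constrained: set[int],
    rng: np.random.Generator,
    freqs: np.ndarray,
) -> str:
    """Resample unconstrained bases until no PCG carries an internal stop.

    Overlapping genes share bases, so fixing one frame can perturb another;
    iterate to a joint fix (overlaps are a few bp, so this converges fast).
    """
    seq = list(sequence)
    for _ in range(100):
        dirty = False
        for f in features:
            if f.feature_class is not FeatureClass.PCG:
                continue
            s, e = f.intervals[0]
            coding = "".join(seq[s:e])
            if f.strand is Strand.N:
                coding = reverse_complement(coding)
            n_codons = len(coding) // 3
            for c in range(1, n_codons - (0 if len(coding) % 3 else 1)):
                codon = coding[3 * c : 3 * c + 3]
                if codon not in STOP_CODONS:
                    continue
                jpos = _jpos_of_codon_base(f, c, rng.integers(3))
                tries = 0
                while jpos in constrained and tries < 5:
                    jpos = _jpos_of_codon_base(f, c, rng.integers(3))
                    tries += 1
                if jpos in constrained:
                    raise ValueError(
                        f"{f.canonical_name}: cannot repair constrained stop"
                    )
                seq[jpos] = _BASES[rng.choice(4, p=freqs)]
                dirty = True
        if not dirty:
            return "".join(seq)
    raise RuntimeError("internal stop repair did not converge")


def _jpos_of_codon_base(f: GeneFeature, codon_idx: int, base_idx: int) -> int:
    s, e = f.intervals[0]
    offset = 3 * codon_idx + int(base_idx)
    if f.strand is Strand.J:
        return s + offset
    return e - 1 - offset


# ---------------------------------------------------------------------------
# Sequence-pair evolution under GTR
# ---------------------------------------------------------------------------

@dataclass
class EvolModel:
    """A GTR model plus a branch length for pair simulation.

    ``exchangeabilities`` are the six symmetric rates in the order
    (AC, AG, AT, CG, CT, GT); ``frequencies`` are stationary (A, C, G, T).
    The rate matrix is normalized to one expected substitution per site per
    unit of ``t``; ``site_rate_classes`` cycles per-site rate multipliers
    (e.g. (1, 1, 5) makes every third site five times faster).
    """

    exchangeabilities: tuple[float, ...] = (1, 1, 1, 1, 1, 1)
    frequencies: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    t: float = 0.1
    site_rate_classes: tuple[float, ...] | None = None
    seed: int = 0

    def q_matrix(self) -> np.ndarray:
        s = self.exchangeabilities
        pi = np.asarray(self.frequencies, dtype=float)
        if not np.isclose(pi.sum(), 1.0) or np.any(pi <= 0):
            raise ValueError("frequencies must be positive and sum to 1")
        if any(x <= 0 for x in s):
            raise ValueError("exchangeabilities must be positive")
        R = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for rate, (i, j) in zip(s, pairs):
            R[i, j] = R[j, i] = rate
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.sum(pi * np.diag(Q)))
        return Q / mu


def jc_model(t: float, seed: int = 0) -> EvolModel:
    return EvolModel(t=t, seed=seed)


def random_gtr_model(
    rng: np.random.Generator, t: float, site_rate_classes=None
) -> EvolModel:
    """A random GTR model with frequencies bounded away from zero."""
    ex = tuple(rng.lognormal(0.0, 0.5, size=6))
    pi = rng.dirichlet([10.0] * 4)
    pi = pi / pi.sum()
    return EvolModel(
        exchangeabilities=ex,
        frequencies=tuple(pi),
        t=t,
        site_rate_classes=site_rate_classes,
        seed=int(rng.integers(2**31 - 1)),
    )


def evolve_pair(
    length: int,
    model: EvolModel,
    codon_mode: bool = False,
) -> tuple[str, str, dict]:
    """Simulate an ancestor/descendant pair at branch length ``t``.

    The ancestor is drawn from the stationary frequencies; each site's
    descendant state is drawn from the exact transition matrix exp(Q t r)
    for its rate class.  In codon mode ``length`` counts codons and stop
    codons are rejected in both sequences (for Ka tests).
    """
    rng = np.random.default_rng(model.seed)
    n = length * 3 if codon_mode else length
    pi = np.asarray(model.frequencies)
    Q = model.q_matrix()
    rates = model.site_rate_classes or (1.0,)
    site_rate = np.array([rates[i % len(rates)] for i in range(n)])
    P = {r: expm(Q * model.t * r) for r in set(rates)}

    anc = rng.choice(4, size=n, p=pi)
    if codon_mode:
        anc = _reject_stop_codons(anc, rng, pi)
    dec = np.empty(n, dtype=int)
    u = rng.random(n)
    for r, Pr in P.items():
        idx = np.where(site_rate == r)[0]
        cum = np.cumsum(Pr, axis=1)
        dec[idx] = np.array(
            [int(np.searchsorted(cum[anc[i]], u[i])) for i in idx]
        )
    if codon_mode:
        dec = _reject_stop_descendants(anc, dec, rng, P, site_rate)
    to_str = lambda arr: "".join(_BASES[i] for i in arr)
    truth = {"t": model.t, "length": n, "seed": model.seed}
    return to_str(anc), to_str(dec), truth


def evolve_star(
    length: int,
    model: EvolModel,
    branch_lengths: dict[str, float],
    codon_mode: bool = False,
) -> tuple[dict[str, str], dict]:
    """Evolve several taxa from one ancestor along a star tree.

    Each taxon descends independently from a shared stationary ancestor by
    exp(Q t_i), so the expected pairwise distance of taxa i and j is
    t_i + t_j.  Returns rows keyed by taxon plus a truth record.
    """
    rng = np.random.default_rng(model.seed)
    n = length * 3 if codon_mode else length
    pi = np.asarray(model.frequencies)
    Q = model.q_matrix()
    rates = model.site_rate_classes or (1.0,)
    site_rate = np.array([rates[i % len(rates)] for i in range(n)])
    anc = rng.choice(4, size=n, p=pi)
    if codon_mode:
        anc = _reject_stop_codons(anc, rng, pi)
    rows: dict[str, str] = {}
    for taxon, t in branch_lengths.items():
        P = {r: expm(Q * t * r) for r in set(rates)}
        u = rng.random(n)
        dec = np.empty(n, dtype=int)
        for r, Pr in P.items():
            idx = np.where(site_rate == r)[0]
            cum = np.cumsum(Pr, axis=1)
            dec[idx] = np.array(
                [int(np.searchsorted(cum[anc[i]], u[i])) for i in idx]
            )
        if codon_mode:
            dec = _reject_stop_descendants(anc, dec, rng, P, site_rate)
        rows[taxon] = "".join(_BASES[i] for i in dec)
    truth = {
        "branch_lengths": dict(branch_lengths),
        "length": n,
        "seed": model.seed,
    }
    return rows, truth


def _codon_is_stop(arr: np.ndarray, i: int) -> bool:
    codon = "".join(_BASES[b] for b in arr[i : i + 3])
    return codon in STOP_CODONS


def _reject_stop_codons(
    anc: np.ndarray, rng: np.random.Generator, pi: np.ndarray
) -> np.ndarray:
    out = anc.copy()
    for i in range(0, len(out), 3):
        while _codon_is_stop(out, i):
            out[i : i + 3] = rng.choice(4, size=3, p=pi)
    return out


def _reject_stop_descendants(
    anc: np.ndarray,
    dec: np.ndarray,
    rng: np.random.Generator,
    P: dict[float, np.ndarray],
    site_rate: np.ndarray,
) -> np.ndarray:
    out = dec.copy()
    for i in range(0, len(out), 3):
        guard = 0
        while _codon_is_stop(out, i) and guard < 1000:
            for j in range(i, i + 3):
                row = P[site_rate[j]][anc[j]]
                out[j] = int(rng.choice(4, p=row / row.sum()))
            guard += 1
    return out
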