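"""Codon usage, RSCU and start/stop codon classification.

All translation uses the invertebrate mitochondrial genetic code
(NCBI transl_table 5): two stop codons (TAA, TAG), AGA/AGG = Ser,
TGA = Trp, ATA = Met — hence 62 sense codons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .genome_io import AnnotatedGenome, FeatureClass, extract_region

__all__ = [
    "GENETIC_CODE_ID",
    "CODON_TO_AA",
    "STOP_CODONS",
    "SYNONYMOUS_FAMILIES",
    "CodonUsageTable",
    "RSCUTable",
    "StartStopRecord",
    "StartStopReport",
    "extract_codons",
    "rscu",
    "start_stop_report",
]

GENETIC_CODE_ID = 5  # invertebrate mitochondrial

_TABLE = CodonTable.unambiguous_dna_by_id[GENETIC_CODE_ID]

#: Sense codon -> one-letter amino acid, DNA alphabet.
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: Amino acid -> tuple of synonymous codons.
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in ("".join(p) for p in itertools.product("TCAG", repeat=3)):
    if _codon in CODON_TO_AA:
        aa = CODON_TO_AA[_codon]
        SYNONYMOUS_FAMILIES.setdefault(aa, ())
        SYNONYMOUS_FAMILIES[aa] += (_codon,)


def _to_rna(codon: str) -> str:
    return codon.replace("T", "U")


@dataclass
class CodonUsageTable:
    """Codon counts pooled over the protein-coding genes of one genome."""

    taxon: str
    counts: dict[str, int]
    total_codons: int
    stop_counts: dict[str, int] = field(default_factory=dict)
    incomplete_stops: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    genetic_code: int = GENETIC_CODE_ID

    def as_rna(self) -> dict[str, int]:
        return {_to_rna(c): n for c, n in self.counts.items()}


@dataclass
class RSCUTable:
    """Relative synonymous codon usage: count / mean count of the family."""

    values: dict[str, float]
    family_sizes: dict[str, int]
    empty_families: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class StartStopRecord:
    gene: str
    start_codon: str
    start_class: str  # ATN | TTG | GTG | other
    stop_codon: str  # TAA | TAG | T | TA | other triplet
    stop_class: str  # complete | incomplete


@dataclass
class StartStopReport:
    records: list[StartStopRecord]

    def get(self, gene: str) -> StartStopRecord:
        for r in self.records:
            if r.gene == gene:
                return r
        raise KeyError(gene)

    @property
    def summary(self) -> dict[str, int]:
        out = {"TAA": 0, "TAG": 0, "incomplete": 0, "other": 0}
        for r in self.records:
            if r.stop_class == "incomplete":
                out["incomplete"] += 1
            elif r.stop_codon in ("TAA", "TAG"):
                out[r.stop_codon] += 1
            else:
                out["other"] += 1
        return out


def extract_codons(
    genome: AnnotatedGenome, drop_first_codon: bool = False
) -> CodonUsageTable:
    """Count codons in frame over all protein-coding genes.

    Complete terminal stop codons are tallied separately and excluded from
    ``total_codons``; a trailing 1-2 nt remainder is recorded as an
    incomplete stop.  An internal stop produces a warning record but the
    gene is still counted.
    """
    pcgs = genome.class_features(FeatureClass.PCG)
    if not pcgs:
        raise ValueError(f"{genome.accession}: no protein-coding genes")
    counts: dict[str, int] = {}
    stop_counts: dict[str, int] = {}
    incomplete: dict[str, str] = {}
    warns: list[str] = []
    total = 0
    for f in pcgs:
        seq = extract_region(genome, f)
        codons = [seq[i : i + 3] for i in range(0, len(seq) - 2, 3)]
        tail = len(seq) % 3
        if tail:
            incomplete[f.canonical_name] = seq[-tail:]
        elif codons and codons[-1] in STOP_CODONS:
            stop = codons.pop()
            stop_counts[stop] = stop_counts.get(stop, 0) + 1
        if drop_first_codon and codons:
            codons = codons[1:]
        for i, codon in enumerate(codons):
            if codon in STOP_CODONS:
                warns.append(
                    f"{f.canonical_name}: internal stop {codon} at codon {i + 1}"
                )
            if "N" in codon:
                continue
            counts[codon] = counts.get(codon, 0) + 1
            total += 1
    return CodonUsageTable(
        taxon=genome.taxon,
        counts=counts,
        total_codons=total,
        stop_counts=stop_counts,
        incomplete_stops=incomplete,
        warnings=warns,
    )


def rscu(usage: CodonUsageTable) -> RSCUTable:
    """RSCU per sense codon.

    RSCU of codon c = count(c) / mean count over c's synonymous family;
    a family with zero total yields RSCU 0 for all members and is flagged.
    """
    if usage.total_codons <= 0:
        raise ValueError("empty codon usage table")
    values: dict[str, float] = {}
    sizes: dict[str, int] = {}
    empty: list[str] = []
    for aa, family in SYNONYMOUS_FAMILIES.items():
        sizes[aa] = len(family)
        family_total = sum(usage.counts.get(c, 0) for c in family)
        if family_total == 0:
            empty.append(aa)
            for c in family:
                values[c] = 0.0
            continue
        mean = family_total / len(family)
        for c in family:
            values[c] = usage.counts.get(c, 0) / mean
    return RSCUTable(values=values, family_sizes=sizes, empty_families=empty)


_STOP_STARTS = ("T", "TA")  # incomplete stop spellings


def start_stop_report(genome: AnnotatedGenome) -> StartStopReport:
    """Classify start and stop codons for every protein-coding gene.

    A CDS whose length is not a multiple of three terminates in an
    incomplete stop (trailing T or TA, completed by polyadenylation).
    """
    records = []
    for f in genome.class_features(FeatureClass.PCG):
        seq = extract_region(genome, f)
        if len(seq) < 6:
            raise ValueError(f"{f.canonical_name}: CDS shorter than 6 nt")
        start = seq[:3]
        if start.startswith("AT"):
            start_class = "ATN"
        elif start in ("TTG", "GTG"):
            start_class = start
        else:
            start_class = "other"
        tail = len(seq) % 3
        if tail:
            stop, stop_class = seq[-tail:], "incomplete"
        else:
            stop = seq[-3:]
            stop_class = "complete"
        records.append(
            StartStopRecord(f.canonical_name, start, start_class, stop,
                            stop_class)
        )
    return StartStopReport(records)
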