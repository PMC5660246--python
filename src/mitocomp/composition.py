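"""Nucleotide composition and strand-skew statistics.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), computed per
region on the J-strand by default so that values are comparable across taxa
regardless of which strand encodes a gene.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from .genome_io import (
    Alignment,
    AnnotatedGenome,
    FeatureClass,
    extract_region,
)

__all__ = ["CompositionProfile", "profile", "table2_profiles", "codon_position_at"]


@dataclass(frozen=True)
class CompositionProfile:
    """Base counts and skew statistics for a named region.

    ``at_skew`` / ``gc_skew`` are None when their denominator is zero
    (the statistic is undefined, not zero).
    """

    region_label: str
    counts: dict[str, int]
    length_used: int
    at_percent: float
    at_skew: float | None
    gc_skew: float | None


def profile(sequence: str, region_label: str = "region") -> CompositionProfile:
    """Composition profile of a nucleotide string; N is excluded."""
    if not sequence:
        raise ValueError(f"{region_label}: empty sequence")
    counts = Counter(sequence.upper())
    bad = set(counts) - {"A", "C", "G", "T", "N"}
    if bad:
        raise ValueError(f"{region_label}: invalid characters {sorted(bad)}")
    a, c, g, t = (counts.get(b, 0) for b in "ACGT")
    used = a + c + g + t
    if used == 0:
        raise ValueError(f"{region_label}: no unambiguous bases")
    return CompositionProfile(
        region_label=region_label,
        counts={"A": a, "C": c, "G": g, "T": t},
        length_used=used,
        at_percent=100.0 * (a + t) / used,
        at_skew=(a - t) / (a + t) if a + t else None,
        gc_skew=(g - c) / (g + c) if g + c else None,
    )


def table2_profiles(
    genome: AnnotatedGenome, coding_strand: bool = False
) -> list[CompositionProfile]:
    """Profiles for the standard comparison regions of one genome.

    Returns whole genome, the 13 PCGs concatenated in genome order (J-strand
    slices, annotated overlaps counted twice), rrnL, rrnS and the control
    region; regions absent from the annotation are omitted with a warning.
    By default every slice is taken on the J-strand; ``coding_strand=True``
    switches to coding-sense slices.
    """
    out = [profile(genome.sequence, "whole")]

    pcgs = genome.class_features(FeatureClass.PCG)
    if pcgs:
        parts = []
        for f in sorted(pcgs, key=lambda f: f.start):
            if coding_strand:
                parts.append(extract_region(genome, f))
            else:
                parts.append(
                    "".join(genome.sequence[s:e] for s, e in f.intervals)
                )
        out.append(profile("".join(parts), "PCGs"))
    else:
        warnings.warn(f"{genome.accession}: no PCGs annotated")

    for gene, label in (("rrnL", "16S"), ("rrnS", "12S")):
        if genome.has(gene):
            f = genome.get(gene)
            seq = (
                extract_region(genome, f)
                if coding_strand
                else "".join(genome.sequence[s:e] for s, e in f.intervals)
            )
            out.append(profile(seq, label))
        else:
            warnings.warn(f"{genome.accession}: {gene} not annotated")

    cr = [f for f in genome.features if f.feature_class is FeatureClass.CR]
    if cr:
        seq = "".join(genome.sequence[s:e] for s, e in cr[0].intervals)
        out.append(profile(seq, "CR"))
    else:
        warnings.warn(f"{genome.accession}: control region not annotated")
    return out


def codon_position_at(alignments: list[Alignment]) -> list[CompositionProfile]:
    """Pooled composition per codon position over PCG alignments.

    Codon position is gene-local: columns 0, 3, 6, ... of each alignment are
    first positions, and so on.  Gap and N characters are excluded.  Returns
    three profiles labelled pos1, pos2, pos3.
    """
    if not alignments:
        raise ValueError("no alignments supplied")
    pooled = ["", "", ""]
    for aln in alignments:
        if aln.feature_class is not FeatureClass.PCG:
            raise ValueError(f"{aln.gene_name}: not a PCG alignment")
        for seq in aln.rows.values():
            for pos in range(3):
                pooled[pos] += seq[pos::3]
    return [
        profile(pooled[pos].replace("-", "").replace("?", ""), f"pos{pos + 1}")
        for pos in range(3)
    ]
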