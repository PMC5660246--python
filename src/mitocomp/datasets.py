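"""Supermatrix construction for phylogenetic datasets.

Builds the five standard datasets from per-gene alignments — P123 (all codon
positions of the 13 PCGs), P12 (first+second positions), P123R / P12R (with
the two rRNAs appended) and AA (translated PCGs) — together with by-gene and
by-gene-by-codon-position character sets in RAxML and NEXUS dialects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .codon_analysis import GENETIC_CODE_ID
from .genome_io import Alignment, FeatureClass

__all__ = [
    "PCG_ORDER",
    "RRNA_ORDER",
    "Charset",
    "SuperMatrix",
    "PartitionScheme",
    "concatenate",
    "codon_subset",
    "translate_matrix",
    "build_five_datasets",
    "strip_gap_and_stop_columns",
    "write_phylip",
    "write_fasta_matrix",
    "write_nexus",
    "write_raxml_partitions",
    "by_codon_position_scheme",
]

#: Canonical concatenation order (genome order; rRNAs appended last).
PCG_ORDER = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4l", "nad6", "cob", "nad1",
)
RRNA_ORDER = ("rrnL", "rrnS")


@dataclass(frozen=True)
class Charset:
    label: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    stride: int = 1
    feature_class: FeatureClass = FeatureClass.PCG


@dataclass
class SuperMatrix:
    taxa: list[str]
    rows: dict[str, str]
    charsets: list[Charset]
    alphabet: str = "nucleotide"  # nucleotide | amino-acid

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def column_count(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def slice_charset(self, label: str) -> Alignment:
        cs = next(c for c in self.charsets if c.label == label)
        rows = {
            t: s[cs.start - 1 : cs.end : cs.stride]
            for t, s in self.rows.items()
        }
        return Alignment(label, cs.feature_class, rows)


@dataclass
class PartitionScheme:
    subsets: list[tuple[str, list[str], str]]  # (name, charset labels, model)


def concatenate(
    alignments: list[Alignment], taxon_order: list[str] | None = None
) -> SuperMatrix:
    """Concatenate per-gene alignments into one supermatrix.

    Taxa missing from a gene are filled with gaps (warned); a charset is
    recorded per gene.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    if taxon_order is None:
        taxon_order = []
        for aln in alignments:
            for t in aln.rows:
                if t not in taxon_order:
                    taxon_order.append(t)
    shared = [
        t for t in taxon_order if any(t in a.rows for a in alignments)
    ]
    if not shared:
        raise ValueError("no taxa shared with the alignments")
    rows = {t: [] for t in shared}
    charsets = []
    pos = 0
    for aln in alignments:
        for t in shared:
            if t not in aln.rows:
                warnings.warn(f"{aln.gene_name}: taxon {t!r} filled with gaps")
            rows[t].append(aln.rows.get(t, "-" * aln.column_count))
        charsets.append(
            Charset(aln.gene_name, pos + 1, pos + aln.column_count,
                    feature_class=aln.feature_class)
        )
        pos += aln.column_count
    return SuperMatrix(shared, {t: "".join(p) for t, p in rows.items()},
                       charsets)


def codon_subset(matrix: SuperMatrix, positions: set[int]) -> SuperMatrix:
    """Keep the requested codon positions (subset of {1,2,3}) of every gene.

    Position is gene-local, counted from each charset's start; charsets are
    rewritten to the new coordinates.
    """
    if not positions or not positions <= {1, 2, 3}:
        raise ValueError(f"positions must be a non-empty subset of {{1,2,3}}")
    keep = sorted(positions)
    for cs in matrix.charsets:
        if cs.feature_class is not FeatureClass.PCG:
            raise ValueError(f"{cs.label}: non-PCG charset in codon subset")
        if (cs.end - cs.start + 1) % 3:
            raise ValueError(f"{cs.label}: length not divisible by 3")
    rows = {t: [] for t in matrix.taxa}
    charsets = []
    pos = 0
    for cs in matrix.charsets:
        width = cs.end - cs.start + 1
        n_codons = width // 3
        for t in matrix.taxa:
            gene = matrix.rows[t][cs.start - 1 : cs.end]
            rows[t].append(
                "".join(
                    gene[3 * c + (p - 1)] for c in range(n_codons) for p in keep
                )
            )
        new_width = n_codons * len(keep)
        charsets.append(
            Charset(cs.label, pos + 1, pos + new_width,
                    feature_class=cs.feature_class)
        )
        pos += new_width
    return SuperMatrix(matrix.taxa, {t: "".join(p) for t, p in rows.items()},
                       charsets)


def translate_matrix(matrix: SuperMatrix) -> SuperMatrix:
    """Codon-wise translation under the invertebrate mitochondrial code.

    All-gap codons become a gap, codons with partial gaps or ambiguity
    become X; an internal stop raises an error naming taxon, gene and site.
    """
    if matrix.alphabet != "nucleotide":
        raise ValueError("matrix is not nucleotide")
    for cs in matrix.charsets:
        if (cs.end - cs.start + 1) % 3:
            raise ValueError(f"{cs.label}: length not divisible by 3")
    rows = {t: [] for t in matrix.taxa}
    charsets = []
    pos = 0
    for cs in matrix.charsets:
        width = (cs.end - cs.start + 1) // 3
        for t in matrix.taxa:
            gene = matrix.rows[t][cs.start - 1 : cs.end]
            aas = []
            for c in range(0, len(gene), 3):
                codon = gene[c : c + 3]
                if codon == "---":
                    aas.append("-")
                elif "-" in codon or "N" in codon:
                    aas.append("X")
                else:
                    aa = str(Seq(codon).translate(table=GENETIC_CODE_ID))
                    if aa == "*":
                        raise ValueError(
                            f"internal stop: taxon {t!r}, gene {cs.label}, "
                            f"codon {c // 3 + 1}"
                        )
                    aas.append(aa)
            rows[t].append("".join(aas))
        charsets.append(
            Charset(cs.label, pos + 1, pos + width,
                    feature_class=cs.feature_class)
        )
        pos += width
    return SuperMatrix(matrix.taxa, {t: "".join(p) for t, p in rows.items()},
                       charsets, alphabet="amino-acid")


def build_five_datasets(
    pcg_alignments: list[Alignment],
    rrna_alignments: list[Alignment] | None = None,
    taxon_order: list[str] | None = None,
) -> dict[str, SuperMatrix]:
    """P123, P12, P123R, P12R and AA supermatrices from per-gene alignments.

    PCGs are concatenated in canonical genome order (then any extras in
    input order); rRNAs follow the PCG block in the R datasets.
    """
    pcgs = _in_canonical_order(pcg_alignments, PCG_ORDER)
    rrns = _in_canonical_order(rrna_alignments or [], RRNA_ORDER)
    p123 = concatenate(pcgs, taxon_order)
    p12 = codon_subset(p123, {1, 2})
    if rrns:
        order = taxon_order or p123.taxa
        p123r = concatenate(pcgs + rrns, order)
        p12r = _append_rrna(p12, rrns, order)
    else:
        p123r = p123
        p12r = p12
    return {
        "P123": p123,
        "P12": p12,
        "P123R": p123r,
        "P12R": p12r,
        "AA": translate_matrix(p123),
    }


def _in_canonical_order(
    alignments: list[Alignment], order: tuple[str, ...]
) -> list[Alignment]:
    rank = {g: i for i, g in enumerate(order)}
    return sorted(
        alignments, key=lambda a: rank.get(a.gene_name, len(order))
    )


def _append_rrna(
    pcg_matrix: SuperMatrix, rrns: list[Alignment], taxon_order: list[str]
) -> SuperMatrix:
    """Append rRNA blocks to an (already codon-subsetted) PCG matrix."""
    rows = {t: [pcg_matrix.rows[t]] for t in pcg_matrix.taxa}
    charsets = list(pcg_matrix.charsets)
    pos = pcg_matrix.column_count
    for aln in rrns:
        for t in pcg_matrix.taxa:
            if t not in aln.rows:
                warnings.warn(f"{aln.gene_name}: taxon {t!r} filled with gaps")
            rows[t].append(aln.rows.get(t, "-" * aln.column_count))
        charsets.append(
            Charset(aln.gene_name, pos + 1, pos + aln.column_count,
                    feature_class=aln.feature_class)
        )
        pos += aln.column_count
    return SuperMatrix(
        pcg_matrix.taxa, {t: "".join(p) for t, p in rows.items()}, charsets
    )


def strip_gap_and_stop_columns(aln: Alignment) -> Alignment:
    """Drop all-gap codon columns and codons that are a stop in any row.

    A permissive pre-filter for raw back-translated alignments; this is a
    simple column stripper, not a GBlocks-style block filter.
    """
    from .codon_analysis import STOP_CODONS

    if aln.feature_class is not FeatureClass.PCG:
        raise ValueError("codon stripping applies to PCG alignments")
    taxa = list(aln.rows)
    keep: list[int] = []
    for c in range(0, aln.column_count, 3):
        codons = [aln.rows[t][c : c + 3] for t in taxa]
        if all(cd == "---" for cd in codons):
            continue
        if any(cd in STOP_CODONS for cd in codons):
            continue
        keep.append(c)
    rows = {
        t: "".join(aln.rows[t][c : c + 3] for c in keep) for t in taxa
    }
    return Alignment(aln.gene_name, aln.feature_class, rows)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_phylip(matrix: SuperMatrix, path: str | Path) -> None:
    """Relaxed PHYLIP (taxon names of any length, space separated)."""
    with open(path, "w") as fh:
        fh.write(f" {len(matrix.taxa)} {matrix.column_count}\n")
        width = max(len(t) for t in matrix.taxa) + 2
        for t in matrix.taxa:
            fh.write(f"{t:<{width}}{matrix.rows[t]}\n")


def write_fasta_matrix(matrix: SuperMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in matrix.taxa:
            fh.write(f">{t}\n{matrix.rows[t]}\n")


def write_nexus(matrix: SuperMatrix, path: str | Path,
                scheme: PartitionScheme | None = None) -> None:
    """NEXUS DATA block plus a SETS block with charsets (and a
    charpartition when a scheme is given)."""
    datatype = "protein" if matrix.alphabet == "amino-acid" else "dna"
    lines = [
        "#NEXUS",
        "begin data;",
        f"  dimensions ntax={len(matrix.taxa)} nchar={matrix.column_count};",
        f"  format datatype={datatype} missing=? gap=-;",
        "  matrix",
    ]
    for t in matrix.taxa:
        safe = t.replace(" ", "_")
        lines.append(f"    {safe}  {matrix.rows[t]}")
    lines += ["  ;", "end;", "", "begin sets;"]
    for cs in matrix.charsets:
        rng = f"{cs.start}-{cs.end}"
        if cs.stride != 1:
            rng += f"\\{cs.stride}"
        lines.append(f"  charset {cs.label} = {rng};")
    if scheme is not None:
        parts = ", ".join(
            f"{name}: {' '.join(labels)}" for name, labels, _ in scheme.subsets
        )
        lines.append(f"  charpartition scheme = {parts};")
    lines += ["end;", ""]
    Path(path).write_text("\n".join(lines))


def write_raxml_partitions(matrix: SuperMatrix, path: str | Path,
                           by_codon: bool = False) -> None:
    """RAxML-style plain-text partition file, by gene or by gene x codon
    position."""
    kind = "WAG" if matrix.alphabet == "amino-acid" else "DNA"
    lines = []
    for cs in matrix.charsets:
        if by_codon and matrix.alphabet == "nucleotide" \
                and cs.feature_class is FeatureClass.PCG:
            for p in range(3):
                lines.append(
                    f"{kind}, {cs.label}_pos{p + 1} = "
                    f"{cs.start + p}-{cs.end}\\3"
                )
        else:
            lines.append(f"{kind}, {cs.label} = {cs.start}-{cs.end}")
    Path(path).write_text("\n".join(lines) + "\n")


def by_codon_position_scheme(matrix: SuperMatrix) -> PartitionScheme:
    """A by-gene-by-codon-position scheme with placeholder models."""
    subsets = []
    for cs in matrix.charsets:
        if cs.feature_class is FeatureClass.PCG \
                and matrix.alphabet == "nucleotide":
            for p in range(3):
                subsets.append(
                    (f"{cs.label}_pos{p + 1}", [cs.label], "GTR+G")
                )
        else:
            subsets.append((cs.label, [cs.label], "GTR+G"))
    return PartitionScheme(subsets)
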