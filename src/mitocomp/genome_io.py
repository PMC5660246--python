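"""Reading, writing and canonicalizing annotated mitochondrial genomes.

The internal data model uses 0-based half-open intervals on the majority
(J) strand; conversion to and from GenBank's 1-based inclusive coordinates
happens only at the I/O boundary.  A feature that spans the origin of the
circular molecule is represented by more than one interval, listed in the
order they are read along the coding walk.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FeatureClass",
    "Strand",
    "GeneFeature",
    "AnnotatedGenome",
    "Alignment",
    "CANONICAL_GENES",
    "TRNA_GENES",
    "PCG_GENES",
    "RRNA_GENES",
    "canonicalize_gene_name",
    "read_genbank",
    "write_genbank",
    "write_fasta",
    "write_feature_table",
    "extract_region",
    "read_alignment",
    "write_alignment_fasta",
    "rotate_genome",
    "ancestral_gene_order",
]


class FeatureClass(str, Enum):
    """Functional class of a mitochondrial gene feature."""

    PCG = "PCG"
    tRNA = "tRNA"
    rRNA = "rRNA"
    CR = "CR"


class Strand(str, Enum):
    """Coding strand: J (majority) or N (minority)."""

    J = "J"
    N = "N"


#: The 13 protein-coding genes of the insect mitogenome.
PCG_GENES: tuple[str, ...] = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
)

#: The 22 tRNA genes, with the two leucine / serine isoacceptors split.
TRNA_GENES: tuple[str, ...] = tuple(
    f"trn{x}" for x in "ACDEFGHIKMNPQRTVWY"
) + ("trnL1", "trnL2", "trnS1", "trnS2")

RRNA_GENES: tuple[str, ...] = ("rrnL", "rrnS")

#: All 37 canonical gene labels (the control region "CR" is tracked separately).
CANONICAL_GENES: tuple[str, ...] = PCG_GENES + TRNA_GENES + RRNA_GENES

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """A single annotated gene on a circular mitogenome.

    ``intervals`` holds 0-based half-open J-strand intervals; more than one
    interval occurs only when the feature wraps the origin.
    """

    canonical_name: str
    feature_class: FeatureClass
    strand: Strand
    intervals: tuple[tuple[int, int], ...]
    inferred: bool = False
    warning: str | None = None

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def start(self) -> int:
        """J-strand start of the first interval (walk order)."""
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        """J-strand end of the last interval (walk order)."""
        return self.intervals[-1][1]

    @property
    def wraps(self) -> bool:
        return len(self.intervals) > 1

    def validate(self, genome_length: int) -> None:
        for s, e in self.intervals:
            if not (0 <= s < e <= genome_length):
                raise ValueError(
                    f"{self.canonical_name}: interval ({s}, {e}) outside "
                    f"genome of length {genome_length}"
                )


@dataclass
class AnnotatedGenome:
    """A circular annotated mitochondrial genome."""

    accession: str
    taxon: str
    sequence: str
    features: list[GeneFeature]
    is_circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        seen: set[str] = set()
        for f in self.features:
            f.validate(len(self.sequence))
            if f.canonical_name in seen and f.canonical_name != "unknown":
                raise ValueError(
                    f"{self.accession}: duplicate gene {f.canonical_name!r}"
                )
            seen.add(f.canonical_name)
        self.features.sort(key=lambda f: f.start)

    def __len__(self) -> int:
        return len(self.sequence)

    def get(self, canonical_name: str) -> GeneFeature:
        for f in self.features:
            if f.canonical_name == canonical_name:
                return f
        raise KeyError(canonical_name)

    def has(self, canonical_name: str) -> bool:
        return any(f.canonical_name == canonical_name for f in self.features)

    def class_features(self, feature_class: FeatureClass) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_class is feature_class]


@dataclass
class Alignment:
    """A per-gene multiple alignment keyed by taxon."""

    gene_name: str
    feature_class: FeatureClass
    rows: dict[str, str]
    column_count: int = field(init=False)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"{self.gene_name}: unequal row lengths {sorted(lengths)}"
            )
        self.column_count = lengths.pop() if lengths else 0
        if self.feature_class is FeatureClass.PCG and self.column_count % 3:
            raise ValueError(
                f"{self.gene_name}: PCG alignment length {self.column_count} "
                "not divisible by 3"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)


# ---------------------------------------------------------------------------
# Name canonicalization
# ---------------------------------------------------------------------------

def _load_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    text = (resources.files("mitocomp.data") / "gene_synonyms.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        syn, canon = line.split("\t")
        table[syn.strip()] = canon.strip()
    return table


_SYNONYMS = _load_synonyms()

_TRNA_RE = re.compile(r"^trna?[-_ ]?([a-z]{3}|[a-z])(\d)?(?:\(([acgut]{3})\))?")


def _squash(name: str) -> str:
    return re.sub(r"[\s\-_()'\".,]", "", name.lower())


def canonicalize_gene_name(raw: str) -> str | None:
    """Map a GenBank gene/product label to its canonical name.

    tRNA labels resolve to ``trnX`` in single-letter code; the leucine and
    serine isoacceptors resolve to trnL1/trnL2/trnS1/trnS2 only when the
    label itself disambiguates them (codon family or trailing digit),
    otherwise plain ``trnL``/``trnS`` is returned for positional
    disambiguation downstream.  Returns None for unmappable labels.
    """
    squashed = _squash(raw)
    if squashed in _SYNONYMS:
        return _SYNONYMS[squashed]
    low = raw.lower().strip()
    m = _TRNA_RE.match(low.replace(" ", ""))
    if m:
        aa, digit, _codon = m.groups()
        one = _AA3_TO_1.get(aa, aa.upper() if len(aa) == 1 else None)
        if one is None:
            return None
        name = f"trn{one}"
        if one in "LS":
            family = _trna_codon_family(raw)
            if family:
                return name + family
            if digit in ("1", "2"):
                return name + digit
            return name  # ambiguous isoacceptor
        return name if name in TRNA_GENES else None
    return None


def _trna_codon_family(raw: str) -> str | None:
    """Resolve L/S isoacceptor number from a codon-family tag in the label."""
    up = raw.upper().replace("T", "U")
    if "CUN" in up:
        return "1"  # trnL1 reads CUN
    if "UUR" in up:
        return "2"  # trnL2 reads UUR
    if "AGN" in up or "AGC" in up or "AGY" in up:
        return "1"  # trnS1 reads AGN
    if "UCN" in up:
        return "2"  # trnS2 reads UCN
    return None


_ANTICODON_TO_ISOACCEPTOR = {
    # anticodon (DNA alphabet) -> canonical isoacceptor
    "TAG": "trnL1", "CAG": "trnL1",
    "TAA": "trnL2",
    "TCT": "trnS1", "GCT": "trnS1",
    "TGA": "trnS2",
}


# ---------------------------------------------------------------------------
# GenBank reading
# ---------------------------------------------------------------------------

def _feature_label(feat: SeqFeature) -> str:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return ""


def _intervals_from_location(loc) -> tuple[tuple[int, int], ...]:
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    return tuple((int(p.start), int(p.end)) for p in parts)


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Read a GenBank flat file into an :class:`AnnotatedGenome`.

    Gene labels are canonicalized through the bundled synonym table;
    ambiguous leucine/serine tRNAs are resolved by anticodon when annotated
    and by position relative to rrnL / nad3 otherwise (flagged inferred).
    Ambiguity codes other than N are mapped to N with a warning.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    if not seq:
        raise ValueError(f"{path}: empty sequence")
    cleaned = re.sub(r"[^ACGTN]", "N", seq)
    if cleaned != seq:
        warnings.warn(f"{record.id}: ambiguity codes mapped to N")
        seq = cleaned

    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "misc_feature", "D-loop"):
            continue
        label = _feature_label(feat)
        if feat.type == "D-loop":
            name: str | None = "CR"
        else:
            name = canonicalize_gene_name(label)
        if feat.type == "misc_feature" and name != "CR":
            continue  # misc_features only carry the control region
        intervals = _intervals_from_location(feat.location)
        strand = Strand.N if feat.location.strand == -1 else Strand.J
        if name is None:
            features.append(
                GeneFeature(
                    "unknown", _class_for(feat.type, "unknown"), strand,
                    intervals, warning=f"unmappable label {label!r}",
                )
            )
            continue
        if name in ("trnL", "trnS"):
            anti = _anticodon_of(feat)
            if anti and anti in _ANTICODON_TO_ISOACCEPTOR:
                resolved = _ANTICODON_TO_ISOACCEPTOR[anti]
                if resolved.startswith(name):
                    name = resolved
        features.append(
            GeneFeature(name, _class_for(feat.type, name), strand, intervals)
        )

    features = _resolve_isoacceptors_by_position(features)
    _check_duplicates(record.id, features)
    return AnnotatedGenome(
        accession=record.id,
        taxon=record.annotations.get("organism", record.description),
        sequence=seq,
        features=features,
        is_circular=record.annotations.get("topology", "circular") == "circular",
    )


def _class_for(gb_type: str, name: str) -> FeatureClass:
    if name == "CR":
        return FeatureClass.CR
    return {
        "CDS": FeatureClass.PCG,
        "tRNA": FeatureClass.tRNA,
        "rRNA": FeatureClass.rRNA,
    }.get(gb_type, FeatureClass.CR)


def _anticodon_of(feat: SeqFeature) -> str | None:
    for key in ("anticodon", "note", "product"):
        for val in feat.qualifiers.get(key, []):
            m = re.search(r"seq\s*:\s*([acgut]{3})", val, re.I)
            if m:
                return m.group(1).upper().replace("U", "T")
    return None


def _resolve_isoacceptors_by_position(
    features: list[GeneFeature],
) -> list[GeneFeature]:
    """Assign trnL1/trnL2 (and trnS1/trnS2) left ambiguous by the labels.

    trnL1 sits beside rrnL and trnS1 beside nad3's downstream tRNA cluster
    in the ancestral arrangement, so proximity to rrnL / nad3 is used as a
    positional fallback; such assignments are flagged ``inferred``.
    """
    out = list(features)
    for base, anchor in (("trnL", "rrnL"), ("trnS", "nad3")):
        idxs = [i for i, f in enumerate(out) if f.canonical_name == base]
        if not idxs:
            continue
        anchor_pos = next(
            (f.start for f in out if f.canonical_name == anchor), None
        )
        taken = {f.canonical_name for f in out}
        free = [n for n in (base + "1", base + "2") if n not in taken]
        if anchor_pos is None or not free:
            continue
        by_dist = sorted(idxs, key=lambda i: abs(out[i].start - anchor_pos))
        for i, name in zip(by_dist, free):
            out[i] = replace(out[i], canonical_name=name, inferred=True)
    return out


def _check_duplicates(accession: str, features: Iterable[GeneFeature]) -> None:
    seen: set[str] = set()
    for f in features:
        if f.canonical_name == "unknown":
            continue
        if f.canonical_name in seen:
            raise ValueError(f"{accession}: duplicate gene {f.canonical_name!r}")
        seen.add(f.canonical_name)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_GB_TYPE = {
    FeatureClass.PCG: "CDS",
    FeatureClass.tRNA: "tRNA",
    FeatureClass.rRNA: "rRNA",
    FeatureClass.CR: "misc_feature",
}


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write an AnnotatedGenome as a GenBank flat file (round-trip safe)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.accession,
        name=genome.accession.split(".")[0][:16],
        description=genome.taxon,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.is_circular else "linear",
            "organism": genome.taxon,
        },
    )
    for f in genome.features:
        strand = -1 if f.strand is Strand.N else 1
        locs = [SimpleLocation(s, e, strand) for s, e in f.intervals]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        qualifiers = {"gene": [f.canonical_name]}
        if f.feature_class is FeatureClass.CR:
            qualifiers["note"] = ["control region"]
        record.features.append(
            SeqFeature(location, type=_GB_TYPE[f.feature_class],
                       qualifiers=qualifiers)
        )
    SeqIO.write(record, str(path), "genbank")


def write_fasta(genome: AnnotatedGenome, path: str | Path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.accession,
                       description=genome.taxon)
    SeqIO.write(record, str(path), "fasta")


def write_feature_table(genome: AnnotatedGenome, path: str | Path) -> None:
    """TSV feature table: accession, gene, class, strand, start, end, length."""
    with open(path, "w", newline="") as fh:
        out = csv.writer(fh, delimiter="\t", lineterminator="\n")
        out.writerow(
            ["accession", "gene", "class", "strand", "start", "end", "length"]
        )
        for f in genome.features:
            out.writerow([
                genome.accession, f.canonical_name, f.feature_class.value,
                f.strand.value, f.start, f.end, f.length,
            ])


# ---------------------------------------------------------------------------
# Region extraction and rotation
# ---------------------------------------------------------------------------

def extract_region(genome: AnnotatedGenome, feature: GeneFeature) -> str:
    """Coding-sense sequence of a feature.

    J-strand features are sliced directly; N-strand features are
    reverse-complemented after concatenating wrap intervals in feature order.
    """
    feature.validate(len(genome.sequence))
    raw = "".join(genome.sequence[s:e] for s, e in feature.intervals)
    return reverse_complement(raw) if feature.strand is Strand.N else raw


def rotate_genome(genome: AnnotatedGenome, offset: int) -> AnnotatedGenome:
    """Rotate the circular origin by ``offset`` bases.

    Feature intervals are re-expressed modulo the genome length; a feature
    cut by the new origin becomes a two-interval (wrapping) feature.
    """
    n = len(genome.sequence)
    offset %= n
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    feats = []
    for f in genome.features:
        intervals: list[tuple[int, int]] = []
        for s, e in f.intervals:
            s2, e2 = (s - offset) % n, (e - offset) % n or n
            if s2 < e2:
                intervals.append((s2, e2))
            else:  # cut by the new origin
                intervals.extend([(s2, n), (0, e2)])
        feats.append(replace(f, intervals=tuple(intervals)))
    return AnnotatedGenome(genome.accession, genome.taxon, seq, feats,
                           genome.is_circular)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_alignment(
    path: str | Path,
    gene_name: str,
    feature_class: FeatureClass = FeatureClass.PCG,
) -> Alignment:
    """Read an aligned FASTA or relaxed PHYLIP file."""
    text = Path(path).read_text()
    fmt = "fasta" if text.lstrip().startswith(">") else "phylip-relaxed"
    aln = AlignIO.read(io.StringIO(text), fmt)
    rows = {rec.id: str(rec.seq).upper() for rec in aln}
    if len(rows) != len(aln):
        raise ValueError(f"{path}: duplicate taxon names")
    return Alignment(gene_name, feature_class, rows)


def write_alignment_fasta(alignment: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=t, description="")
        for t, s in alignment.rows.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Bundled reference order
# ---------------------------------------------------------------------------

def ancestral_gene_order() -> list[tuple[str, Strand]]:
    """The 37-gene ancestral insect arrangement, anchored at trnI."""
    text = (resources.files("mitocomp.data") / "ancestral_order.tsv").read_text()
    entries: list[tuple[str, Strand]] = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gene, strand = line.split("\t")
        entries.append((gene.strip(), Strand(strand.strip())))
    return entries
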