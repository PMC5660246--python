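# Methods

## Data model and coordinates

Genomes are circular; internally every feature interval is 0-based
half-open on the majority (J) strand, and conversion to GenBank's 1-based
inclusive coordinates happens only at the I/O boundary.  A feature that
spans the origin is stored as an ordered list of intervals, so length,
extraction and rotation are exact on the circle.  Gene labels are
canonicalized to the 37 standard names through a bundled, editable synonym
table; the leucine/serine isoacceptors (trnL1/trnL2, trnS1/trnS2) are
resolved by an annotated anticodon or codon-family tag when present, and
otherwise by position relative to rrnL (for trnL1) and nad3 (for trnS1),
flagged as inferred.  Ambiguity codes other than N are mapped to N with a
warning, because the composition statistics are defined over {A,C,G,T}.

## Composition and skews

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C); a zero denominator leaves
the statistic undefined (None), never zero.  Per-region profiles are
computed on the J-strand slice for every region by default — including
genes encoded on the N strand — so that values are comparable across taxa
regardless of which strand carries a gene; a coding-strand mode is
available.  The "PCGs" region is the concatenation of the 13 CDS slices in
genome order with annotated overlaps counted twice, matching how per-region
lengths are usually tabulated.  Codon-position composition pools gene-local
positions (columns 0, 3, 6, … of each codon-framed alignment are first
positions) with gaps excluded.  Percentages are printed to one decimal,
skews to three.

## Codon usage

Translation, stop identification and synonymous-family structure all use
the invertebrate mitochondrial code (transl_table 5): TAA and TAG are the
only stops, so there are 62 sense codons.  Codon counts pool the 13 PCGs
of a genome; start codons are counted as their literal triplet, complete
terminal stops are tallied separately and excluded from the total, and a
CDS whose length is not a multiple of three contributes its trailing 1–2 nt
as an incomplete stop.  RSCU is count over mean family count; a family with
zero usage yields all-zero RSCU and is flagged rather than dividing by
zero.  A `--drop-first-codon` option exists because published RSCU figures
do not always state whether initiation codons were included; the default
includes them.

## Gene order and rearrangement

A gene order is the signed (gene, strand) sequence read along the J strand,
linearized at trnI; re-anchoring is a pure rotation.  Two orders are
compared by their sets of strand-signed circular adjacencies, normalized
for reading direction ((x, y) ≡ (−y, −x)); the breakpoint count is the
number of adjacencies of one order absent from the other, which is
symmetric by circularity and zero exactly when the orders agree up to
rotation.  Runs of consecutive broken adjacencies are reported as
differing blocks.  No inversion/translocation sorting scenario is
reconstructed — the statistic describes the event, not a history.  The
reference arrangement bundled as data is the ancestral insect order of
*Drosophila yakuba*.

## Junctions and the control region

Features sorted by start are walked around the circle; consecutive pairs
overlap (negative gap), abut, or enclose a spacer.  Spacers adjacent to the
control region — or, when the CR is unannotated, the rrnS→trnI span that
holds it — are reported separately and excluded from spacer totals, since
the CR is conventionally tabulated on its own.  `locate_control_region`
prefers annotated coordinates and otherwise takes the unannotated span
from the end of rrnS to the start of trnI, wrapping the origin if needed,
warning when a longer unannotated span exists elsewhere.

## Tandem repeats

Candidate periods are seeded from exact k-mer recurrence distances
(k = 12, reduced to the minimum period for short periods; at least two
concordant seed votes).  For each candidate period p the region is compared
against itself shifted by p, and maximal segments with mean identity above
the threshold are found by a Kadane-style scan on (match − threshold).
Each call is reduced to its fundamental period by testing divisors of p at
the same identity threshold, and overlapping calls are resolved greedily by
identity × copies × period, preferring the smaller period on ties.
Defaults: minimum period 10, minimum copies 1.8, minimum identity 0.80 —
chosen to approximate the defaults of the widely used tandem-repeat finder.
Fractional copies are reported rather than asserting partial-copy
boundaries.  On i.i.d. random 1 kb sequence the detector is empty in ≥95%
of seeded trials; planted repeats with period 20–300, 2–5 copies and ≤5%
per-base noise are recovered with the exact period in ≥95% of trials (both
properties are tested).

## Distances and saturation

p-distance uses pairwise deletion (columns with a gap or N in either row
are excluded).  The GTR distance is the deterministic closed-form
estimator: with F the symmetrized divergence-proportion matrix and Π the
diagonal of its marginals, d = −tr(Π log(Π⁻¹F)), computed in real
arithmetic by eigendecomposition of Π^(1/2-similar) symmetrization; an
eigenvalue ≤ 1e−12 marks the pair saturated and the distance undefined
(returned as a flag, never an exception).  Bases absent from both
sequences are dropped so reduced-alphabet inputs remain defined.  When the
divergence matrix is exactly symmetric with uniform composition the
estimator reduces to the Jukes–Cantor closed form −(3/4)ln(1−4p/3), which
is verified to 1e−6 in tests.  Saturation analysis pools alignment columns
by gene-local codon position (plus an rRNA class), computes all defined
pairwise (GTR, p) points, and fits ordinary least squares of p on GTR with
a free intercept (a through-origin mode exists); slope, Pearson r, mean
GTR distance and the pair counts are reported.  The reading rule is that a
lower slope means more saturation; per-pair ML optimization was
deliberately avoided in favour of the reproducible closed form.

## Nonsynonymous divergence (Ka)

Nei–Gojobori (1986) counting under transl_table 5.  Per codon, each
position contributes one site split by the fraction of its possible
single-base changes that are synonymous, excluding changes that create a
stop; site totals are averaged over the two sequences.  Codon differences
are averaged over all orderings of single-base steps, discarding orderings
that pass through a stop codon (if every ordering is blocked, all are used
with stop-touching steps counted nonsynonymous — a rare fallback).
pn = Nd/N is corrected as ka = −(3/4)ln(1−4pn/3); pn ≥ 3/4 is flagged
undefined.  Ks and Ka/Ks are computed internally but Ka is the surfaced
statistic.  Codons containing gaps, N or stops in either sequence are
skipped.  The implementation is checked against an independent exhaustive
oracle over all sense-codon pairs with ≤2 differences.

## Datasets

Genes are concatenated in canonical genome order (rRNAs last), recorded as
charsets; taxa missing from a gene are gap-filled with a warning.  The five
standard matrices are P123 (all PCG positions), P12 (positions 1+2), P123R
and P12R (rRNAs appended), and AA (codon-wise translation; all-gap codons
become a gap, partially gapped codons X, and an internal stop is an error
naming taxon, gene and codon).  Column identities |P12| = (2/3)|P123|,
|AA| = |P123|/3 and |P123R|−|P123| = |P12R|−|P12| hold by construction and
are property-tested.  Partition files are emitted in RAxML plain text and
NEXUS sets-block dialects with placeholder models; model selection and tree
inference are out of scope.  A permissive utility strips all-gap and stop
codon columns from raw back-translated alignments; it is a simple column
stripper, not a GBlocks-style block filter.

## Synthetic data

The generator realizes a 37-gene circular genome in a specified order
(ancestral by default) with typical insect gene lengths, planted overlaps,
spacers, start/stop codons (incomplete stops shorten the annotation by the
truncated bases), and a control region containing a planted tandem repeat
(partial copy leading, as a suffix of the unit, so the array is
uninterrupted).  Composition control samples bases i.i.d. from frequencies
implied by the A+T% and skew targets, complemented for minority-strand
genes so targets are met on the J strand; because stop-codon rejection in
coding genes biases composition slightly, generation is two-pass — the
realized composition of a first draft is measured and the targets are
reflected about it before the final draw — cancelling the first-order bias
(~1 point hit to within sampling noise, tested at ±1 point at 15 kb and
±0.5 at ~100 kb).  Codon constraints at overlap junctions are written with
priority (conflicting constraints are an error), and an iterative repair
pass resamples unconstrained bases until no CDS carries an internal stop.

Pair/star evolution uses a GTR rate matrix normalized to one expected
substitution per site, an ancestor drawn from the stationary frequencies,
and descendants drawn from exp(Qt) exactly per site; per-codon-position
rate multipliers cycle over sites, and codon mode rejects stop codons in
ancestor and descendants.  All outputs are bit-reproducible from the seed.

What the generator does **not** emulate: real protein sequences (CDS bodies
are random stop-free codons), indels (simulated alignments are gap-free),
tRNA/rRNA secondary structure, within-genome rate heterogeneity beyond the
cyclic multipliers, and sequencing error.  Passing tests therefore show
that the statistics and estimators are computed correctly and recover known
truth under their own model assumptions — not that the biological
conclusions of any particular dataset are correct.

## Problem sizes and defaults used in tests

The default synthetic genome is ~15.4 kb (typical of leafhopper
mitogenomes), A+T target 78%, AT skew +0.05, GC skew −0.20, control region
908 bp with a 239 bp repeat at 2.75 copies, overlaps atp8–atp6 7 bp,
nad4–nad4l 7 bp, trnW–trnC 8 bp, and a leafhopper-like start/stop pattern
(nad5 TTG/TAG; cox2 and nad1 incomplete T).  Branch-length recovery is
exercised at 10 kb over t ∈ [0.05, 0.5] (median relative error < 5%);
the dominance check GTR ≥ p runs on 1000 pairs of 500 bp; saturation
ordering uses six taxa on a star tree with third positions 5× faster.
Accession-based checks (genome statistics and saturation slopes of the
published records) require the GenBank records under `data/accessions/`
(see `scripts/fetch_accessions.py`) and fail with a clear message when the
records are absent; everything else is self-contained and seeded.
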