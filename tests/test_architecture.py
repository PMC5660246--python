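"""Gene order, breakpoints, junctions, control region, tandem repeats."""

import itertools

import numpy as np
import pytest

from mitocomp.architecture import (
    GeneOrder,
    RepeatConfig,
    ancestral_order,
    compare_orders,
    find_tandem_repeats,
    gene_order,
    junctions,
    locate_control_region,
)
from mitocomp.genome_io import (
    AnnotatedGenome,
    FeatureClass,
    GeneFeature,
    Strand,
    extract_region,
)
from mitocomp.synthetic_data import CRSpec, GenomeSpec, generate_genome


# ---------------------------------------------------------------------------
# Gene order
# ---------------------------------------------------------------------------

def test_gene_order_of_default_genome_is_ancestral(default_genome):
    genome, _ = default_genome
    assert gene_order(genome).entries == ancestral_order().entries


def test_reanchoring_is_a_rotation(default_genome):
    genome, _ = default_genome
    o1 = gene_order(genome, "cox1")
    o2 = o1.rotated("trnI")
    assert o2.entries == gene_order(genome).entries
    assert sorted(o1.entries) == sorted(o2.entries)


def test_missing_anchor_lists_available_genes(default_genome):
    genome, _ = default_genome
    with pytest.raises(ValueError, match="trnI"):
        gene_order(genome, "nonexistent")


def test_identical_orders_have_zero_breakpoints():
    ref = ancestral_order()
    rep = compare_orders(ref, ancestral_order("cox1"))
    assert rep.breakpoint_count == 0
    assert rep.differing_blocks == []


def test_wcy_cluster_rearrangement_breakpoints(rearranged_genome):
    """Permuting trnW-trnC-trnY to trnY-trnW-trnC breaks three adjacencies
    and keeps (trnW, trnC)."""
    genome, _ = rearranged_genome
    rep = compare_orders(gene_order(genome), ancestral_order())
    assert rep.breakpoint_count == 3
    # the trnW-trnC adjacency survives (stored orientation-normalized)
    assert ("trnW", "-trnC") in rep.shared_adjacencies or (
        "trnC", "-trnW",
    ) in rep.shared_adjacencies
    rearranged = {g for _, obs in rep.differing_blocks for g in obs}
    assert {"trnW", "trnC", "trnY"} <= rearranged


def test_compare_orders_symmetric_and_rotation_invariant(rearranged_genome):
    genome, _ = rearranged_genome
    obs = gene_order(genome)
    ref = ancestral_order()
    forward = compare_orders(obs, ref).breakpoint_count
    assert compare_orders(ref, obs).breakpoint_count == forward
    assert compare_orders(obs.rotated("cox3"), ref).breakpoint_count == forward


def _brute_force_breakpoints(perm_a, perm_b):
    """Oracle: count signed circular adjacencies of A absent from B,
    enumerating consecutive pairs directly (both reading directions)."""

    def adjacencies(perm):
        n = len(perm)
        out = set()
        for i in range(n):
            (ga, sa), (gb, sb) = perm[i], perm[(i + 1) % n]
            out.add((ga, sa, gb, sb))
        # reading the other strand reverses order and flips strands
        flip = {"J": "N", "N": "J"}
        for ga, sa, gb, sb in list(out):
            out.add((gb, flip[sb], ga, flip[sa]))
        return out

    a, b = adjacencies(perm_a), adjacencies(perm_b)
    return len(a - b) // 2  # each adjacency counted in both directions


def test_breakpoints_match_brute_force_oracle_on_random_permutations():
    rng = np.random.default_rng(17)
    genes = [f"g{i}" for i in range(10)]
    for _ in range(50):
        perm = [
            (g, Strand.J if rng.random() < 0.7 else Strand.N)
            for g in rng.permutation(genes)
        ]
        ref = [(g, Strand.J) for g in genes]
        rep = compare_orders(
            GeneOrder(perm[0][0], tuple(perm)),
            GeneOrder("g0", tuple(ref)),
        )
        assert rep.breakpoint_count == _brute_force_breakpoints(perm, ref)
        assert rep.breakpoint_count <= len(genes)


def test_disjoint_gene_sets_error():
    a = GeneOrder("x", (("x", Strand.J), ("y", Strand.J)))
    b = GeneOrder("p", (("p", Strand.J), ("q", Strand.J)))
    with pytest.raises(ValueError):
        compare_orders(a, b)


# ---------------------------------------------------------------------------
# Junctions
# ---------------------------------------------------------------------------

def test_overlap_of_two_features():
    g = AnnotatedGenome(
        "X", "toy", "A" * 25,
        [
            GeneFeature("trnI", FeatureClass.tRNA, Strand.J, ((0, 10),)),
            GeneFeature("trnM", FeatureClass.tRNA, Strand.J, ((7, 20),)),
        ],
    )
    rep = junctions(g)
    assert rep.overlap("trnI", "trnM") == 3
    # circular wrap spacer trnM -> trnI: 25-20 + 0 = 5
    assert rep.totals["spacer_bp"] == 5


def test_junctions_report_planted_overlaps(default_genome):
    genome, truth = default_genome
    rep = junctions(genome)
    for a, b, k in truth["overlaps"]:
        assert rep.overlap(a, b) == k
    assert rep.totals["overlap_junctions"] == len(truth["overlaps"])
    assert rep.totals["overlap_bp"] == sum(k for _, _, k in truth["overlaps"])


def test_longest_spacer_at_rearranged_cluster(rearranged_genome):
    """The spacer planted between the rearranged tRNAs is the longest, and
    the control region never enters spacer totals."""
    genome, truth = rearranged_genome
    rep = junctions(genome)
    assert all("CR" not in (j.gene_a, j.gene_b) for j in rep.spacers)
    longest = rep.longest_spacer
    assert (longest.gene_a, longest.gene_b, longest.length) == (
        "trnY", "trnW", 73,
    )
    assert rep.totals["spacer_bp"] == 73


def test_architecture_bookkeeping_conservation(default_genome):
    """Spacers + overlap-corrected feature span + CR tile the circle."""
    genome, truth = default_genome
    rep = junctions(genome)
    feature_bp = sum(
        f.length for f in genome.features
        if f.feature_class is not FeatureClass.CR
    )
    cr_bp = locate_control_region(genome).length
    total = (
        feature_bp
        - rep.totals["overlap_bp"]
        + rep.totals["spacer_bp"]
        + cr_bp
    )
    assert total == len(genome)


# ---------------------------------------------------------------------------
# Control region
# ---------------------------------------------------------------------------

def test_annotated_control_region_is_preferred(default_genome):
    genome, truth = default_genome
    cr = locate_control_region(genome)
    assert not cr.inferred  # annotated coordinates win over inference
    assert cr.start == truth["control_region"]["cr_start"]
    assert cr.length == 908


def test_control_region_inferred_between_rrns_and_trni():
    spec = GenomeSpec(
        seed=21, annotate_cr=False,
        cr_spec=CRSpec(length=500, period=80, copies=3.0),
    )
    genome, truth = generate_genome(spec)
    cr = locate_control_region(genome)
    assert cr.inferred
    assert cr.length == 500
    assert cr.start == genome.get("rrnS").end


def test_control_region_wraps_origin_when_rotated():
    spec = GenomeSpec(seed=22, annotate_cr=False)
    genome, _ = generate_genome(spec)
    # rotate the origin into the middle of the CR span
    from mitocomp.genome_io import rotate_genome

    cr0 = locate_control_region(genome)
    rotated = rotate_genome(genome, cr0.start + 200)
    cr = locate_control_region(rotated)
    assert cr.wraps
    assert cr.length == cr0.length
    assert extract_region(rotated, cr) == extract_region(genome, cr0)


def test_zero_span_is_error():
    g = AnnotatedGenome(
        "X", "toy", "A" * 40,
        [
            GeneFeature("rrnS", FeatureClass.rRNA, Strand.N, ((0, 20),)),
            GeneFeature("trnI", FeatureClass.tRNA, Strand.J, ((20, 40),)),
        ],
    )
    with pytest.raises(ValueError):
        locate_control_region(g)


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

def test_perfect_short_repeat():
    reps = find_tandem_repeats(
        "ACGTACGTACGT", RepeatConfig(min_period=4)
    )
    assert len(reps) == 1
    assert (reps[0].period, reps[0].copies, reps[0].identity) == (4, 3.0, 1.0)
    assert reps[0].consensus == "ACGT"


def test_planted_cr_repeat_is_recovered(default_genome):
    genome, truth = default_genome
    cr = locate_control_region(genome)
    region = extract_region(genome, cr)
    reps = find_tandem_repeats(region)
    assert reps, "planted repeat not detected"
    best = max(reps, key=lambda r: r.score)
    assert best.period == truth["control_region"]["period"]
    assert best.copies == pytest.approx(
        truth["control_region"]["copies"], abs=0.15
    )
    assert best.identity >= 0.9


def test_repeat_recovery_rate_on_planted_arrays():
    """>= 95% of planted repeats (period 20-300, copies 2-5, <= 5% noise)
    are recovered with the exact period."""
    rng = np.random.default_rng(99)
    hits = 0
    n_trials = 100
    for _ in range(n_trials):
        period = int(rng.integers(20, 301))
        copies = float(rng.uniform(2.0, 5.0))
        noise = float(rng.uniform(0.0, 0.05))
        unit = "".join(rng.choice(list("ACGT"), period))
        total = int(period * copies)
        array = (unit * (int(copies) + 1))[:total]
        chars = list(array)
        for i in range(len(chars)):
            if rng.random() < noise:
                chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
        flank = lambda n: "".join(rng.choice(list("ACGT"), n))
        region = flank(100) + "".join(chars) + flank(100)
        reps = find_tandem_repeats(region)
        if any(r.period == period for r in reps):
            hits += 1
    assert hits >= 95


def test_false_positive_rate_on_random_sequence():
    """Random 1 kb sequences yield no calls in >= 95% of seeded trials."""
    empty = 0
    for seed in range(100):
        rng = np.random.default_rng(1000 + seed)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        if not find_tandem_repeats(seq):
            empty += 1
    assert empty >= 95


def test_short_region_returns_empty():
    assert find_tandem_repeats("ACGTACG", RepeatConfig(min_period=10)) == []
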