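"""Shared fixtures: seeded synthetic genomes and alignments.

All fixtures are deterministic; session scope keeps genome generation out
of per-test cost.
"""

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mitocomp.genome_io import Alignment, FeatureClass, ancestral_gene_order
from mitocomp.synthetic_data import (
    EvolModel,
    GenomeSpec,
    evolve_star,
    generate_genome,
)


@pytest.fixture(scope="session")
def default_genome():
    """Ancestral-order synthetic genome with the default planted layout."""
    genome, truth = generate_genome(GenomeSpec(seed=11))
    return genome, truth


@pytest.fixture(scope="session")
def rearranged_genome():
    """Synthetic genome with the trnW-trnC-trnY cluster permuted to
    trnY-trnW-trnC (overlaps dropped, since trnW/trnC are separated)."""
    order = ancestral_gene_order()
    names = [g for g, _ in order]
    i = names.index("trnW")
    w, c, y = order[i : i + 3]
    permuted = order[:i] + [y, w, c] + order[i + 3 :]
    spec = GenomeSpec(
        seed=12,
        gene_order=permuted,
        overlap_spec=(("atp8", "atp6", 7), ("nad4", "nad4l", 7)),
        spacer_spec=(("trnY", "trnW", 73),),
        accession="SYNREARR",
    )
    genome, truth = generate_genome(spec)
    return genome, truth


@pytest.fixture(scope="session")
def star_alignments():
    """Per-gene codon alignments of 6 taxa from a star tree, with fast
    third positions, plus two rRNA alignments."""
    branch_lengths = {f"taxon{i}": 0.03 + 0.05 * i for i in range(6)}
    pcgs = []
    for i, gene in enumerate(("cox1", "cox2", "nad2")):
        rows, _ = evolve_star(
            400,
            EvolModel(site_rate_classes=(1, 1, 5), seed=200 + i),
            branch_lengths,
            codon_mode=True,
        )
        pcgs.append(Alignment(gene, FeatureClass.PCG, rows))
    rrns = []
    for i, gene in enumerate(("rrnL", "rrnS")):
        rows, _ = evolve_star(
            600, EvolModel(seed=300 + i), branch_lengths
        )
        rrns.append(Alignment(gene, FeatureClass.rRNA, rows))
    return pcgs, rrns
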