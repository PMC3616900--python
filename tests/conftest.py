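"""Shared fixtures: hand-built micro-genomes and seeded synthetic worlds.

Session-scoped fixtures carry the expensive artifacts (generated genome
collections, ortholog clusterings, one full benchmark run) so unit tests
and end-to-end checks share them instead of regenerating.
"""

from __future__ import annotations

import pytest

from regulonkit.genomes import Gene, Genome, GenomeSet
from regulonkit.orthology import build_ortholog_groups
from regulonkit.regulons import prepare_regions
from regulonkit.synthetic import RegulonSpec, SyntheticConfig, generate


def make_gene(gid, start, end, strand="+", replicon="chr", protein="M" * 50, **kw):
    return Gene(id=gid, replicon=replicon, start=start, end=end, strand=strand,
                protein=protein, **kw)


@pytest.fixture
def toy_genome():
    """Three + strand genes on one 5 kb replicon, with gaps 50 and 400."""
    seq = "ACGT" * 1250
    genes = [
        make_gene("g1", 1001, 2000),
        make_gene("g2", 2051, 2550),  # gap 50 to g1
        make_gene("g3", 2951, 3450),  # gap 400 to g2
    ]
    return Genome(id="toy", lineage="A", sequences={"chr": seq}, genes=genes)


@pytest.fixture(scope="session")
def ortho_world():
    """5 genomes x 30 single-copy families at 60% within-family identity."""
    config = SyntheticConfig(
        lineages={"a": 5}, n_families=30, family_presence=1.0,
        within_family_identity=0.60, regulons=[], seed=7,
    )
    genome_set, truth = generate(config, 7)
    groups, hits = build_ortholog_groups(genome_set)
    return {"genome_set": genome_set, "truth": truth, "groups": groups, "hits": hits}


@pytest.fixture(scope="session")
def mini_world():
    """6 genomes, 2 planted regulons with a cascade: the small end-to-end
    world for workflow and network-analysis tests."""
    config = SyntheticConfig(
        lineages={"a": 6},
        n_families=40,
        regulons=[
            RegulonSpec(name="R1", n_member_operons=5, presence_prob=0.9),
            RegulonSpec(name="R2", n_member_operons=4, presence_prob=0.9),
        ],
        decoy_rate=0.5,
        cascades=[("R1", "R2")],
        seed=11,
    )
    genome_set, truth = generate(config, 11)
    index = prepare_regions(genome_set)
    groups, hits = build_ortholog_groups(genome_set)
    return {
        "config": config, "genome_set": genome_set, "truth": truth,
        "index": index, "groups": groups,
    }


@pytest.fixture(scope="session")
def bench1():
    """One full run of the standard recovery benchmark (seed 1)."""
    from regulonkit.benchmark import run_regulon_benchmark

    return run_regulon_benchmark(1)
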