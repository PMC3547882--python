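"""Shared fixtures: tiny hand-built inputs and small cached synthetic worlds."""

from __future__ import annotations

import pytest

from linkmark.data_io import Gene, GenomeTable, OrthologEntry, OrthologMap, PathwayAnnotation
from linkmark.synthetic_data import WorldConfig, generate_world


def make_genome(genome_id: str, rows: list[tuple[str, int, int, str]],
                length_bp: int | None = None) -> GenomeTable:
    """Build a GenomeTable from (gene_id, start, end, strand) rows."""
    rows = sorted(rows, key=lambda r: (r[1], r[0]))
    genes = [Gene(gid, start, end, strand, rank)
             for rank, (gid, start, end, strand) in enumerate(rows)]
    if length_bp is None:
        length_bp = max(end for _, _, end, _ in rows) + 500
    return GenomeTable(genome_id=genome_id, length_bp=length_bp, genes=genes)


def make_omap(assignments: dict[str, dict[str, str]],
              counts: dict[str, int] | None = None,
              bit: float = 100.0, self_bit: float = 200.0) -> OrthologMap:
    """OrthologMap from {query: {genome: ortholog_gene_id}}."""
    entries = {
        query: {genome: OrthologEntry(gene_id, bit, self_bit)
                for genome, gene_id in per_genome.items()}
        for query, per_genome in assignments.items()
    }
    if counts is None:
        genomes = {g for per_genome in assignments.values() for g in per_genome}
        counts = {g: 100 for g in genomes}
    return OrthologMap(entries=entries, genome_protein_counts=counts)


def make_annotation(rows: list[tuple[str, str, str]]) -> PathwayAnnotation:
    memberships: dict[str, set] = {}
    for protein, level2, level3 in rows:
        memberships.setdefault(protein, set()).add((level2, level3))
    return PathwayAnnotation(memberships={p: frozenset(s) for p, s in memberships.items()})


SMALL_WORLD_CONFIG = WorldConfig(
    seed=7, n_genomes=25, n_proteins=60, n_categories=3,
    pathways_per_category=2, proteins_per_pathway=8, n_conditions=60,
    co_inheritance=0.9, operon_prob=0.9, coexpression=0.9, coevolution=0.9,
)


@pytest.fixture(scope="session")
def small_world():
    """A small fully-signalled world, generated once per session."""
    return generate_world(SMALL_WORLD_CONFIG)


@pytest.fixture(scope="session")
def null_world():
    """A small world with every signal knob at 0."""
    cfg = WorldConfig(seed=11, n_genomes=25, n_proteins=60, n_categories=3,
                      pathways_per_category=2, proteins_per_pathway=8, n_conditions=60)
    return generate_world(cfg)
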