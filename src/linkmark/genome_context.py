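"""Gene Neighbor (GN) and Gene Cluster (GC) scorers.

Both methods read chromosomal gene order in a set of reference genomes
through the ortholog map.  GN turns the minimum circular gene-rank distance
over any one reference genome into a similarity; GC estimates the
probability that the two orthologs are encoded from the same co-directional
gene cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .data_io import GenomeTable, OrthologMap, PairScoreTable, pair_key

logger = logging.getLogger("linkmark")


def gene_rank_distance(rank_a: int, rank_b: int, genome_size: int) -> int:
    """Minimum number of gene steps between two ranks on a circular chromosome.

    Equals ``min(|a-b|, G-|a-b|)`` and lies in ``[1, G//2]``.  Equal ranks are
    an error: two distinct proteins mapping to the same gene have no defined
    distance and the pair must be treated as undefined upstream.
    """
    G = genome_size
    if G < 2:
        raise ValueError("genome_size must be >= 2")
    if not (0 <= rank_a < G and 0 <= rank_b < G):
        raise ValueError(f"ranks ({rank_a},{rank_b}) out of range for G={G}")
    if rank_a == rank_b:
        raise ValueError("self-distance undefined for equal ranks")
    d = abs(rank_a - rank_b)
    return min(d, G - d)


def _resolve_rank(table: GenomeTable, rank_of: dict[str, int], gene_id: str, protein: str) -> int:
    try:
        return rank_of[gene_id]
    except KeyError:
        raise KeyError(
            f"ortholog gene {gene_id!r} of {protein!r} absent from genome table "
            f"{table.genome_id!r}") from None


def gn_scores(pairs: Iterable[tuple[str, str]], ortholog_map: OrthologMap,
              genomes: Sequence[GenomeTable]) -> PairScoreTable:
    """Gene Neighbor similarity for each pair.

    For every reference genome where both orthologs exist, the circular
    gene-rank distance is normalized by ``G//2`` to (0,1]; the score is one
    minus the minimum normalized distance over genomes.  Pairs never
    co-present in any reference genome score 0 and are flagged undefined.
    """
    table = PairScoreTable(method="GN")
    rank_maps = [(g, g.rank_of()) for g in genomes]
    for a, b in (pair_key(*p) for p in pairs):
        best: float | None = None
        for genome, rank_of in rank_maps:
            ea = ortholog_map.get(a, genome.genome_id)
            eb = ortholog_map.get(b, genome.genome_id)
            if ea is None or eb is None:
                continue
            ra = _resolve_rank(genome, rank_of, ea.ortholog_gene_id, a)
            rb = _resolve_rank(genome, rank_of, eb.ortholog_gene_id, b)
            if ra == rb:
                logger.info("pair (%s,%s): orthologs share gene %s in %s; genome skipped",
                            a, b, ea.ortholog_gene_id, genome.genome_id)
                continue
            d = gene_rank_distance(ra, rb, genome.size) / (genome.size // 2)
            best = d if best is None else min(best, d)
        if best is None:
            table.set(a, b, 0.0, undefined=True)
        else:
            table.set(a, b, 1.0 - best)
    return table


@dataclass
class GeneCluster:
    """Maximal run of co-directional genes with small intergenic gaps."""

    genome_id: str
    strand: str
    member_gene_ids: list[str]
    span: tuple[int, int]


def _gap(prev_end: int, next_start: int) -> int:
    # overlapping genes (negative gap) count as gap 0
    return max(0, next_start - prev_end - 1)


def detect_gene_clusters(genome: GenomeTable, max_gap: int = 100) -> list[GeneCluster]:
    """Partition a circular genome's genes into maximal co-directional clusters.

    Consecutive genes join a cluster when they share strand and their
    intergenic gap (``next.start - prev.end - 1``, clipped at 0) is at most
    ``max_gap`` (inclusive).  The wrap-around junction between the last and
    first gene is evaluated too; a merge across the origin is logged.
    """
    genes = genome.genes
    if not genes:
        return []
    runs: list[list[int]] = [[0]]
    for i in range(1, len(genes)):
        prev, cur = genes[i - 1], genes[i]
        if cur.strand == prev.strand and _gap(prev.end, cur.start) <= max_gap:
            runs[-1].append(i)
        else:
            runs.append([i])
    if len(runs) > 1:
        first, last = genes[0], genes[-1]
        wrap_gap = _gap(last.end, genome.length_bp + first.start)
        if first.strand == last.strand and wrap_gap <= max_gap:
            logger.info("%s: wrap-around cluster merge across the origin", genome.genome_id)
            runs[0] = runs.pop() + runs[0]
    clusters = []
    for run in runs:
        members = [genes[i] for i in run]
        clusters.append(GeneCluster(
            genome_id=genome.genome_id,
            strand=members[0].strand,
            member_gene_ids=[g.gene_id for g in members],
            span=(members[0].start, members[-1].end),
        ))
    return clusters


def cluster_index(genome: GenomeTable, max_gap: int = 100) -> dict[str, int]:
    """gene_id → cluster ordinal, from :func:`detect_gene_clusters`."""
    idx: dict[str, int] = {}
    for ci, cluster in enumerate(detect_gene_clusters(genome, max_gap)):
        for gid in cluster.member_gene_ids:
            idx[gid] = ci
    return idx


def gc_scores(pairs: Iterable[tuple[str, str]], ortholog_map: OrthologMap,
              genomes: Sequence[GenomeTable], max_gap: int = 100) -> PairScoreTable:
    """Gene Cluster co-occurrence probability for each pair.

    score = (# reference genomes where both orthologs lie in the same
    cluster) / (# reference genomes where both orthologs are present).
    Pairs never co-present score 0 and are flagged undefined.
    """
    table = PairScoreTable(method="GC")
    indexed = [(g, g.rank_of(), cluster_index(g, max_gap)) for g in genomes]
    for a, b in (pair_key(*p) for p in pairs):
        n_present = 0
        n_same = 0
        for genome, rank_of, cidx in indexed:
            ea = ortholog_map.get(a, genome.genome_id)
            eb = ortholog_map.get(b, genome.genome_id)
            if ea is None or eb is None:
                continue
            ga = ea.ortholog_gene_id
            gb = eb.ortholog_gene_id
            _resolve_rank(genome, rank_of, ga, a)
            _resolve_rank(genome, rank_of, gb, b)
            n_present += 1
            if cidx[ga] == cidx[gb]:
                n_same += 1
        if n_present == 0:
            table.set(a, b, 0.0, undefined=True)
        else:
            table.set(a, b, n_same / n_present)
    return table
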