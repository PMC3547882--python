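"""Phylogenetic Profiling (PP) scorer.

Builds a proteins × reference-genomes matrix of ortholog bit scores,
normalizes it for protein and species divergence, and scores pairs by the
Pearson correlation of their profile rows.  A dereplication step collapses
near-identical reference genomes before the matrix is built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .data_io import OrthologMap, PairScoreTable, pair_key

logger = logging.getLogger("linkmark")


@dataclass
class ProfileMatrix:
    """proteins × genomes non-negative matrix; 0 exactly where no ortholog."""

    protein_ids: list[str]
    genome_ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.genome_ids)):
            raise ValueError("values shape does not match id lists")
        if (self.values < 0).any() or not np.isfinite(self.values).all():
            raise ValueError("profile values must be finite and >= 0")

    def row(self, protein_id: str) -> np.ndarray:
        return self.values[self.protein_ids.index(protein_id)]


def select_reference_genomes(ortholog_map: OrthologMap, query_protein_ids: Sequence[str],
                             overlap_threshold: float = 0.90) -> list[str]:
    """Collapse clusters of genomes sharing more than ``overlap_threshold``
    of their query orthologs down to one representative each.

    Two genomes are linked when ``|S1 ∩ S2| / min(|S1|, |S2|)`` exceeds the
    threshold, where ``Si`` is the set of query proteins with an ortholog in
    genome i.  Single-linkage connected components are each represented by
    the genome with the largest ortholog set (ties broken lexicographically).
    Returns representatives sorted by genome id.
    """
    queries = set(query_protein_ids)
    genomes = ortholog_map.genomes()
    sets = {g: ortholog_map.ortholog_set(g) & queries for g in genomes}
    graph = nx.Graph()
    graph.add_nodes_from(genomes)
    for i, g1 in enumerate(genomes):
        for g2 in genomes[i + 1:]:
            denom = min(len(sets[g1]), len(sets[g2]))
            if denom == 0:
                continue
            if len(sets[g1] & sets[g2]) / denom > overlap_threshold:
                graph.add_edge(g1, g2)
    reps = []
    for component in nx.connected_components(graph):
        reps.append(min(component, key=lambda g: (-len(sets[g]), g)))
    return sorted(reps)


def build_profile_matrix(ortholog_map: OrthologMap, query_protein_ids: Sequence[str],
                         genome_ids: Sequence[str]) -> ProfileMatrix:
    """Raw profile matrix: cell (i,j) = ortholog bit score, or 0 if absent."""
    unknown = [g for g in genome_ids if g not in ortholog_map.genome_protein_counts]
    if unknown:
        raise KeyError(f"genomes not in ortholog map: {unknown}")
    values = np.zeros((len(query_protein_ids), len(genome_ids)))
    for i, protein in enumerate(query_protein_ids):
        per_genome = ortholog_map.entries.get(protein)
        if per_genome is None:
            logger.warning("query protein %s unknown to ortholog map; zero profile row", protein)
            continue
        for j, genome in enumerate(genome_ids):
            entry = per_genome.get(genome)
            if entry is not None:
                values[i, j] = entry.bit_score
    return ProfileMatrix(list(query_protein_ids), list(genome_ids), values, normalized=False)


def normalize_profile_matrix(matrix: ProfileMatrix, ortholog_map: OrthologMap) -> ProfileMatrix:
    """Normalize a raw profile matrix for protein and species divergence.

    Step 1 (protein divergence): each nonzero cell is divided by the query
    protein's self-alignment bit score.  Step 2 (species divergence): each
    column is divided by the mean of its nonzero entries; all-zero columns
    stay zero.  Zeros (absent orthologs) are preserved throughout.
    """
    if matrix.normalized:
        raise ValueError("matrix already normalized")
    values = matrix.values.copy()
    for i, protein in enumerate(matrix.protein_ids):
        per_genome = ortholog_map.entries.get(protein, {})
        for j, genome in enumerate(matrix.genome_ids):
            if values[i, j] == 0:
                continue
            entry = per_genome.get(genome)
            if entry is None:
                raise ValueError(f"no self bit score for nonzero cell ({protein},{genome})")
            values[i, j] /= entry.self_bit_score
    nonzero = values != 0
    col_counts = nonzero.sum(axis=0)
    with np.errstate(invalid="ignore"):
        col_means = np.where(col_counts > 0, values.sum(axis=0) / np.maximum(col_counts, 1), 1.0)
    values = values / col_means
    return ProfileMatrix(matrix.protein_ids, matrix.genome_ids, values, normalized=True)


def pp_scores(pairs: Iterable[tuple[str, str]], matrix: ProfileMatrix) -> PairScoreTable:
    """Pearson correlation of normalized profile rows, clamped below at 0.

    The full row vectors (zeros included) are correlated.  Pairs where either
    profile has zero variance are undefined and score 0.
    """
    if not matrix.normalized:
        raise ValueError("pp_scores requires a normalized ProfileMatrix")
    index = {p: i for i, p in enumerate(matrix.protein_ids)}
    X = matrix.values
    n = X.shape[1]
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    table = PairScoreTable(method="PP")
    n_clamped = 0
    for a, b in (pair_key(*p) for p in pairs):
        try:
            ia, ib = index[a], index[b]
        except KeyError as exc:
            raise KeyError(f"protein {exc.args[0]!r} absent from profile matrix") from None
        if norms[ia] == 0 or norms[ib] == 0 or n < 2:
            table.set(a, b, 0.0, undefined=True)
            continue
        r = float(centered[ia] @ centered[ib] / (norms[ia] * norms[ib]))
        r = min(1.0, r)
        if r < 0:
            n_clamped += 1
            r = 0.0
        table.set(a, b, r)
    if n_clamped:
        table.metadata["clamped_negative"] = str(n_clamped)
    return table
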