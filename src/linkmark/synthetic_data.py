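"""Synthetic comparative-genomics worlds with controllable linkage signal.

Generates every input the five scorers consume — reference genome tables, an
RBH-style ortholog map with bit scores, an expression compendium, per-protein
inter-species distance matrices with shared-ortholog genome counts, and a
two-level pathway annotation — plus ground-truth linked pairs.  Four
independent signal knobs (co_inheritance, operon_prob, coexpression,
coevolution) inject the statistical structure each scorer assumes, so each
method's recovery can be attributed to its own channel; with all knobs at 0
every scorer sees pure noise.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import yaml
from dendropy.simulate import treesim

from .data_io import (
    ExpressionMatrix,
    Gene,
    GenomeTable,
    OrthologEntry,
    OrthologMap,
    PathwayAnnotation,
    config_hash,
    pair_key,
    standard_header,
    write_expression_matrix,
    write_genome_table,
    write_ortholog_map,
    write_pathway_annotations,
)
from .mirrortree_gm import DistanceMatrix, write_distance_matrix
from .pathway_benchmark import build_global_gold

__all__ = [
    "WorldConfig", "SyntheticWorld", "generate_world", "export_world",
    "simulate_species_tree", "simulate_presence_profiles", "simulate_gene_orders",
    "simulate_expression", "simulate_distance_matrices",
]

_PROBS = ("co_inheritance", "operon_prob", "coexpression", "coevolution", "profile_flip_rate")


@dataclass(frozen=True)
class WorldConfig:
    """All knobs of one synthetic world; the seed is mandatory."""

    seed: int
    n_genomes: int = 60
    n_proteins: int = 200
    n_categories: int = 4
    pathways_per_category: int = 3
    proteins_per_pathway: int = 16
    n_conditions: int = 380
    co_inheritance: float = 0.0
    operon_prob: float = 0.0
    coexpression: float = 0.0
    coevolution: float = 0.0
    profile_flip_rate: float = 0.05
    expr_sigma: float = 0.3
    dist_sigma: float = 0.05
    coevolution_residual_sd: float = 0.5

    def __post_init__(self) -> None:
        for name in _PROBS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        for name in ("n_genomes", "n_proteins", "n_categories", "pathways_per_category",
                     "proteins_per_pathway", "n_conditions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_annotated > self.n_proteins:
            raise ValueError("pathway layout requires more proteins than n_proteins")
        if self.n_genomes < 3:
            raise ValueError("need at least 3 genomes")

    @property
    def n_pathways(self) -> int:
        return self.n_categories * self.pathways_per_category

    @property
    def n_annotated(self) -> int:
        return self.n_pathways * self.proteins_per_pathway

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, payload: dict) -> "WorldConfig":
        return cls(**payload)

    def hash(self) -> str:
        return config_hash(self.to_dict())


@dataclass
class SyntheticWorld:
    """One generated world: all scorer inputs plus ground-truth linkage."""

    config: WorldConfig
    species_ids: list[str]
    tree_newick: str
    tree_distances: np.ndarray          # normalized patristic distances, max 1
    protein_ids: list[str]
    assignments: dict[str, tuple[str, str] | None]
    presence: np.ndarray                # proteins × genomes, bool
    genome_tables: dict[str, GenomeTable]
    ortholog_map: OrthologMap
    expression: ExpressionMatrix
    distance_matrices: dict[str, DistanceMatrix]
    genome_shared_counts: dict[tuple[str, str], int]
    annotation: PathwayAnnotation
    truth: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def annotated_proteins(self) -> list[str]:
        return self.annotation.proteins()

    def pair_universe(self) -> list[tuple[str, str]]:
        """All unordered pairs of annotated proteins (the evaluation universe)."""
        proteins = self.annotated_proteins()
        return [(a, b) for i, a in enumerate(proteins) for b in proteins[i + 1:]]


# ---------------------------------------------------------------------------
# stage simulators
# ---------------------------------------------------------------------------

def simulate_species_tree(n_genomes: int, seed: int) -> tuple[str, list[str], np.ndarray]:
    """Pure-birth ultrametric species tree; returns (newick, tip ids, patristic matrix).

    Deterministic under ``seed``; branch lengths are exponential waiting
    times of a birth rate-1 process.
    """
    if n_genomes < 3:
        raise ValueError("need at least 3 genomes")
    species = [f"G{i + 1:03d}" for i in range(n_genomes)]
    taxa = dendropy.TaxonNamespace(species)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_genomes,
        taxon_namespace=taxa, rng=random.Random(seed),
    )
    pdm = tree.phylogenetic_distance_matrix()
    taxon_of = {t.label: t for t in taxa}
    dist = np.zeros((n_genomes, n_genomes))
    for i, a in enumerate(species):
        for j in range(i + 1, n_genomes):
            d = pdm.patristic_distance(taxon_of[a], taxon_of[species[j]])
            dist[i, j] = dist[j, i] = d
    return tree.as_string(schema="newick").strip(), species, dist


def _smoothed_presence_probs(dist_norm: np.ndarray, focal: int) -> np.ndarray:
    # close relatives of the focal lineage are likely to retain the gene;
    # gentle decay keeps average presence near 0.5 (patristic distances on an
    # ultrametric tree pile up near the maximum)
    return np.clip(0.30 + 0.65 * np.exp(-1.5 * dist_norm[focal]), 0.05, 0.95)


def simulate_presence_profiles(config: WorldConfig, dist_norm: np.ndarray,
                               pathway_of: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Presence/absence vectors (proteins × genomes).

    Each pathway draws a tree-smoothed base vector; each member copies the
    base entry with probability ``co_inheritance`` and otherwise its own
    independent tree-smoothed vector, then every entry flips with probability
    ``profile_flip_rate``.  Proteins present in fewer than 3 genomes are
    resampled (forced after 50 tries).
    """
    G = config.n_genomes
    bases = np.empty((config.n_pathways, G), dtype=bool)
    for k in range(config.n_pathways):
        focal = int(rng.integers(G))
        bases[k] = rng.random(G) < _smoothed_presence_probs(dist_norm, focal)
    presence = np.empty((config.n_proteins, G), dtype=bool)
    for i in range(config.n_proteins):
        k = pathway_of[i]
        for _attempt in range(50):
            own = rng.random(G) < _smoothed_presence_probs(dist_norm, int(rng.integers(G)))
            if k >= 0:
                use_base = rng.random(G) < config.co_inheritance
                profile = np.where(use_base, bases[k], own)
            else:
                profile = own
            profile = profile ^ (rng.random(G) < config.profile_flip_rate)
            if profile.sum() >= 3:
                break
        else:
            profile[rng.choice(G, size=3, replace=False)] = True
        presence[i] = profile
    return presence


def _ortholog_map_from_presence(config: WorldConfig, species: list[str],
                                protein_ids: list[str], presence: np.ndarray,
                                dist_norm: np.ndarray,
                                rng: np.random.Generator) -> OrthologMap:
    """Bit scores decay with the genome's tree distance to the query lineage."""
    d_query = dist_norm[0]
    self_bits = rng.uniform(200.0, 800.0, size=len(protein_ids))
    entries: dict[str, dict[str, OrthologEntry]] = {}
    for i, protein in enumerate(protein_ids):
        per_genome: dict[str, OrthologEntry] = {}
        for j, genome in enumerate(species):
            if not presence[i, j]:
                continue
            bit = self_bits[i] * (1.0 - 0.8 * d_query[j]) * (1.0 + 0.02 * rng.standard_normal())
            bit = float(np.clip(bit, 30.0, self_bits[i]))
            per_genome[genome] = OrthologEntry(f"{protein}@{genome}", bit, float(self_bits[i]))
        entries[protein] = per_genome
    counts = {g: max(1, int(presence[:, j].sum())) for j, g in enumerate(species)}
    return OrthologMap(entries=entries, genome_protein_counts=counts)


def simulate_gene_orders(config: WorldConfig, species: list[str], protein_ids: list[str],
                         presence: np.ndarray, pathway_of: np.ndarray,
                         rng: np.random.Generator) -> dict[str, GenomeTable]:
    """Circular gene layouts.

    With probability ``operon_prob`` a pathway's co-present genes form an
    adjacent co-directional block with intergenic gaps in [0, 100]; all other
    genes are placed independently with large gaps and random strand.
    """
    tables: dict[str, GenomeTable] = {}
    for j, genome in enumerate(species):
        present = [i for i in range(len(protein_ids)) if presence[i, j]]
        by_pathway: dict[int, list[int]] = {}
        singletons: list[int] = []
        for i in present:
            k = int(pathway_of[i])
            if k >= 0:
                by_pathway.setdefault(k, []).append(i)
            else:
                singletons.append(i)
        blocks: list[tuple[list[int], bool]] = []
        for k in sorted(by_pathway):
            members = by_pathway[k]
            if len(members) >= 2 and rng.random() < config.operon_prob:
                members = list(rng.permutation(members))
                blocks.append((members, True))
            else:
                singletons.extend(members)
        blocks.extend(([i], False) for i in singletons)
        order = rng.permutation(len(blocks))
        genes: list[tuple[str, int, int, str]] = []
        pos = 1 + int(rng.integers(150, 5001))
        for bi in order:
            members, is_operon = blocks[bi]
            strand = "+" if rng.random() < 0.5 else "-"
            for mi, i in enumerate(members):
                if not is_operon:
                    strand = "+" if rng.random() < 0.5 else "-"
                length = int(rng.integers(300, 3001))
                genes.append((f"{protein_ids[i]}@{genome}", pos, pos + length - 1, strand))
                gap = int(rng.integers(0, 101)) if is_operon else int(rng.integers(150, 5001))
                pos += length + gap
        length_bp = (genes[-1][2] if genes else 0) + int(rng.integers(150, 5001))
        gene_objs = [Gene(gid, start, end, strand, rank)
                     for rank, (gid, start, end, strand) in enumerate(genes)]
        tables[genome] = GenomeTable(genome_id=genome, length_bp=length_bp, genes=gene_objs)
    return tables


def simulate_expression(config: WorldConfig, protein_ids: list[str], pathway_of: np.ndarray,
                        rng: np.random.Generator) -> ExpressionMatrix:
    """Expression over ``n_conditions``: pathway latent mixed with a private latent."""
    C = config.n_conditions
    latents = rng.standard_normal((config.n_pathways, C))
    values = np.empty((len(protein_ids), C))
    for i in range(len(protein_ids)):
        own = rng.standard_normal(C)
        k = pathway_of[i]
        signal = config.coexpression * latents[k] + (1.0 - config.coexpression) * own \
            if k >= 0 else own
        values[i] = signal + config.expr_sigma * rng.standard_normal(C)
    values *= rng.uniform(0.5, 2.0, size=C)  # heterogeneous condition variance
    conditions = [f"cond{c + 1:03d}" for c in range(C)]
    return ExpressionMatrix(gene_ids=list(protein_ids), condition_ids=conditions, values=values)


def _symmetric_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    upper = np.triu(rng.standard_normal((n, n)) * sd, k=1)
    return upper + upper.T


def simulate_distance_matrices(config: WorldConfig, species: list[str],
                               protein_ids: list[str], presence: np.ndarray,
                               pathway_of: np.ndarray, dist_norm: np.ndarray,
                               rng: np.random.Generator,
                               ) -> tuple[dict[str, DistanceMatrix], dict[tuple[str, str], int]]:
    """Per-protein distance matrices plus genome-pair shared-ortholog counts.

    DX = tree distance (restricted to genomes where the protein is present)
    + ``coevolution`` × a residual matrix shared by pathway partners + noise;
    entries floored at 0.  Shared counts are derived from the presence
    vectors.
    """
    G = len(species)
    residuals = np.stack([_symmetric_noise(G, config.coevolution_residual_sd, rng)
                          for _ in range(config.n_pathways)]) if config.n_pathways else np.zeros((0, G, G))
    matrices: dict[str, DistanceMatrix] = {}
    for i, protein in enumerate(protein_ids):
        idx = np.nonzero(presence[i])[0]
        if len(idx) < 2:
            continue
        sub = np.ix_(idx, idx)
        values = dist_norm[sub].copy()
        k = pathway_of[i]
        if k >= 0:
            values = values + config.coevolution * residuals[k][sub]
        values = values + _symmetric_noise(len(idx), config.dist_sigma, rng)
        values = np.clip(values, 0.0, None)
        np.fill_diagonal(values, 0.0)
        matrices[protein] = DistanceMatrix(
            label=protein, species_ids=[species[j] for j in idx], values=values)
    counts = presence.astype(np.int64)
    shared_matrix = counts.T @ counts
    shared = {pair_key(species[i], species[j]): int(shared_matrix[i, j])
              for i in range(G) for j in range(i + 1, G)}
    return matrices, shared


# ---------------------------------------------------------------------------
# world assembly and export
# ---------------------------------------------------------------------------

def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Assemble a full synthetic world; a pure function of the config."""
    rng = np.random.default_rng(config.seed)
    newick, species, raw_dist = simulate_species_tree(config.n_genomes, config.seed)
    dist_norm = raw_dist / raw_dist.max()
    protein_ids = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    pathway_of = np.full(config.n_proteins, -1, dtype=int)
    pathway_names: list[tuple[str, str]] = []
    for c in range(config.n_categories):
        for p in range(config.pathways_per_category):
            pathway_names.append((f"CAT{c + 1:02d}", f"path_{c + 1:02d}_{p + 1:02d}"))
    for i in range(config.n_annotated):
        pathway_of[i] = i // config.proteins_per_pathway
    assignments = {protein_ids[i]: (pathway_names[pathway_of[i]] if pathway_of[i] >= 0 else None)
                   for i in range(config.n_proteins)}

    presence = simulate_presence_profiles(config, dist_norm, pathway_of, rng)
    # guard: every genome needs at least 2 genes for a meaningful table
    for j in range(config.n_genomes):
        if presence[:, j].sum() < 2:
            presence[rng.choice(config.n_proteins, size=2, replace=False), j] = True
    ortholog_map = _ortholog_map_from_presence(config, species, protein_ids, presence,
                                               dist_norm, rng)
    genome_tables = simulate_gene_orders(config, species, protein_ids, presence,
                                         pathway_of, rng)
    expression = simulate_expression(config, protein_ids, pathway_of, rng)
    matrices, shared = simulate_distance_matrices(config, species, protein_ids, presence,
                                                  pathway_of, dist_norm, rng)
    memberships = {p: frozenset({entry}) for p, entry in assignments.items() if entry is not None}
    annotation = PathwayAnnotation(memberships=memberships)
    truth = build_global_gold(annotation).positives
    return SyntheticWorld(
        config=config, species_ids=species, tree_newick=newick,
        tree_distances=dist_norm, protein_ids=protein_ids, assignments=assignments,
        presence=presence, genome_tables=genome_tables, ortholog_map=ortholog_map,
        expression=expression, distance_matrices=matrices, genome_shared_counts=shared,
        annotation=annotation, truth=frozenset(truth),
    )


def export_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write every scorer input as TSV/YAML under ``out_dir``; returns the manifest."""
    out = Path(out_dir)
    cfg_hash = world.config.hash()
    header = standard_header(cfg_hash, world.config.seed)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    cfg_path = out / "world_config.yaml"
    cfg_path.write_text(yaml.safe_dump({"world": world.config.to_dict(),
                                        "config_hash": cfg_hash}, sort_keys=True),
                        encoding="utf-8")
    manifest["config"] = cfg_path

    tree_path = out / "species_tree.nwk"
    tree_path.write_text(world.tree_newick + "\n", encoding="utf-8")
    manifest["tree"] = tree_path

    for genome_id, table in sorted(world.genome_tables.items()):
        path = out / "genomes" / f"{genome_id}.tsv"
        write_genome_table(table, path, header_comments=header)
        manifest[f"genome:{genome_id}"] = path

    write_ortholog_map(world.ortholog_map, out / "orthologs.tsv", out / "genome_counts.tsv",
                       header_comments=header)
    manifest["orthologs"] = out / "orthologs.tsv"
    manifest["genome_counts"] = out / "genome_counts.tsv"

    shared_lines = [f"# {c}" for c in header]
    shared_lines += [f"{a}\t{b}\t{n}" for (a, b), n in sorted(world.genome_shared_counts.items())]
    (out / "genome_shared.tsv").write_text("\n".join(shared_lines) + "\n", encoding="utf-8")
    manifest["genome_shared"] = out / "genome_shared.tsv"

    write_expression_matrix(world.expression, out / "expression.tsv", header_comments=header)
    manifest["expression"] = out / "expression.tsv"

    for protein, matrix in sorted(world.distance_matrices.items()):
        path = out / "matrices" / f"{protein}.tsv"
        write_distance_matrix(matrix, path, header_comments=header)
    manifest["matrices_dir"] = out / "matrices"

    write_pathway_annotations(world.annotation, out / "annotations.tsv", header_comments=header)
    manifest["annotations"] = out / "annotations.tsv"

    truth_lines = [f"# {c}" for c in header]
    truth_lines += [f"{a}\t{b}" for a, b in sorted(world.truth)]
    (out / "truth_pairs.tsv").write_text("\n".join(truth_lines) + "\n", encoding="utf-8")
    manifest["truth"] = out / "truth_pairs.tsv"

    pair_lines = [f"# {c}" for c in header]
    pair_lines += [f"{a}\t{b}" for a, b in world.pair_universe()]
    (out / "pairs.tsv").write_text("\n".join(pair_lines) + "\n", encoding="utf-8")
    manifest["pairs"] = out / "pairs.tsv"
    return manifest


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column pair list TSV (``#`` comments allowed)."""
    pairs = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        a, b = line.split("\t")[:2]
        pairs.append(pair_key(a, b))
    return pairs


def with_knobs(config: WorldConfig, **knobs: float | int) -> WorldConfig:
    """Convenience: a copy of ``config`` with some fields replaced."""
    return replace(config, **knobs)
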