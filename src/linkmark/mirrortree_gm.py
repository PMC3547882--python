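"""Genome distance-Mirrortree (GM) scorer.

Per-protein inter-species distance matrices are corrected for the shared
speciation signal by subtracting a rescaled copy of each from a
shared-ortholog genome-distance matrix (DG); corrected matrices are then
compared pairwise by Pearson correlation over their common species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .data_io import PairScoreTable, pair_key

logger = logging.getLogger("linkmark")

GENOME_LABEL = "GENOME"


@dataclass
class DistanceMatrix:
    """Symmetric inter-species distance matrix for one protein (or DG).

    Dimension equals the number of species in which the protein has an
    ortholog.  Corrected matrices (``corrected=True``) may contain negative
    entries; raw ones must be non-negative.
    """

    label: str
    species_ids: list[str]
    values: np.ndarray
    corrected: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species_ids)
        if len(set(self.species_ids)) != n:
            raise ValueError(f"{self.label}: duplicate species ids")
        if self.values.shape != (n, n):
            raise ValueError(f"{self.label}: matrix shape {self.values.shape} != ({n},{n})")
        if not np.isfinite(self.values).all():
            raise ValueError(f"{self.label}: non-finite entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-12:
            raise ValueError(f"{self.label}: matrix not symmetric")
        if n and np.abs(np.diag(self.values)).max() != 0.0:
            raise ValueError(f"{self.label}: nonzero diagonal")
        if not self.corrected and (self.values < 0).any():
            raise ValueError(f"{self.label}: negative distances")

    def restrict(self, species: list[str]) -> np.ndarray:
        idx = [self.species_ids.index(s) for s in species]
        return self.values[np.ix_(idx, idx)]


def upper_triangle(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def distance_matrix_from_alignment(msa: Mapping[str, str], label: str = "",
                                   gap_chars: str = "-.") -> DistanceMatrix:
    """p-distance matrix from an MSA keyed by species.

    Entry (i,j) is the fraction of mismatching positions among columns where
    both sequences are non-gap; a pair with zero comparable columns is an
    error.
    """
    species = list(msa)
    if len(species) < 2:
        raise ValueError("need at least 2 aligned sequences")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
    arr = np.array([list(msa[s].upper()) for s in species])
    non_gap = ~np.isin(arr, list(gap_chars))
    n = len(species)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = non_gap[i] & non_gap[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {species[i]} and {species[j]}")
            values[i, j] = values[j, i] = float((arr[i][both] != arr[j][both]).sum()) / m
    return DistanceMatrix(label=label or "MSA", species_ids=species, values=values)


def read_alignment_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    msa: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in msa:
            raise ValueError(f"duplicate species key {record.id!r} in {path}")
        msa[record.id] = str(record.seq)
    return msa


def genome_distance(n_a: int, n_b: int, n_shared: int) -> float:
    """Shared-ortholog genome distance ``1 - n_shared / min(n_a, n_b)``."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("genome protein counts must be positive")
    if n_shared < 0 or n_shared > min(n_a, n_b):
        raise ValueError(f"n_shared={n_shared} outside [0, min({n_a},{n_b})]")
    return 1.0 - n_shared / min(n_a, n_b)


def build_genome_distance_matrix(genome_protein_counts: Mapping[str, int],
                                 pairwise_shared: Mapping[tuple[str, str], int]) -> DistanceMatrix:
    """DG: symmetric genome-distance matrix over all genomes in the counts table.

    ``pairwise_shared`` maps unordered genome pairs to shared-ortholog counts
    (from precomputed bidirectional searches); a missing pair is an error.
    """
    species = sorted(genome_protein_counts)
    n = len(species)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = pair_key(species[i], species[j])
            if key not in pairwise_shared:
                raise KeyError(f"missing shared-ortholog count for genome pair {key}")
            d = genome_distance(genome_protein_counts[species[i]],
                                genome_protein_counts[species[j]],
                                pairwise_shared[key])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(label=GENOME_LABEL, species_ids=species, values=values)


@dataclass(frozen=True)
class GmRescale:
    """Rescale factor: highest PCC between DG and any protein matrix."""

    rho: float
    argmax_protein: str

    def __post_init__(self) -> None:
        if not (0.0 < self.rho <= 1.0):
            raise ValueError(f"rho must be in (0,1], got {self.rho}")


def _common_species(a: DistanceMatrix, b: DistanceMatrix) -> list[str]:
    present = set(b.species_ids)
    return [s for s in a.species_ids if s in present]


def compute_rescale_factor(dg: DistanceMatrix,
                           protein_matrices: Mapping[str, DistanceMatrix]) -> GmRescale:
    """Maximum PCC between DG and any protein matrix over their common species.

    Protein matrices sharing fewer than 3 species with DG are skipped; if no
    matrix qualifies, or the best correlation is not positive, the correction
    is impossible and an error is raised.
    """
    best: tuple[float, str] | None = None
    for protein in sorted(protein_matrices):
        dx = protein_matrices[protein]
        common = _common_species(dg, dx)
        if len(common) < 3:
            continue
        u = upper_triangle(dg.restrict(common))
        v = upper_triangle(dx.restrict(common))
        if np.std(u) == 0 or np.std(v) == 0:
            continue
        r = float(stats.pearsonr(u, v).statistic)
        if best is None or r > best[0]:
            best = (r, protein)
    if best is None:
        raise ValueError("no protein matrix shares >=3 species with DG")
    if best[0] <= 0:
        raise ValueError(f"highest DG correlation is {best[0]:.3f} <= 0; correction impossible")
    return GmRescale(rho=min(1.0, best[0]), argmax_protein=best[1])


def correct_distance_matrix(dx: DistanceMatrix, dg: DistanceMatrix,
                            rescale: GmRescale) -> DistanceMatrix:
    """Speciation-bias correction: ``corrected(i,j) = DG(i,j) - DX(i,j)/rho``.

    Restricted to species common to DX and DG (at least 3 required); the
    diagonal is forced to 0 and negative entries are retained.
    """
    common = _common_species(dx, dg)
    if len(common) < 3:
        raise ValueError(f"{dx.label}: only {len(common)} species in common with DG")
    corrected = dg.restrict(common) - dx.restrict(common) / rescale.rho
    np.fill_diagonal(corrected, 0.0)
    return DistanceMatrix(label=dx.label, species_ids=common, values=corrected, corrected=True)


def gm_scores(pairs: Iterable[tuple[str, str]],
              corrected_matrices: Mapping[str, DistanceMatrix],
              min_common_species: int = 10) -> PairScoreTable:
    """PCC of corrected-matrix upper triangles over common species, clamped at 0.

    Pairs with fewer than ``min_common_species`` common species, a missing
    matrix, or a zero-variance triangle are flagged undefined with score 0.
    """
    table = PairScoreTable(method="GM")
    species_sets = {p: set(m.species_ids) for p, m in corrected_matrices.items()}
    for a, b in (pair_key(*p) for p in pairs):
        ma = corrected_matrices.get(a)
        mb = corrected_matrices.get(b)
        if ma is None or mb is None:
            table.set(a, b, 0.0, undefined=True)
            continue
        common = [s for s in ma.species_ids if s in species_sets[b]]
        if len(common) < min_common_species:
            table.set(a, b, 0.0, undefined=True)
            continue
        u = upper_triangle(ma.restrict(common))
        v = upper_triangle(mb.restrict(common))
        if np.std(u) == 0 or np.std(v) == 0:
            table.set(a, b, 0.0, undefined=True)
            continue
        r = float(stats.pearsonr(u, v).statistic)
        table.set(a, b, min(1.0, max(0.0, r)))
    return table


def write_distance_matrix(matrix: DistanceMatrix, path, header_comments: Iterable[str] = ()) -> None:
    """Square labeled TSV: header row of species, one labeled row per species."""
    lines = [f"# {c}" for c in header_comments]
    lines.append(f"# label={matrix.label}")
    lines.append(f"# corrected={int(matrix.corrected)}")
    lines.append("species\t" + "\t".join(matrix.species_ids))
    for s, row in zip(matrix.species_ids, matrix.values):
        lines.append(s + "\t" + "\t".join(repr(float(v)) for v in row))
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_distance_matrix(path) -> DistanceMatrix:
    from pathlib import Path
    label = ""
    corrected = False
    species: list[str] | None = None
    rows: list[list[float]] = []
    row_labels: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("label="):
                label = body.split("=", 1)[1]
            elif body.startswith("corrected="):
                corrected = bool(int(body.split("=", 1)[1]))
            continue
        if not line.strip():
            continue
        fields = line.split("\t")
        if species is None:
            species = fields[1:]
            continue
        row_labels.append(fields[0])
        rows.append([float(v) for v in fields[1:]])
    if species is None:
        raise ValueError(f"{path}: empty distance matrix file")
    if row_labels != species:
        raise ValueError(f"{path}: row labels do not match column labels")
    return DistanceMatrix(label=label, species_ids=species, values=np.array(rows), corrected=corrected)
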