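"""Domain types and tab-delimited readers/writers shared by all pipeline stages.

All on-disk formats are UTF-8 TSV with ``#`` comment lines.  Readers validate
every declared type invariant and reject malformed input with the offending
row number; the only silent coercion anywhere is the documented
duplicate-ortholog rule (keep the higher bit score).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import yaml

logger = logging.getLogger("linkmark")

STRANDS = ("+", "-")


class DataValidationError(ValueError):
    """An input file violates a declared type invariant."""


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered-pair key: lexicographically sorted, no self-pairs."""
    if a == b:
        raise DataValidationError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


# ---------------------------------------------------------------------------
# GenomeTable
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int  # 1-based bp
    end: int    # 1-based bp, inclusive
    strand: str
    rank: int   # 0-based index in ascending start order


@dataclass
class GenomeTable:
    """Ordered, stranded gene coordinates of one circular replicon."""

    genome_id: str
    length_bp: int
    genes: list[Gene]

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise DataValidationError(f"{self.genome_id}: non-positive length_bp")
        seen: set[str] = set()
        starts = []
        for g in self.genes:
            if g.strand not in STRANDS:
                raise DataValidationError(f"{self.genome_id}/{g.gene_id}: bad strand {g.strand!r}")
            if g.start > g.end:
                raise DataValidationError(f"{self.genome_id}/{g.gene_id}: end < start")
            if g.end > self.length_bp:
                raise DataValidationError(f"{self.genome_id}/{g.gene_id}: end > length_bp")
            if g.gene_id in seen:
                raise DataValidationError(f"{self.genome_id}: duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            starts.append(g.start)
        if starts != sorted(starts):
            raise DataValidationError(f"{self.genome_id}: genes not sorted by start")
        for i, g in enumerate(self.genes):
            if g.rank != i:
                raise DataValidationError(f"{self.genome_id}: rank of {g.gene_id} is {g.rank}, expected {i}")

    @property
    def size(self) -> int:
        return len(self.genes)

    def rank_of(self) -> dict[str, int]:
        return {g.gene_id: g.rank for g in self.genes}


def read_genome_table(path: str | Path) -> GenomeTable:
    """Read a PTT-like TSV gene table (or GFF3, see :func:`read_genome_gff3`).

    Expected layout::

        #genome_id=<id>
        #length_bp=<int>
        gene_id  start  end  strand      <- header row
        g1       10     100  +

    Rows may appear out of start order; genes are sorted and ranked on read.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if text.lstrip().startswith("##gff-version"):
        return read_genome_gff3(path)

    genome_id: str | None = None
    length_bp: int | None = None
    rows: list[tuple[int, str, int, int, str]] = []
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("genome_id="):
                genome_id = body.split("=", 1)[1]
            elif body.startswith("length_bp="):
                length_bp = int(body.split("=", 1)[1])
            continue
        fields = line.split("\t")
        if not header_seen:
            if fields[:4] != ["gene_id", "start", "end", "strand"]:
                raise DataValidationError(f"{path}:{lineno}: bad column header {fields!r}")
            header_seen = True
            continue
        if len(fields) < 4:
            raise DataValidationError(f"{path}:{lineno}: expected 4 columns")
        gene_id, start_s, end_s, strand = fields[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise DataValidationError(f"{path}:{lineno}: non-integer coordinate") from exc
        if strand not in STRANDS:
            raise DataValidationError(f"{path}:{lineno}: malformed strand {strand!r}")
        if end < start:
            raise DataValidationError(f"{path}:{lineno}: end < start")
        rows.append((lineno, gene_id, start, end, strand))
    if genome_id is None or length_bp is None:
        raise DataValidationError(f"{path}: missing #genome_id= or #length_bp= header")
    seen: dict[str, int] = {}
    for lineno, gid, *_ in rows:
        if gid in seen:
            raise DataValidationError(f"{path}:{lineno}: duplicate gene_id {gid!r} (first at row {seen[gid]})")
        seen[gid] = lineno
    for lineno, gid, start, end, strand in rows:
        if end > length_bp:
            raise DataValidationError(f"{path}:{lineno}: end {end} > length_bp {length_bp}")
    rows.sort(key=lambda r: (r[2], r[1]))
    genes = [Gene(gid, start, end, strand, rank) for rank, (_, gid, start, end, strand) in enumerate(rows)]
    return GenomeTable(genome_id=genome_id, length_bp=length_bp, genes=genes)


def read_genome_gff3(path: str | Path) -> GenomeTable:
    """Read a single-replicon GFF3, using ``gene`` features only.

    The ``##sequence-region`` pragma supplies the replicon id and length.
    """
    path = Path(path)
    genome_id: str | None = None
    length_bp: int | None = None
    rows: list[tuple[int, str, int, int, str]] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                genome_id, length_bp = parts[1], int(parts[3])
            continue
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise DataValidationError(f"{path}:{lineno}: GFF3 rows need 9 columns")
        seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
        if ftype != "gene":
            continue
        if genome_id is not None and seqid != genome_id:
            raise DataValidationError(f"{path}:{lineno}: multiple replicons not supported ({seqid})")
        attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        gene_id = attr_map.get("ID") or attr_map.get("locus_tag")
        if gene_id is None:
            raise DataValidationError(f"{path}:{lineno}: gene feature lacks ID attribute")
        if strand not in STRANDS:
            raise DataValidationError(f"{path}:{lineno}: malformed strand {strand!r}")
        rows.append((lineno, gene_id, int(start_s), int(end_s), strand))
    if genome_id is None or length_bp is None:
        raise DataValidationError(f"{path}: missing ##sequence-region pragma")
    rows.sort(key=lambda r: (r[2], r[1]))
    genes = [Gene(gid, start, end, strand, rank) for rank, (_, gid, start, end, strand) in enumerate(rows)]
    return GenomeTable(genome_id=genome_id, length_bp=length_bp, genes=genes)


def write_genome_table(table: GenomeTable, path: str | Path, header_comments: Iterable[str] = ()) -> None:
    path = Path(path)
    lines = [f"# {c}" for c in header_comments]
    lines += [f"#genome_id={table.genome_id}", f"#length_bp={table.length_bp}",
              "gene_id\tstart\tend\tstrand"]
    lines += [f"{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}" for g in table.genes]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# OrthologMap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologEntry:
    ortholog_gene_id: str
    bit_score: float
    self_bit_score: float


@dataclass
class OrthologMap:
    """Reciprocal-best-hit ortholog assignments with alignment bit scores.

    ``entries[query][genome]`` gives at most one ortholog per (query, genome);
    ``genome_protein_counts`` carries each genome's total protein count.
    """

    entries: dict[str, dict[str, OrthologEntry]]
    genome_protein_counts: dict[str, int]

    def __post_init__(self) -> None:
        for gid, n in self.genome_protein_counts.items():
            if n <= 0:
                raise DataValidationError(f"genome {gid}: non-positive protein count")
        for q, per_genome in self.entries.items():
            for gid, e in per_genome.items():
                if e.bit_score <= 0 or e.self_bit_score <= 0:
                    raise DataValidationError(f"({q},{gid}): non-positive bit score")

    def genomes(self) -> list[str]:
        return sorted(self.genome_protein_counts)

    def get(self, query: str, genome: str) -> OrthologEntry | None:
        return self.entries.get(query, {}).get(genome)

    def ortholog_set(self, genome: str) -> set[str]:
        """Query proteins having an ortholog in ``genome``."""
        return {q for q, per_genome in self.entries.items() if genome in per_genome}


def read_ortholog_map(orthologs_path: str | Path, counts_path: str | Path) -> OrthologMap:
    """Read an already-filtered RBH table plus per-genome protein counts.

    The BLAST-level thresholds (e-value, minimum bit score) are assumed to
    have been applied upstream; this reader only ingests the tabular product.
    Duplicate (query, genome) rows keep the higher bit score with a warning.
    """
    entries: dict[str, dict[str, OrthologEntry]] = {}
    for lineno, fields in _tsv_rows(orthologs_path, 5):
        query, genome, gene_id, bit_s, self_s = fields[:5]
        try:
            bit, self_bit = float(bit_s), float(self_s)
        except ValueError as exc:
            raise DataValidationError(f"{orthologs_path}:{lineno}: non-numeric bit score") from exc
        if bit <= 0:
            raise DataValidationError(f"{orthologs_path}:{lineno}: non-positive bit score {bit}")
        if self_bit <= 0:
            raise DataValidationError(f"{orthologs_path}:{lineno}: non-positive self bit score")
        entry = OrthologEntry(gene_id, bit, self_bit)
        prev = entries.setdefault(query, {}).get(genome)
        if prev is not None:
            keep = entry if entry.bit_score > prev.bit_score else prev
            logger.warning("duplicate ortholog row for (%s,%s); keeping bit %.1f", query, genome, keep.bit_score)
            entry = keep
        entries[query][genome] = entry
    counts: dict[str, int] = {}
    for lineno, fields in _tsv_rows(counts_path, 2):
        genome, n_s = fields[:2]
        if genome in counts:
            raise DataValidationError(f"{counts_path}:{lineno}: duplicate genome {genome!r}")
        counts[genome] = int(n_s)
    return OrthologMap(entries=entries, genome_protein_counts=counts)


def write_ortholog_map(omap: OrthologMap, orthologs_path: str | Path, counts_path: str | Path,
                       header_comments: Iterable[str] = ()) -> None:
    lines = [f"# {c}" for c in header_comments]
    for q in sorted(omap.entries):
        for gid in sorted(omap.entries[q]):
            e = omap.entries[q][gid]
            lines.append(f"{q}\t{gid}\t{e.ortholog_gene_id}\t{e.bit_score!r}\t{e.self_bit_score!r}")
    Path(orthologs_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    clines = [f"# {c}" for c in header_comments]
    clines += [f"{gid}\t{n}" for gid, n in sorted(omap.genome_protein_counts.items())]
    Path(counts_path).write_text("\n".join(clines) + "\n", encoding="utf-8")


def _tsv_rows(path: str | Path, min_cols: int) -> Iterator[tuple[int, list[str]]]:
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < min_cols:
            raise DataValidationError(f"{path}:{lineno}: expected ≥{min_cols} columns, got {len(fields)}")
        yield lineno, fields


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """genes × conditions real matrix; missing entries are NaN."""

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray  # float, NaN = missing

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataValidationError("duplicate gene ids")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise DataValidationError("duplicate condition ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise DataValidationError("values shape does not match id lists")
        finite = np.isfinite(self.values).sum(axis=1)
        if len(self.gene_ids) and (finite < 2).any():
            bad = [g for g, n in zip(self.gene_ids, finite) if n < 2]
            raise DataValidationError(f"rows with <2 finite values: {bad}")

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix: first column gene id, header row of conditions.

    Empty cells are treated as missing; rows with fewer than two finite values
    are dropped with a log message.
    """
    path = Path(path)
    header: list[str] | None = None
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = fields[1:]
            if len(set(header)) != len(header):
                dupes = sorted({c for c in header if header.count(c) > 1})
                raise DataValidationError(f"{path}:{lineno}: duplicate condition id(s) {dupes}")
            continue
        gene_ids.append(fields[0])
        vals = [float(v) if v.strip() != "" else math.nan for v in fields[1:]]
        if len(vals) != len(header):
            raise DataValidationError(f"{path}:{lineno}: row width mismatch")
        rows.append(vals)
    if header is None:
        raise DataValidationError(f"{path}: empty expression file")
    values = np.array(rows, dtype=float) if rows else np.zeros((0, len(header)))
    keep = np.isfinite(values).sum(axis=1) >= 2
    for gid in np.array(gene_ids, dtype=object)[~keep]:
        logger.info("dropping expression row %s: <2 finite values", gid)
    kept_ids = [g for g, k in zip(gene_ids, keep) if k]
    if len(set(kept_ids)) != len(kept_ids):
        raise DataValidationError(f"{path}: duplicate gene ids")
    return ExpressionMatrix(gene_ids=kept_ids, condition_ids=list(header), values=values[keep])


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            header_comments: Iterable[str] = ()) -> None:
    lines = [f"# {c}" for c in header_comments]
    lines.append("gene_id\t" + "\t".join(matrix.condition_ids))
    for gid, row in zip(matrix.gene_ids, matrix.values):
        cells = ["" if not np.isfinite(v) else repr(float(v)) for v in row]
        lines.append(gid + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# PathwayAnnotation
# ---------------------------------------------------------------------------

@dataclass
class PathwayAnnotation:
    """protein → set of (level2 category, level3 pathway) memberships."""

    memberships: dict[str, frozenset[tuple[str, str]]]

    def __post_init__(self) -> None:
        pathway_category: dict[str, str] = {}
        for protein, entries in self.memberships.items():
            if not entries:
                raise DataValidationError(f"{protein}: annotated protein with no entries")
            for level2, level3 in entries:
                prev = pathway_category.setdefault(level3, level2)
                if prev != level2:
                    raise DataValidationError(
                        f"pathway {level3!r} listed under both {prev!r} and {level2!r}")

    def proteins(self) -> list[str]:
        return sorted(self.memberships)

    def categories(self) -> set[str]:
        return {l2 for entries in self.memberships.values() for l2, _ in entries}

    def pathways(self, protein: str) -> frozenset[tuple[str, str]]:
        return self.memberships.get(protein, frozenset())


def read_pathway_annotations(path: str | Path) -> PathwayAnnotation:
    """Read TSV rows (protein_id, level2_category, level3_pathway)."""
    memberships: dict[str, set[tuple[str, str]]] = {}
    pathway_rows: dict[str, tuple[int, str]] = {}
    for lineno, fields in _tsv_rows(path, 3):
        protein, level2, level3 = fields[:3]
        prev = pathway_rows.get(level3)
        if prev is not None and prev[1] != level2:
            raise DataValidationError(
                f"{path}: pathway {level3!r} under {prev[1]!r} (row {prev[0]}) and {level2!r} (row {lineno})")
        pathway_rows.setdefault(level3, (lineno, level2))
        memberships.setdefault(protein, set()).add((level2, level3))
    return PathwayAnnotation(memberships={p: frozenset(s) for p, s in memberships.items()})


def write_pathway_annotations(annotation: PathwayAnnotation, path: str | Path,
                              header_comments: Iterable[str] = ()) -> None:
    lines = [f"# {c}" for c in header_comments]
    for protein in annotation.proteins():
        for level2, level3 in sorted(annotation.memberships[protein]):
            lines.append(f"{protein}\t{level2}\t{level3}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# PairScoreTable
# ---------------------------------------------------------------------------

METHODS = ("GN", "GC", "PP", "GM", "ES")


@dataclass
class PairScoreTable:
    """Per-pair interaction scores of one method, on a 0–1 scale.

    Pairs the method could not evaluate carry score 0 and appear in
    ``undefined_pairs`` so the evaluation universe stays identical across
    methods.
    """

    method: str
    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    undefined_pairs: set[tuple[str, str]] = field(default_factory=set)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise DataValidationError(f"unknown method {self.method!r}")

    def set(self, a: str, b: str, score: float, *, undefined: bool = False) -> None:
        key = pair_key(a, b)
        if not (0.0 <= score <= 1.0):
            raise DataValidationError(f"score {score} for {key} outside [0,1]")
        self.scores[key] = float(score)
        if undefined:
            self.undefined_pairs.add(key)

    def get(self, a: str, b: str) -> float:
        return self.scores[pair_key(a, b)]

    def __len__(self) -> int:
        return len(self.scores)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairScoreTable):
            return NotImplemented
        return (self.method == other.method and self.scores == other.scores
                and self.undefined_pairs == other.undefined_pairs)


def write_score_table(table: PairScoreTable, path: str | Path) -> None:
    """Write TSV (protein_a, protein_b, score, status) with metadata comments.

    Pairs are emitted with protein_a < protein_b; floats use ``repr`` so the
    read→write round trip is bit-exact.
    """
    lines = [f"# method={table.method}"]
    for k in sorted(table.metadata):
        lines.append(f"# {k}={table.metadata[k]}")
    lines.append("protein_a\tprotein_b\tscore\tstatus")
    for (a, b) in sorted(table.scores):
        status = "undefined" if (a, b) in table.undefined_pairs else "ok"
        lines.append(f"{a}\t{b}\t{table.scores[(a, b)]!r}\t{status}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_score_table(path: str | Path) -> PairScoreTable:
    path = Path(path)
    method: str | None = None
    metadata: dict[str, str] = {}
    scores: dict[tuple[str, str], float] = {}
    undefined: set[tuple[str, str]] = set()
    header_seen = False
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                if k == "method":
                    method = v
                else:
                    metadata[k] = v
            continue
        if not line.strip():
            continue
        if not header_seen:
            header_seen = True
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise DataValidationError(f"{path}:{lineno}: expected ≥3 columns")
        a, b, score_s = fields[:3]
        status = fields[3] if len(fields) > 3 else "ok"
        key = pair_key(a, b)
        if key in scores:
            raise DataValidationError(f"{path}:{lineno}: duplicate pair {key}")
        scores[key] = float(score_s)
        if status == "undefined":
            undefined.add(key)
    if method is None:
        raise DataValidationError(f"{path}: missing '# method=' comment")
    table = PairScoreTable(method=method, scores=scores, undefined_pairs=undefined, metadata=metadata)
    for key, s in scores.items():
        if not (0.0 <= s <= 1.0):
            raise DataValidationError(f"{path}: score {s} for {key} outside [0,1]")
    return table


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline-level knobs; holds the method parameters and the RNG seed."""

    seed: int
    max_gap: int = 100           # intergenic cutoff, nt
    top_k_conditions: int = 300  # most-varying conditions kept for ES
    min_common_species: int = 10 # minimum shared species for a GM pair
    dereplicate_threshold: float = 0.90
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.max_gap <= 0 or self.top_k_conditions <= 0 or self.min_common_species <= 0:
            raise DataValidationError("cutoffs must be positive")
        if not (0.0 < self.dereplicate_threshold <= 1.0):
            raise DataValidationError("dereplicate_threshold must be in (0,1]")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "max_gap": self.max_gap,
            "top_k_conditions": self.top_k_conditions,
            "min_common_species": self.min_common_species,
            "dereplicate_threshold": self.dereplicate_threshold,
            "log_level": self.log_level,
        }


def config_hash(payload: Mapping) -> str:
    """Stable 12-hex-digit hash of a configuration mapping."""
    blob = yaml.safe_dump(dict(payload), sort_keys=True).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:12]


def standard_header(cfg_hash: str, seed: int) -> list[str]:
    return [f"config_hash={cfg_hash}", f"seed={seed}"]
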