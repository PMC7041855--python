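"""Amplicon panel designs and raw coverage matrices.

A *design* is an ordered catalogue of amplicons (the unit of read counting
in panel sequencing), sorted by genomic position.  A *run* is the design
plus an amplicons x samples matrix of raw read counts with a missing-value
mask; all downstream statistics skip masked cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Amplicon",
    "AmpliconDesign",
    "RunMatrix",
    "read_design",
    "write_design",
    "read_coverage",
    "read_count_matrix",
    "assemble_run",
]


def default_gene(amplicon_id: str) -> str:
    """Gene label inferred from an amplicon id: prefix before the last underscore."""
    if "_" in amplicon_id:
        return amplicon_id.rsplit("_", 1)[0]
    return amplicon_id


@dataclass(frozen=True, slots=True)
class Amplicon:
    """One PCR target region.  Coordinates are 1-based inclusive."""

    id: str
    chromosome: str
    start: int
    end: int
    gene: str = ""
    pool: int = 1

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("amplicon id must be non-empty")
        if not self.chromosome:
            raise ValueError(f"amplicon {self.id!r}: chromosome must be non-empty")
        if self.start > self.end:
            raise ValueError(
                f"amplicon {self.id!r}: start {self.start} > end {self.end}"
            )
        if self.pool < 1:
            raise ValueError(f"amplicon {self.id!r}: pool must be >= 1")
        if not self.gene:
            object.__setattr__(self, "gene", default_gene(self.id))


class AmpliconDesign:
    """Ordered amplicon catalogue.

    Amplicons are kept sorted by (chromosome, start, end, id); adjacency
    ("successive amplicons") is defined by this order restricted to one
    chromosome.  Ids are unique.
    """

    def __init__(self, amplicons: Iterable[Amplicon]) -> None:
        amps = sorted(amplicons, key=lambda a: (a.chromosome, a.start, a.end, a.id))
        if not amps:
            raise ValueError("design must contain at least one amplicon")
        seen: set[str] = set()
        for a in amps:
            if a.id in seen:
                raise ValueError(f"duplicate amplicon id {a.id!r} in design")
            seen.add(a.id)
        self.amplicons: tuple[Amplicon, ...] = tuple(amps)
        self.index: dict[str, int] = {a.id: i for i, a in enumerate(amps)}
        self.ids: tuple[str, ...] = tuple(a.id for a in amps)
        self.chromosomes = np.array([a.chromosome for a in amps])
        self.starts = np.array([a.start for a in amps], dtype=np.int64)
        self.ends = np.array([a.end for a in amps], dtype=np.int64)
        self.pools = np.array([a.pool for a in amps], dtype=np.int64)
        self.genes = np.array([a.gene for a in amps])

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self) -> Iterator[Amplicon]:
        return iter(self.amplicons)

    def __getitem__(self, i: int) -> Amplicon:
        return self.amplicons[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AmpliconDesign):
            return NotImplemented
        return self.amplicons == other.amplicons

    def __repr__(self) -> str:
        n_chrom = len(dict.fromkeys(self.chromosomes.tolist()))
        return f"AmpliconDesign({len(self)} amplicons, {n_chrom} chromosomes)"

    def chromosome_order(self) -> list[str]:
        """Chromosome names in order of first appearance in the sorted design."""
        return list(dict.fromkeys(self.chromosomes.tolist()))

    def chromosome_blocks(self) -> dict[str, np.ndarray]:
        """Map chromosome -> array of design indices, in design order."""
        blocks: dict[str, np.ndarray] = {}
        for chrom in self.chromosome_order():
            blocks[chrom] = np.flatnonzero(self.chromosomes == chrom)
        return blocks

    def gene_indices(self, gene: str) -> np.ndarray:
        idx = np.flatnonzero(self.genes == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not in design")
        return idx


@dataclass
class RunMatrix:
    """Raw read counts for one sequencing run: amplicons x samples."""

    design: AmpliconDesign
    sample_ids: list[str]
    counts: np.ndarray  # int64, shape (n_amplicons, n_samples)
    missing: np.ndarray  # bool, same shape; True = excluded from computation

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.missing = np.asarray(self.missing, dtype=bool)
        shape = (len(self.design), len(self.sample_ids))
        if self.counts.shape != shape or self.missing.shape != shape:
            raise ValueError(
                f"count/mask shape {self.counts.shape} does not match "
                f"{len(self.design)} amplicons x {len(self.sample_ids)} samples"
            )
        if (self.counts[~self.missing] < 0).any():
            raise ValueError("negative read counts are not allowed")

    @property
    def n_amplicons(self) -> int:
        return len(self.design)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in run") from None

    def copy(self) -> "RunMatrix":
        return RunMatrix(
            self.design, list(self.sample_ids), self.counts.copy(), self.missing.copy()
        )


# ---------------------------------------------------------------------------
# design I/O

_TSV1_COLUMNS = ("chrom", "start", "end", "amplicon", "gene", "pool")


def read_design(path: str | Path, dialect: str = "tsv1") -> AmpliconDesign:
    """Read a panel design.

    ``bed0``: whitespace-separated, 0-based half-open coordinates, columns
    chrom/start/end/name[/gene[/pool]]; starts are shifted to the internal
    1-based inclusive convention.  ``tsv1``: tab-separated with a header
    (chrom, start, end, amplicon[, gene, pool]), coordinates 1-based
    inclusive.
    """
    path = Path(path)
    if dialect not in ("bed0", "tsv1"):
        raise ValueError(f"unknown design dialect {dialect!r}")
    amplicons: list[Amplicon] = []
    with path.open() as fh:
        lines = fh.read().splitlines()
    if dialect == "tsv1":
        if not lines:
            raise ValueError(f"{path}: empty design file")
        header = [c.strip().lower() for c in lines[0].split("\t")]
        for col in ("chrom", "start", "end", "amplicon"):
            if col not in header:
                raise ValueError(f"{path}: missing required column {col!r}")
        col = {name: header.index(name) for name in header}
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            fields = line.split("\t")
            try:
                amplicons.append(
                    Amplicon(
                        id=fields[col["amplicon"]],
                        chromosome=fields[col["chrom"]],
                        start=int(fields[col["start"]]),
                        end=int(fields[col["end"]]),
                        gene=fields[col["gene"]] if "gene" in col else "",
                        pool=int(fields[col["pool"]]) if "pool" in col else 1,
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable design row: {exc}") from exc
    else:  # bed0
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns")
            try:
                amplicons.append(
                    Amplicon(
                        id=fields[3],
                        chromosome=fields[0],
                        start=int(fields[1]) + 1,
                        end=int(fields[2]),
                        gene=fields[4] if len(fields) > 4 else "",
                        pool=int(fields[5]) if len(fields) > 5 else 1,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable BED row: {exc}") from exc
    return AmpliconDesign(amplicons)


def write_design(design: AmpliconDesign, path: str | Path) -> None:
    """Write a design in the tsv1 dialect (1-based inclusive coordinates)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_TSV1_COLUMNS) + "\n")
        for a in design:
            fh.write(f"{a.chromosome}\t{a.start}\t{a.end}\t{a.id}\t{a.gene}\t{a.pool}\n")


# ---------------------------------------------------------------------------
# coverage I/O

def read_coverage(
    path: str | Path, design: AmpliconDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (amplicon_id, total_reads) TSV for one sample.

    Returns (counts, missing) aligned to design order; design amplicons
    absent from the file are flagged missing.
    """
    path = Path(path)
    counts = np.zeros(len(design), dtype=np.int64)
    missing = np.ones(len(design), dtype=bool)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            amp_id, raw = fields[0], fields[1]
            if lineno == 1:
                try:
                    int(raw)
                except ValueError:
                    continue  # header line
            try:
                value = int(raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad count {raw!r}") from exc
            if amp_id not in design.index:
                raise ValueError(f"{path}:{lineno}: unknown amplicon id {amp_id!r}")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative count for {amp_id!r}")
            i = design.index[amp_id]
            counts[i] = value
            missing[i] = False
    return counts, missing


def read_count_matrix(
    path: str | Path, design: AmpliconDesign
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Read a combined matrix TSV: first column amplicon_id, one column per sample.

    Empty fields are missing.  Returns per-sample (sample_id, counts, missing)
    tuples in file column order, suitable for :func:`assemble_run`.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise ValueError(f"{path}: no sample columns")
    n = len(design)
    counts = np.zeros((n, len(sample_ids)), dtype=np.int64)
    missing = np.ones((n, len(sample_ids)), dtype=bool)
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        amp_id = fields[0]
        if amp_id not in design.index:
            raise ValueError(f"{path}:{lineno}: unknown amplicon id {amp_id!r}")
        i = design.index[amp_id]
        for j, raw in enumerate(fields[1:]):
            raw = raw.strip()
            if raw == "":
                continue
            value = int(raw)
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative count for {amp_id!r}")
            counts[i, j] = value
            missing[i, j] = False
    return [
        (sid, counts[:, j].copy(), missing[:, j].copy())
        for j, sid in enumerate(sample_ids)
    ]


def assemble_run(
    design: AmpliconDesign,
    vectors: Sequence[tuple[str, np.ndarray, np.ndarray] | tuple[str, np.ndarray]],
) -> RunMatrix:
    """Stack per-sample count vectors into a RunMatrix (column order = input order)."""
    if not vectors:
        raise ValueError("at least one sample is required")
    sample_ids: list[str] = []
    cols: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for item in vectors:
        if len(item) == 2:
            sid, counts = item  # type: ignore[misc]
            miss = np.zeros(len(design), dtype=bool)
        else:
            sid, counts, miss = item  # type: ignore[misc]
        if sid in sample_ids:
            raise ValueError(f"duplicate sample id {sid!r}")
        counts = np.asarray(counts, dtype=np.int64)
        miss = np.asarray(miss, dtype=bool)
        if counts.shape != (len(design),) or miss.shape != (len(design),):
            raise ValueError(f"sample {sid!r}: vector length does not match design")
        sample_ids.append(sid)
        cols.append(counts)
        masks.append(miss)
    return RunMatrix(
        design=design,
        sample_ids=sample_ids,
        counts=np.column_stack(cols),
        missing=np.column_stack(masks),
    )
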