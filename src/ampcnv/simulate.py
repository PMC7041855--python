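"""Synthetic panel/run generation and cancer-cell-fraction dilution.

The generator emulates a multiplex amplicon sequencing run: a design of
genes split across chromosomes and primer pools, per-amplicon capture
efficiencies shared across samples, per-sample library depth, optional
multiplicative log-normal noise and Poisson resampling.  CNVs are injected
into raw counts with the dilution model

    SRC = RRC * (1 - f) + RRC * (c / 2) * f

for copy number ``c`` and carrier-cell fraction ``f`` (f = 1 is the
germline/clonal case).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .charts import cusum_tracks
from .detect import DetectionConfig, State, two_stage_detect
from .normalize import NormalizationConfig
from .panel_io import Amplicon, AmpliconDesign, RunMatrix

__all__ = [
    "SimulationSpec",
    "CnvEvent",
    "DilutionPoint",
    "make_design",
    "make_gene_sizes",
    "simulate_run",
    "apply_cnv",
    "gene_region",
    "dilution_sweep",
]


def make_design(
    gene_sizes: Sequence[int],
    gene_names: Sequence[str] | None = None,
    n_chromosomes: int = 22,
    n_pools: int = 2,
    chromosome_of: dict[str, str] | None = None,
    amplicon_length: int = 200,
    spacing: int = 1000,
    origin: int = 10_000,
) -> AmpliconDesign:
    """Deterministic synthetic design: genes laid out round-robin across
    chromosomes, amplicons tiled left to right, pools alternating.

    ``chromosome_of`` pins named genes to specific chromosomes (e.g. to put
    one large region alone on its own chromosome).
    """
    if gene_names is None:
        gene_names = [f"GENE{g + 1:03d}" for g in range(len(gene_sizes))]
    if len(gene_names) != len(gene_sizes):
        raise ValueError("gene_names and gene_sizes lengths differ")
    chromosome_of = chromosome_of or {}
    cursor: dict[str, int] = {}
    amplicons: list[Amplicon] = []
    k = 0  # global amplicon counter, drives pool alternation
    auto = 0
    for gene, size in zip(gene_names, gene_sizes):
        if size < 1:
            raise ValueError(f"gene {gene!r}: size must be >= 1")
        if gene in chromosome_of:
            chrom = chromosome_of[gene]
        else:
            chrom = f"chr{auto % n_chromosomes + 1}"
            auto += 1
        pos = cursor.get(chrom, origin)
        for a in range(size):
            start = pos
            end = pos + amplicon_length - 1
            amplicons.append(
                Amplicon(
                    id=f"{gene}_a{a + 1:03d}",
                    chromosome=chrom,
                    start=start,
                    end=end,
                    gene=gene,
                    pool=k % n_pools + 1,
                )
            )
            pos = end + spacing
            k += 1
        cursor[chrom] = pos + spacing  # extra gap between genes
    return AmpliconDesign(amplicons)


def make_gene_sizes(
    total_amplicons: int,
    special: dict[str, int] | None = None,
    filler_size: int = 10,
) -> tuple[list[str], list[int]]:
    """Gene name/size lists with the given named genes plus filler genes of
    ``filler_size`` amplicons, summing exactly to ``total_amplicons``."""
    special = special or {}
    names = list(special)
    sizes = [special[g] for g in names]
    remaining = total_amplicons - sum(sizes)
    if remaining < 0:
        raise ValueError("special genes exceed total_amplicons")
    i = 0
    while remaining > 0:
        size = min(filler_size, remaining)
        if 0 < remaining - size < 2:  # avoid a trailing 1-amplicon gene
            size = remaining
        names.append(f"FILL{i + 1:04d}")
        sizes.append(size)
        remaining -= size
        i += 1
    return names, sizes


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic run.

    ``library_size_range`` is the uniform range of per-sample mean
    per-amplicon depth; ``amplicon_efficiency_sd`` the log-scale SD of the
    per-amplicon multiplicative efficiency (shared across samples);
    ``noise_cv`` the per-cell multiplicative coefficient of variation.
    """

    design: AmpliconDesign
    n_samples: int
    library_size_range: tuple[float, float] = (800.0, 1200.0)
    amplicon_efficiency_sd: float = 0.4
    noise_cv: float = 0.05
    count_noise: str = "none"  # {"none", "poisson"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")
        if self.noise_cv < 0 or self.amplicon_efficiency_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.count_noise not in ("none", "poisson"):
            raise ValueError("count_noise must be 'none' or 'poisson'")


def simulate_run(spec: SimulationSpec) -> RunMatrix:
    """Generate a raw count matrix; identical spec + seed gives identical output."""
    rng = np.random.default_rng(spec.seed)
    n_amp, n_samp = len(spec.design), spec.n_samples
    lo, hi = spec.library_size_range
    depth = rng.uniform(lo, hi, size=n_samp)
    if spec.amplicon_efficiency_sd > 0:
        efficiency = np.exp(rng.normal(0.0, spec.amplicon_efficiency_sd, size=n_amp))
    else:
        efficiency = np.ones(n_amp)
    expected = efficiency[:, None] * depth[None, :]
    if spec.noise_cv > 0:
        # mean-1 log-normal multiplicative noise with the requested CV
        s = np.sqrt(np.log1p(spec.noise_cv**2))
        expected = expected * np.exp(rng.normal(-0.5 * s * s, s, size=(n_amp, n_samp)))
    if spec.count_noise == "poisson":
        counts = rng.poisson(expected)
    else:
        counts = np.rint(expected).astype(np.int64)
    return RunMatrix(
        design=spec.design,
        sample_ids=[f"S{j + 1}" for j in range(n_samp)],
        counts=counts,
        missing=np.zeros((n_amp, n_samp), dtype=bool),
    )


@dataclass(frozen=True)
class CnvEvent:
    """A copy-number event to inject: contiguous amplicon range on one
    chromosome, integer copy number != 2, carrier-cell fraction in [0, 1]."""

    sample_id: str
    region: tuple[str, str]  # (first amplicon id, last amplicon id), inclusive
    copy_number: int
    cancer_cell_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.copy_number < 0 or self.copy_number == 2:
            raise ValueError("copy_number must be >= 0 and != 2")
        if not (0.0 <= self.cancer_cell_fraction <= 1.0):
            raise ValueError("cancer_cell_fraction must be in [0, 1]")


def gene_region(design: AmpliconDesign, gene: str) -> tuple[str, str]:
    """Region tuple spanning all amplicons of one gene."""
    idx = design.gene_indices(gene)
    return design.ids[idx[0]], design.ids[idx[-1]]


def _region_indices(design: AmpliconDesign, region: tuple[str, str]) -> np.ndarray:
    first, last = region
    try:
        i0, i1 = design.index[first], design.index[last]
    except KeyError as exc:
        raise ValueError(f"region amplicon not in design: {exc}") from exc
    if i1 < i0:
        i0, i1 = i1, i0
    idx = np.arange(i0, i1 + 1)
    chroms = set(design.chromosomes[idx].tolist())
    if len(chroms) != 1:
        raise ValueError(f"region {region} crosses chromosomes {sorted(chroms)}")
    return idx


def apply_cnv(run: RunMatrix, event: CnvEvent) -> RunMatrix:
    """Inject an event into raw counts via the dilution formula; counts
    outside the region are conserved exactly.  Half-up rounding."""
    out = run.copy()
    j = out.sample_index(event.sample_id)
    idx = _region_indices(run.design, event.region)
    f = event.cancer_cell_fraction
    factor = (1.0 - f) + (event.copy_number / 2.0) * f
    src = out.counts[idx, j] * factor
    out.counts[idx, j] = np.floor(src + 0.5).astype(np.int64)
    return out


@dataclass
class DilutionPoint:
    fraction: float
    n_flagged: int  # region amplicons in the event direction
    n_region: int
    call_overlap: bool  # any correct-direction call overlapping the region
    max_abs_s_minus: float  # CUSUM deletion excursion over the region
    max_s_plus: float


def dilution_sweep(
    run: RunMatrix,
    region: tuple[str, str],
    sample_id: str,
    fractions: Sequence[float] | None = None,
    copy_number: int = 1,
    ncfg: NormalizationConfig | None = None,
    dcfg: DetectionConfig | None = None,
) -> list[DilutionPoint]:
    """Re-inject the event at each carrier fraction and summarize detection.

    For each fraction the event is applied to a fresh copy of the run, the
    full two-stage pipeline runs, and the region's flagged-amplicon count,
    call overlap, and CUSUM excursions are recorded.
    """
    if fractions is None:
        fractions = np.round(np.arange(0.0, 1.0001, 0.05), 10).tolist()
    ncfg = ncfg or NormalizationConfig()
    dcfg = dcfg or DetectionConfig()
    direction = State.DEL if copy_number < 2 else State.DUP
    idx = _region_indices(run.design, region)
    region_ids = set(run.design.ids[i] for i in idx)
    chrom = str(run.design.chromosomes[idx[0]])
    start = int(run.design.starts[idx[0]])
    end = int(run.design.ends[idx[-1]])
    points: list[DilutionPoint] = []
    for f in fractions:
        diluted = (
            apply_cnv(run, CnvEvent(sample_id, region, copy_number, f))
            if f > 0
            else run.copy()
        )
        res = two_stage_detect(diluted, ncfg, dcfg)
        statuses = res.statuses[sample_id]
        n_flagged = sum(
            1
            for i in idx
            if statuses[i].state is direction
        )
        overlap = any(
            c.direction is direction and c.overlaps(chrom, start, end)
            for c in res.calls[sample_id]
        )
        col = res.nrc.column(sample_id)
        max_abs_s_minus = 0.0
        max_s_plus = 0.0
        for track in cusum_tracks(col, run.design):
            if track.chromosome != chrom:
                continue
            in_region = np.array([a in region_ids for a in track.amplicon_ids])
            if in_region.any():
                max_abs_s_minus = float(np.max(np.abs(track.s_minus[in_region])))
                max_s_plus = float(np.max(track.s_plus[in_region]))
        points.append(
            DilutionPoint(
                fraction=float(f),
                n_flagged=n_flagged,
                n_region=len(idx),
                call_overlap=overlap,
                max_abs_s_minus=max_abs_s_minus,
                max_s_plus=max_s_plus,
            )
        )
    return points
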