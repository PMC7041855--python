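"""Desk-scale synthetic benchmark experiments.

Reusable experiment builders that exercise the full pipeline on synthetic
runs sized like a real multiplex panel (2,394 amplicons, 16-sample runs):
a low-cell-fraction dilution experiment, a large null cohort for
per-amplicon specificity, and a battery of germline CNV injections for
amplicon-level sensitivity.  Used by the acceptance tests and the
acceptance report script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import DetectionConfig, State, two_stage_detect
from .normalize import NormalizationConfig
from .panel_io import AmpliconDesign
from .simulate import (
    CnvEvent,
    SimulationSpec,
    apply_cnv,
    gene_region,
    make_design,
    make_gene_sizes,
    simulate_run,
)

__all__ = [
    "benchmark_design",
    "dilution_flag_count",
    "null_specificity",
    "germline_battery",
    "GERMLINE_EVENTS",
]

#: named genes with the amplicon footprints used across the experiments
_SPECIAL_GENES = {
    "G10": 10,    # 10-amplicon gene: specificity target and small events
    "G58": 58,
    "G98": 98,    # whole-chromosome-scale event, alone on chrX
    "G25A": 25,
    "G25B": 25,
    "G4": 4,
    "G7": 7,
    "GDEL80": 80,  # 80-amplicon gene for the dilution experiment
}

#: germline battery: 11 runs of 16 samples; per event (sample slot 1-16,
#: gene, copy number). 3 = single-copy gain, 1 = single-copy loss; 461
#: event amplicons in total.
GERMLINE_EVENTS: list[list[tuple[int, str, int]]] = [
    [(3, "G10", 3), (8, "G58", 3), (9, "G98", 3)],
    [(2, "G25A", 3), (15, "G25B", 1)],
    [(3, "G58", 3)],
    [(4, "G4", 3), (12, "G58", 3)],
    [(3, "G25A", 3), (15, "G10", 3), (16, "G10", 1)],
    [(2, "G10", 3), (9, "G4", 3)],
    [(2, "G4", 3), (6, "G10", 3)],
    [(8, "G10", 1)],
    [(6, "G10", 1)],
    [(10, "G7", 3), (16, "G4", 3)],
    [(8, "G10", 3), (14, "G4", 3), (15, "G7", 3)],
]


def benchmark_design(total_amplicons: int = 2394) -> AmpliconDesign:
    """The benchmark panel: 2,394 amplicons, named genes above plus filler."""
    names, sizes = make_gene_sizes(total_amplicons, _SPECIAL_GENES)
    return make_design(sizes, names, chromosome_of={"G98": "chrX"})


def _simulate(design: AmpliconDesign, n_samples: int, seed: int):
    spec = SimulationSpec(design=design, n_samples=n_samples, noise_cv=0.05,
                          seed=seed)
    return simulate_run(spec)


@dataclass
class DilutionResult:
    n_flagged: int
    n_region: int
    fraction: float


def dilution_flag_count(seed: int, fraction: float = 0.60) -> DilutionResult:
    """Delete the 80-amplicon gene at the given carrier-cell fraction in one
    sample of a 16-sample run and count region amplicons flagged as deleted
    by the default pipeline."""
    design = benchmark_design()
    run = _simulate(design, 16, seed)
    region = gene_region(design, "GDEL80")
    run = apply_cnv(run, CnvEvent("S1", region, copy_number=1,
                                  cancer_cell_fraction=fraction))
    res = two_stage_detect(run)
    idx = design.gene_indices("GDEL80")
    statuses = res.statuses["S1"]
    n_flagged = sum(1 for i in idx if statuses[i].state is State.DEL)
    return DilutionResult(n_flagged=n_flagged, n_region=len(idx),
                          fraction=fraction)


@dataclass
class SpecificityResult:
    specificity: float
    n_cells: int
    n_false: int


def null_specificity(
    seed: int,
    n_samples: int = 456,
    batch_size: int = 16,
    gene: str = "G10",
) -> SpecificityResult:
    """Per-amplicon specificity over a CNV-free cohort.

    The cohort is processed in ``batch_size``-sample runs (as on a
    sequencer); a cell counts as a false positive when its amplicon belongs
    to any final call of its sample."""
    design = benchmark_design()
    idx = design.gene_indices(gene)
    gene_ids = {design.ids[i] for i in idx}
    n_false = 0
    done = 0
    batch = 0
    while done < n_samples:
        size = min(batch_size, n_samples - done)
        run = _simulate(design, size, seed * 10_000 + batch)
        res = two_stage_detect(run)
        for sid in run.sample_ids:
            in_calls = {a for c in res.calls[sid] for a in c.amplicon_ids}
            n_false += len(in_calls & gene_ids)
        done += size
        batch += 1
    n_cells = len(idx) * n_samples
    return SpecificityResult(
        specificity=1.0 - n_false / n_cells, n_cells=n_cells, n_false=n_false
    )


@dataclass
class GermlineResult:
    sensitivity: float
    n_event_amplicons: int
    n_correct_amplicons: int
    n_events_detected: int
    n_events: int


def germline_battery(seed: int) -> GermlineResult:
    """Inject the 22-event germline battery (fraction 1) into 11 simulated
    16-sample runs and score amplicon-level sensitivity plus whole-event
    recovery by correct-direction calls."""
    design = benchmark_design()
    n_correct = 0
    n_total = 0
    n_events_detected = 0
    n_events = 0
    for r, events in enumerate(GERMLINE_EVENTS):
        run = _simulate(design, 16, seed * 1000 + r)
        for slot, gene, cn in events:
            region = gene_region(design, gene)
            run = apply_cnv(run, CnvEvent(f"S{slot}", region, copy_number=cn))
        res = two_stage_detect(run)
        for slot, gene, cn in events:
            sid = f"S{slot}"
            direction = State.DEL if cn < 2 else State.DUP
            idx = design.gene_indices(gene)
            statuses = res.statuses[sid]
            n_total += len(idx)
            n_correct += sum(1 for i in idx if statuses[i].state is direction)
            chrom = str(design.chromosomes[idx[0]])
            lo, hi = int(design.starts[idx[0]]), int(design.ends[idx[-1]])
            n_events += 1
            if any(c.direction is direction and c.overlaps(chrom, lo, hi)
                   for c in res.calls[sid]):
                n_events_detected += 1
    return GermlineResult(
        sensitivity=n_correct / n_total,
        n_event_amplicons=n_total,
        n_correct_amplicons=n_correct,
        n_events_detected=n_events_detected,
        n_events=n_events,
    )
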