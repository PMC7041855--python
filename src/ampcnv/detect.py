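"""Z-score CNV detection with two-stage ratio refinement and gap merging.

Per sample, normalized read counts are standardized against the sample's
own genome-wide mean and population standard deviation; amplicons beyond
the one-tailed normal quantile at ``alpha`` are flagged as deleted (z < 0)
or duplicated (z > 0).  Runs of at least ``min_amplicons`` same-direction
flagged amplicons, adjacent in design order on one chromosome, become
calls.  Two same-direction calls separated by a single amplicon that is
significant at the relaxed ``alpha_relax`` level are merged; an optional
maximum genomic distance merges calls across wider gaps.

The *two-stage ratio* reruns the cross-sample median ratio after removing
each sample's first-pass CNV amplicons from the denominator pools, which
stabilizes regions where many samples share an event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.stats import norm

from .normalize import (
    NormalizationConfig,
    NormalizedMatrix,
    median_ratio,
    normalize_run,
)
from .panel_io import AmpliconDesign, RunMatrix

__all__ = [
    "State",
    "AmpliconStatus",
    "CnvCall",
    "DetectionConfig",
    "DetectionResult",
    "z_scores",
    "classify",
    "call_segments",
    "merge_segments",
    "detect_sample",
    "two_stage_detect",
]


class State(str, Enum):
    DEL = "DEL"
    DUP = "DUP"
    NEUTRAL = "NEUTRAL"
    MISSING = "MISSING"
    MERGED_GAP = "MERGED_GAP"


@dataclass(slots=True)
class AmpliconStatus:
    """Per-amplicon evidence for one sample."""

    amplicon_id: str
    z: float
    p_one_tailed: float
    state: State
    nrc: float = float("nan")


@dataclass(slots=True)
class CnvCall:
    """A contiguous run of same-direction significant amplicons in one sample."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    direction: State  # DEL or DUP
    amplicon_ids: tuple[str, ...]
    mean_nrc: float
    merged: bool = False

    @property
    def n_amplicons(self) -> int:
        return len(self.amplicon_ids)

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        return (
            self.chromosome == chromosome
            and self.start <= end
            and start <= self.end
        )


@dataclass(frozen=True)
class DetectionConfig:
    alpha: float = 0.01
    alpha_relax: float = 0.05
    min_amplicons: int = 3
    max_merge_distance: int | None = None
    two_stage: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < self.alpha_relax < 1):
            raise ValueError("require 0 < alpha < alpha_relax < 1")
        if self.min_amplicons < 1:
            raise ValueError("min_amplicons must be >= 1")
        if self.max_merge_distance is not None and self.max_merge_distance < 0:
            raise ValueError("max_merge_distance must be >= 0")


@dataclass
class DetectionResult:
    calls: dict[str, list[CnvCall]]
    statuses: dict[str, list[AmpliconStatus]]
    nrc: NormalizedMatrix
    stage1_calls: dict[str, list[CnvCall]]
    reference_ids: set[str]


def z_scores(nrc_row: np.ndarray) -> np.ndarray:
    """Standardize one sample's NRC vector against its own mean and
    population SD; NaN entries propagate as NaN.

    The output has mean 0 and population SD 1 exactly over the non-missing
    entries.
    """
    nrc_row = np.asarray(nrc_row, dtype=float)
    finite = np.isfinite(nrc_row)
    if finite.sum() < 2:
        raise ValueError("z-scores require >= 2 non-missing values")
    mu = nrc_row[finite].mean()
    sigma = nrc_row[finite].std()  # population SD
    if sigma == 0:
        raise ValueError("zero variance sample")
    z = np.full(nrc_row.shape, np.nan)
    z[finite] = (nrc_row[finite] - mu) / sigma
    return z


def classify(
    z: np.ndarray,
    design: AmpliconDesign,
    alpha: float,
    nrc: np.ndarray | None = None,
) -> list[AmpliconStatus]:
    """One-tailed classification of each amplicon's z-score.

    p is the standard-normal tail probability beyond |z|; an amplicon is
    DEL when z < 0 and p <= alpha, DUP when z > 0 and p <= alpha (ties at
    exactly alpha count as significant).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    z = np.asarray(z, dtype=float)
    if nrc is None:
        nrc = np.full(z.shape, np.nan)
    finite = np.isfinite(z)
    p = np.full(z.shape, np.nan)
    p[finite] = norm.sf(np.abs(z[finite]))
    statuses: list[AmpliconStatus] = []
    for i, amp_id in enumerate(design.ids):
        if not finite[i]:
            state = State.MISSING
        elif p[i] <= alpha and z[i] < 0:
            state = State.DEL
        elif p[i] <= alpha and z[i] > 0:
            state = State.DUP
        else:
            state = State.NEUTRAL
        statuses.append(AmpliconStatus(amp_id, float(z[i]), float(p[i]), state, float(nrc[i])))
    return statuses


def _make_call(
    design: AmpliconDesign,
    member_idx: list[int],
    direction: State,
    statuses: list[AmpliconStatus],
    sample_id: str,
    merged: bool = False,
) -> CnvCall:
    nrcs = np.array([statuses[i].nrc for i in member_idx], dtype=float)
    with np.errstate(all="ignore"):
        mean_nrc = float(np.nanmean(nrcs)) if np.isfinite(nrcs).any() else float("nan")
    return CnvCall(
        sample_id=sample_id,
        chromosome=str(design.chromosomes[member_idx[0]]),
        start=int(design.starts[member_idx[0]]),
        end=int(design.ends[member_idx[-1]]),
        direction=direction,
        amplicon_ids=tuple(design.ids[i] for i in member_idx),
        mean_nrc=mean_nrc,
        merged=merged,
    )


def call_segments(
    statuses: list[AmpliconStatus],
    design: AmpliconDesign,
    cfg: DetectionConfig,
    sample_id: str = "",
) -> list[CnvCall]:
    """Maximal runs of same-direction significant amplicons of length >=
    ``min_amplicons``, per chromosome.  MISSING amplicons are transparent:
    they neither break a run nor count toward its length."""
    if len(statuses) != len(design):
        raise ValueError("statuses must align with the design")
    calls: list[CnvCall] = []
    for chrom, idxs in design.chromosome_blocks().items():
        run_idx: list[int] = []
        run_dir: State | None = None

        def flush() -> None:
            nonlocal run_idx, run_dir
            if run_dir is not None and len(run_idx) >= cfg.min_amplicons:
                calls.append(_make_call(design, run_idx, run_dir, statuses, sample_id))
            run_idx, run_dir = [], None

        for i in idxs:
            st = statuses[i].state
            if st is State.MISSING:
                continue
            if st in (State.DEL, State.DUP):
                if run_dir is st:
                    run_idx.append(i)
                else:
                    flush()
                    run_idx, run_dir = [int(i)], st
            else:
                flush()
        flush()
    return calls


def _direction_p(z: float, direction: State) -> float:
    """One-tailed p of z in the given direction (DEL: lower tail)."""
    if direction is State.DEL:
        return float(norm.cdf(z))
    return float(norm.sf(z))


def merge_segments(
    calls: list[CnvCall],
    statuses: list[AmpliconStatus],
    design: AmpliconDesign,
    cfg: DetectionConfig,
) -> list[CnvCall]:
    """Merge same-direction calls on one chromosome, repeatedly until a
    fixed point.

    Rule 1 (single gap): the two calls are separated by exactly one
    non-missing amplicon whose one-tailed p in the call direction is <=
    ``alpha_relax``; that amplicon joins the merged call with state
    MERGED_GAP.  Rule 2 (distance): when ``max_merge_distance`` is set,
    calls whose genomic gap (bases strictly between them) is <= that
    distance are merged, their intermediate non-missing amplicons joining
    as MERGED_GAP.
    """
    def first_idx(c: CnvCall) -> int:
        return design.index[c.amplicon_ids[0]]

    calls = sorted(calls, key=first_idx)
    changed = True
    while changed:
        changed = False
        out: list[CnvCall] = []
        for call in calls:
            if not out:
                out.append(call)
                continue
            prev = out[-1]
            merged = _try_merge(prev, call, statuses, design, cfg)
            if merged is not None:
                out[-1] = merged
                changed = True
            else:
                out.append(call)
        calls = out
    return calls


def _try_merge(
    a: CnvCall,
    b: CnvCall,
    statuses: list[AmpliconStatus],
    design: AmpliconDesign,
    cfg: DetectionConfig,
) -> CnvCall | None:
    if a.chromosome != b.chromosome or a.direction != b.direction:
        return None
    last_a = design.index[a.amplicon_ids[-1]]
    first_b = design.index[b.amplicon_ids[0]]
    if first_b <= last_a:
        return None
    gap_idx = [
        i for i in range(last_a + 1, first_b)
        if statuses[i].state is not State.MISSING
    ]
    ok = False
    if len(gap_idx) == 1:
        g = gap_idx[0]
        if _direction_p(statuses[g].z, a.direction) <= cfg.alpha_relax:
            ok = True
    if not ok and cfg.max_merge_distance is not None:
        gap_bp = b.start - a.end - 1
        if gap_bp <= cfg.max_merge_distance:
            ok = True
    if not ok:
        return None
    for g in gap_idx:
        if statuses[g].state is State.NEUTRAL:
            statuses[g].state = State.MERGED_GAP
    members = (
        [design.index[x] for x in a.amplicon_ids]
        + gap_idx
        + [design.index[x] for x in b.amplicon_ids]
    )
    return _make_call(design, members, a.direction, statuses,
                      a.sample_id or b.sample_id, merged=True)


def detect_sample(
    nrc_row: np.ndarray,
    design: AmpliconDesign,
    cfg: DetectionConfig,
    sample_id: str = "",
) -> tuple[list[AmpliconStatus], list[CnvCall]]:
    """z-scores -> classify -> call_segments -> merge_segments for one sample."""
    z = z_scores(nrc_row)
    statuses = classify(z, design, cfg.alpha, nrc=nrc_row)
    calls = call_segments(statuses, design, cfg, sample_id=sample_id)
    calls = merge_segments(calls, statuses, design, cfg)
    return statuses, calls


def _detect_all(
    nrc: NormalizedMatrix, cfg: DetectionConfig
) -> tuple[dict[str, list[AmpliconStatus]], dict[str, list[CnvCall]]]:
    statuses: dict[str, list[AmpliconStatus]] = {}
    calls: dict[str, list[CnvCall]] = {}
    for j, sid in enumerate(nrc.sample_ids):
        st, cl = detect_sample(nrc.nrc[:, j], nrc.design, cfg, sample_id=sid)
        statuses[sid] = st
        calls[sid] = cl
    return statuses, calls


def two_stage_detect(
    run: RunMatrix,
    ncfg: NormalizationConfig | None = None,
    dcfg: DetectionConfig | None = None,
) -> DetectionResult:
    """Normalize and call CNVs, refining the median ratio in a second stage.

    Stage 1 runs the full chain with no exclusions.  Each sample's stage-1
    call amplicons (merged gaps included) are then removed from the median
    denominators, the ratio is recomputed, and detection reruns.  Exactly
    two stages.  Control mode and ``two_stage=False`` skip stage 2.
    """
    ncfg = ncfg or NormalizationConfig()
    dcfg = dcfg or DetectionConfig()
    res1 = normalize_run(run, ncfg)
    stat1, calls1 = _detect_all(res1.nrc, dcfg)
    skip_stage2 = not dcfg.two_stage or ncfg.control_sample_ids is not None
    if skip_stage2:
        return DetectionResult(calls1, stat1, res1.nrc, calls1, res1.reference_ids)
    exclusions = {
        sid: {amp for c in sample_calls for amp in c.amplicon_ids}
        for sid, sample_calls in calls1.items()
        if sample_calls
    }
    if not exclusions:
        return DetectionResult(calls1, stat1, res1.nrc, calls1, res1.reference_ids)
    nrc2 = median_ratio(
        res1.scaled, res1.missing, run.design, list(run.sample_ids), ncfg, exclusions
    )
    stat2, calls2 = _detect_all(nrc2, dcfg)
    return DetectionResult(calls2, stat2, nrc2, calls1, res1.reference_ids)
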