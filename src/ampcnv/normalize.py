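"""Normalization chain: raw counts -> normalized read counts (NRC).

The chain is: low-coverage filtering, per-sample per-pool share
normalization, stable-reference scaling, then a cross-sample median ratio.
The NRC has a theoretical value of 1 at two copies, 0.5 at a heterozygous
deletion and 1.5 at a single-copy duplication.  When control samples are
declared, the median-ratio denominators come from the controls only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel_io import AmpliconDesign, RunMatrix

__all__ = [
    "NormalizationConfig",
    "NormalizedMatrix",
    "NormalizationResult",
    "filter_low_coverage",
    "pool_normalize",
    "select_reference_amplicons",
    "reference_scale",
    "median_ratio",
    "normalize_run",
]

#: an amplicon masked in at least this fraction of samples is dropped panel-wide
DROP_AMPLICON_MISSING_FRACTION = 0.5


@dataclass(frozen=True)
class NormalizationConfig:
    """Normalization thresholds and sample/amplicon roles."""

    min_raw_reads: int = 20
    reference_fraction: float = 0.10
    forced_reference_ids: frozenset[str] | None = None
    excluded_ids: frozenset[str] = frozenset()
    control_sample_ids: frozenset[str] | None = None
    exclude_self_in_median: bool = False

    def __post_init__(self) -> None:
        if self.min_raw_reads < 0:
            raise ValueError("min_raw_reads must be >= 0")
        if not (0 < self.reference_fraction <= 1):
            raise ValueError("reference_fraction must be in (0, 1]")
        if self.forced_reference_ids and self.excluded_ids & self.forced_reference_ids:
            overlap = sorted(self.excluded_ids & self.forced_reference_ids)
            raise ValueError(
                f"forced reference and excluded amplicon sets overlap: {overlap}"
            )


@dataclass
class NormalizedMatrix:
    """Normalized read counts; NaN at missing cells, mask kept alongside."""

    design: AmpliconDesign
    sample_ids: list[str]
    nrc: np.ndarray  # float64, NaN where missing
    missing: np.ndarray  # bool

    def column(self, sample_id: str) -> np.ndarray:
        j = self.sample_ids.index(sample_id)
        return self.nrc[:, j]


@dataclass
class NormalizationResult:
    """Full-chain output, keeping the pre-median-ratio values so the
    median ratio can be recomputed with per-sample exclusions."""

    nrc: NormalizedMatrix
    reference_ids: set[str]
    scaled: np.ndarray  # reference-scaled values (input of the median ratio)
    missing: np.ndarray  # mask after low-coverage filtering


def filter_low_coverage(run: RunMatrix, min_raw_reads: int) -> RunMatrix:
    """Mask cells with raw counts below ``min_raw_reads``.

    An amplicon left missing in >= 50% of samples is masked in every sample,
    keeping cross-sample medians meaningful.
    """
    if min_raw_reads < 0:
        raise ValueError("min_raw_reads must be >= 0")
    missing = run.missing | (run.counts < min_raw_reads)
    frac = missing.mean(axis=1)
    missing[frac >= DROP_AMPLICON_MISSING_FRACTION, :] = True
    return RunMatrix(run.design, list(run.sample_ids), run.counts.copy(), missing)


def pool_normalize(run: RunMatrix) -> np.ndarray:
    """Per-sample per-pool shares: count / sum of non-missing counts of the
    same sample within the same primer pool.  NaN at missing cells."""
    values = np.full(run.counts.shape, np.nan)
    counts = run.counts.astype(float)
    counts[run.missing] = np.nan
    for pool in np.unique(run.design.pools):
        rows = run.design.pools == pool
        totals = np.nansum(counts[rows], axis=0)
        n_ok = (~run.missing[rows]).sum(axis=0)
        for j, sid in enumerate(run.sample_ids):
            if n_ok[j] == 0 or totals[j] == 0:
                raise ValueError(
                    f"pool {pool} has no usable amplicons in sample {sid!r}"
                )
        values[rows] = counts[rows] / totals
    return values


def select_reference_amplicons(
    values: np.ndarray,
    missing: np.ndarray,
    design: AmpliconDesign,
    cfg: NormalizationConfig,
) -> set[str]:
    """Choose reference amplicons: the most stable across samples.

    Stability is the coefficient of variation (population SD / mean) of the
    pool-normalized values across samples; only amplicons non-missing in
    every sample and not excluded are eligible.  ``forced_reference_ids``
    short-circuits the selection.
    """
    if cfg.forced_reference_ids is not None:
        for amp_id in sorted(cfg.forced_reference_ids):
            if amp_id not in design.index:
                raise ValueError(f"forced reference amplicon {amp_id!r} not in design")
        refs = set(cfg.forced_reference_ids) - set(cfg.excluded_ids)
        if not refs:
            raise ValueError("forced reference set is empty after exclusions")
        return refs
    if values.shape[1] < 2:
        raise ValueError("reference selection requires >= 2 samples")
    eligible = ~missing.any(axis=1)
    if cfg.excluded_ids:
        excluded_rows = np.array([a.id in cfg.excluded_ids for a in design])
        eligible &= ~excluded_rows
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        raise ValueError("no amplicon is non-missing in every sample")
    sub = values[idx]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1)  # population SD
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.inf)
    k = max(1, math.ceil(cfg.reference_fraction * idx.size))
    order = np.argsort(cv, kind="stable")[:k]
    return {design.ids[i] for i in idx[order]}


def reference_scale(
    values: np.ndarray,
    missing: np.ndarray,
    design: AmpliconDesign,
    refs: set[str],
) -> np.ndarray:
    """Divide each sample's column by the mean of its reference-amplicon values."""
    if not refs:
        raise ValueError("reference set must be non-empty")
    ref_idx = np.array(sorted(design.index[r] for r in refs))
    bad = np.argwhere(missing[ref_idx])
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"reference amplicon {design.ids[ref_idx[i]]!r} is missing in sample column {j}"
        )
    scale = values[ref_idx].mean(axis=0)
    if (scale <= 0).any():
        raise ValueError("non-positive reference scale")
    return values / scale


def median_ratio(
    values: np.ndarray,
    missing: np.ndarray,
    design: AmpliconDesign,
    sample_ids: list[str],
    cfg: NormalizationConfig,
    exclusions: dict[str, set[str]] | None = None,
) -> NormalizedMatrix:
    """Divide each cell by the per-amplicon cross-sample median.

    Denominators are computed over the control samples when
    ``cfg.control_sample_ids`` is set, otherwise over all samples whose cell
    is non-missing and whose per-sample ``exclusions`` do not list the
    amplicon.  Cells with an empty denominator pool or zero denominator are
    masked.
    """
    n_amp, n_samp = values.shape
    if cfg.control_sample_ids is not None:
        for cid in sorted(cfg.control_sample_ids):
            if cid not in sample_ids:
                raise ValueError(f"control sample {cid!r} not among run samples")
        if not cfg.control_sample_ids:
            raise ValueError("control mode requires >= 1 control sample")
    elif n_samp < 2:
        raise ValueError("median ratio without controls requires >= 2 samples")

    pool = values.copy()
    pool[missing] = np.nan
    if exclusions:
        for sid, amp_ids in exclusions.items():
            if sid not in sample_ids:
                raise ValueError(f"exclusion sample {sid!r} not among run samples")
            j = sample_ids.index(sid)
            rows = [design.index[a] for a in amp_ids]
            pool[rows, j] = np.nan

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # all-NaN denominator pools are legitimate: those cells get masked
        warnings.filterwarnings("ignore", message="All-NaN slice")
        if cfg.control_sample_ids is not None:
            ctrl_cols = [j for j, s in enumerate(sample_ids) if s in cfg.control_sample_ids]
            denom = np.nanmedian(pool[:, ctrl_cols], axis=1)
            denom = np.broadcast_to(denom[:, None], values.shape)
        elif cfg.exclude_self_in_median:
            denom = np.empty_like(values)
            for j in range(n_samp):
                others = np.delete(pool, j, axis=1)
                denom[:, j] = np.nanmedian(others, axis=1)
        else:
            denom = np.broadcast_to(np.nanmedian(pool, axis=1)[:, None], values.shape)

    out_missing = missing | ~np.isfinite(denom) | (denom == 0)
    with np.errstate(all="ignore"):
        nrc = values / denom
    nrc = np.where(out_missing, np.nan, nrc)
    return NormalizedMatrix(design, list(sample_ids), nrc, out_missing)


def normalize_run(
    run: RunMatrix,
    cfg: NormalizationConfig | None = None,
    exclusions: dict[str, set[str]] | None = None,
) -> NormalizationResult:
    """Run the full chain: filter -> pool shares -> reference scale -> median ratio."""
    cfg = cfg or NormalizationConfig()
    filtered = filter_low_coverage(run, cfg.min_raw_reads)
    shares = pool_normalize(filtered)
    refs = select_reference_amplicons(shares, filtered.missing, run.design, cfg)
    scaled = reference_scale(shares, filtered.missing, run.design, refs)
    nrc = median_ratio(
        scaled, filtered.missing, run.design, list(run.sample_ids), cfg, exclusions
    )
    return NormalizationResult(
        nrc=nrc, reference_ids=refs, scaled=scaled, missing=filtered.missing
    )
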