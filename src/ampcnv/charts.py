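"""Numeric diagnostic tracks: per-chromosome CUSUM series and Loess curves.

Both tracks are pure outputs for visual inspection/export; they never feed
the automated caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .panel_io import AmpliconDesign

__all__ = [
    "CusumTrack",
    "LoessTrack",
    "cusum_series",
    "cusum_tracks",
    "loess_fit",
    "loess_tracks",
]


@dataclass
class CusumTrack:
    """Cumulative-sum control chart for one chromosome.

    ``s_plus`` accumulates excursions above mean+SD (clipped at 0 from
    below); ``s_minus`` accumulates excursions below mean-SD (clipped at 0
    from above).  A sustained positive s_plus marks a candidate
    duplication; a sustained negative s_minus marks a candidate deletion.
    """

    chromosome: str
    amplicon_ids: tuple[str, ...]
    s_plus: np.ndarray
    s_minus: np.ndarray


@dataclass
class LoessTrack:
    chromosome: str
    amplicon_ids: tuple[str, ...]
    positions: np.ndarray
    fitted: np.ndarray
    bandwidth: float


def cusum_series(
    x: np.ndarray, mean: float, sd: float
) -> tuple[np.ndarray, np.ndarray]:
    """CUSUM recurrences for one chromosome's values, from S0+ = S0- = 0:

    S_n+ = max(0, S_{n-1}+ + x_n - (mean + sd))
    S_n- = min(0, S_{n-1}- + x_n - (mean - sd))
    """
    x = np.asarray(x, dtype=float)
    s_plus = np.empty(len(x))
    s_minus = np.empty(len(x))
    up, dn = 0.0, 0.0
    for n, xn in enumerate(x):
        up = max(0.0, up + xn - (mean + sd))
        dn = min(0.0, dn + xn - (mean - sd))
        s_plus[n] = up
        s_minus[n] = dn
    return s_plus, s_minus


def cusum_tracks(nrc_row: np.ndarray, design: AmpliconDesign) -> list[CusumTrack]:
    """Per-chromosome CUSUM tracks for one sample.

    The centre (mean) and allowance (SD) are genome-wide over the sample's
    non-missing amplicons, as in the z-scores; each chromosome restarts at
    0 and missing amplicons are skipped.
    """
    nrc_row = np.asarray(nrc_row, dtype=float)
    finite = np.isfinite(nrc_row)
    if finite.sum() < 2:
        raise ValueError("CUSUM requires >= 2 non-missing amplicons")
    mean = float(nrc_row[finite].mean())
    sd = float(nrc_row[finite].std())
    if sd == 0:
        raise ValueError("zero variance sample")
    tracks: list[CusumTrack] = []
    for chrom, idxs in design.chromosome_blocks().items():
        keep = idxs[finite[idxs]]
        if keep.size == 0:
            continue
        s_plus, s_minus = cusum_series(nrc_row[keep], mean, sd)
        tracks.append(
            CusumTrack(
                chromosome=chrom,
                amplicon_ids=tuple(design.ids[i] for i in keep),
                s_plus=s_plus,
                s_minus=s_minus,
            )
        )
    return tracks


def loess_fit(
    positions: np.ndarray, values: np.ndarray, bandwidth: float = 0.25
) -> np.ndarray:
    """Locally weighted linear regression (tricube weights, no robustness
    iterations) fitted at every input position.

    ``bandwidth`` is the fraction of points in each local window.
    """
    if not (0 < bandwidth <= 1):
        raise ValueError("bandwidth must be in (0, 1]")
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(positions) != len(values):
        raise ValueError("positions and values must have equal length")
    if len(positions) < 3:
        raise ValueError("loess requires >= 3 points")
    fitted = lowess(
        values,
        positions,
        frac=bandwidth,
        it=0,
        delta=0.0,
        return_sorted=False,
    )
    return np.asarray(fitted, dtype=float)


def loess_tracks(
    nrc_row: np.ndarray, design: AmpliconDesign, bandwidth: float = 0.25
) -> list[LoessTrack]:
    """Per-chromosome Loess curves over a sample's non-missing amplicons.

    Chromosomes with fewer than 3 usable points are skipped with a warning.
    """
    nrc_row = np.asarray(nrc_row, dtype=float)
    finite = np.isfinite(nrc_row)
    tracks: list[LoessTrack] = []
    for chrom, idxs in design.chromosome_blocks().items():
        keep = idxs[finite[idxs]]
        if keep.size < 3:
            warnings.warn(
                f"chromosome {chrom}: fewer than 3 usable amplicons, "
                "loess track omitted",
                stacklevel=2,
            )
            continue
        pos = design.starts[keep].astype(float)
        fitted = loess_fit(pos, nrc_row[keep], bandwidth)
        tracks.append(
            LoessTrack(
                chromosome=chrom,
                amplicon_ids=tuple(design.ids[i] for i in keep),
                positions=pos,
                fitted=fitted,
                bandwidth=bandwidth,
            )
        )
    return tracks
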