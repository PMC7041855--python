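"""Export of CNV calls: VCF 4.2 with symbolic alleles, and tabular reports."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .detect import AmpliconStatus, CnvCall, State
from .panel_io import AmpliconDesign

__all__ = [
    "to_vcf",
    "calls_to_frame",
    "statuses_to_frame",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_status_tsv",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP,Description="Duplication">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=AMPLICONS,Number=1,Type=Integer,Description="Number of supporting amplicons">
##INFO=<ID=MEANNRC,Number=1,Type=Float,Description="Mean normalized read count over the call">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def to_vcf(
    calls: list[CnvCall],
    design: AmpliconDesign,
    sample_id: str,
    path: str | Path,
) -> None:
    """Write one sample's merged calls as VCF 4.2: exactly one data line per
    call, symbolic <DEL>/<DUP> alleles, REF=N (no reference genome), contigs
    taken from the design."""
    contigs = design.chromosome_order()
    contig_rank = {c: i for i, c in enumerate(contigs)}
    records = sorted(calls, key=lambda c: (contig_rank[c.chromosome], c.start))
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_id}\n"
        )
        for call in records:
            svtype = call.direction.value
            info = (
                f"SVTYPE={svtype};END={call.end};"
                f"AMPLICONS={call.n_amplicons};MEANNRC={call.mean_nrc:.4f}"
            )
            fh.write(
                f"{call.chromosome}\t{call.start}\t.\tN\t<{svtype}>\t.\t.\t"
                f"{info}\tGT\t./1\n"
            )


def calls_to_frame(calls_by_sample: dict[str, list[CnvCall]]) -> pd.DataFrame:
    rows = [
        {
            "sample": sid,
            "chromosome": c.chromosome,
            "start": c.start,
            "end": c.end,
            "direction": c.direction.value,
            "n_amplicons": c.n_amplicons,
            "mean_nrc": c.mean_nrc,
            "merged": c.merged,
        }
        for sid, calls in calls_by_sample.items()
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "chromosome", "start", "end",
            "direction", "n_amplicons", "mean_nrc", "merged",
        ],
    )


def statuses_to_frame(
    statuses_by_sample: dict[str, list[AmpliconStatus]]
) -> pd.DataFrame:
    """Per-amplicon evidence table; one row per non-missing cell."""
    rows = [
        {
            "sample": sid,
            "amplicon": st.amplicon_id,
            "nrc": st.nrc,
            "z": st.z,
            "p": st.p_one_tailed,
            "state": st.state.value,
        }
        for sid, statuses in statuses_by_sample.items()
        for st in statuses
        if st.state is not State.MISSING
    ]
    return pd.DataFrame(
        rows, columns=["sample", "amplicon", "nrc", "z", "p", "state"]
    )


def write_calls_tsv(
    calls_by_sample: dict[str, list[CnvCall]], path: str | Path
) -> None:
    calls_to_frame(calls_by_sample).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"sample": str, "chromosome": str, "direction": str},
    )


def write_status_tsv(
    statuses_by_sample: dict[str, list[AmpliconStatus]], path: str | Path
) -> None:
    statuses_to_frame(statuses_by_sample).to_csv(path, sep="\t", index=False)
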