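"""Readers and writers for the plain-text formats used across the pipeline.

Dialects are fixed: VCF positions are 1-based, BED intervals 0-based
half-open, measurement and chip tables tidy CSV.  Every writer's output is
readable by its paired reader with lossless field recovery.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .fluidigm import ExpressionMatrix
from .variants import VariantCall

__all__ = [
    "write_measurements_csv",
    "read_measurements_csv",
    "write_chip_csv",
    "read_chip_csv",
    "write_fasta",
    "read_fasta",
    "write_vcf",
    "read_vcf",
    "write_bed",
    "read_bed",
    "write_expression_csv",
    "read_expression_csv",
    "write_guides_tsv",
]

MEASUREMENT_COLUMNS = ["guide", "clone", "batch", "replicate", "value"]


# ----- tidy measurement / chip tables --------------------------------------


def write_measurements_csv(data: pd.DataFrame, path) -> None:
    data[MEASUREMENT_COLUMNS].to_csv(path, index=False)


def read_measurements_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    return df[MEASUREMENT_COLUMNS]


def write_chip_csv(ct: pd.DataFrame, path) -> None:
    """Tidy (sample, probe, ct) CSV from a wide samples x probes matrix."""
    tidy = ct.stack().rename("ct").rename_axis(["sample", "probe"]).reset_index()
    tidy.to_csv(path, index=False)


def read_chip_csv(path) -> pd.DataFrame:
    tidy = pd.read_csv(path)
    wide = tidy.pivot(index="sample", columns="probe", values="ct")
    wide.index.name = None
    wide.columns.name = None
    return wide


def write_expression_csv(m: ExpressionMatrix, path, meta_path=None) -> None:
    m.values.to_csv(path, index_label="sample")
    if meta_path is not None and m.sample_meta is not None:
        m.sample_meta.to_csv(meta_path, index_label="sample")


def read_expression_csv(path, meta_path=None) -> ExpressionMatrix:
    values = pd.read_csv(path, index_col="sample")
    values.index.name = None
    meta = pd.read_csv(meta_path, index_col="sample") if meta_path else None
    if meta is not None:
        meta = meta.loc[values.index]
        meta.index.name = None
    return ExpressionMatrix(values, meta)


# ----- FASTA ----------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ----- VCF (minimal: CHROM POS REF ALT, DP in INFO) -------------------------


def write_vcf(calls: list[VariantCall], path) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##INFO=<ID=EXONIC,Number=0,Type=Flag,Description="Exonic call">')
    max_pos: dict[str, int] = {}
    for c in calls:
        max_pos[c.chrom] = max(max_pos.get(c.chrom, 0), c.pos)
    for chrom, mp in sorted(max_pos.items()):
        header.contigs.add(chrom, length=mp + 1000)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt)):
            rec = vcf.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                alleles=(c.ref, c.alt),
            )
            rec.info["DP"] = c.depth
            if c.exonic:
                rec.info["EXONIC"] = True
            vcf.write(rec)


def read_vcf(path) -> list[VariantCall]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            out.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else "N",
                    depth=int(rec.info.get("DP", 0)),
                    exonic=bool(rec.info.get("EXONIC", False)),
                )
            )
    return out


# ----- BED (0-based half-open) ----------------------------------------------


def write_bed(intervals: dict[str, list[tuple[int, int]]], path) -> None:
    rows = [
        {"chrom": chrom, "start": start, "end": end}
        for chrom, ivs in sorted(intervals.items())
        for start, end in sorted(ivs)
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
    )
    out: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.chrom), []).append((int(row.start), int(row.end)))
    return out


# ----- guide candidate tables -----------------------------------------------

_GUIDE_HEADER = (
    "# coordinates: 0-based window frame; cut_pos = base immediately 5' of the "
    "blunt scission (between the 3rd and 4th nt 5' of the PAM) on the "
    "candidate strand\n"
)


def write_guides_tsv(cands, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "protospacer": c.protospacer,
                "pam": c.pam,
                "strand": c.strand,
                "protospacer_start": c.protospacer_start,
                "cut_pos": c.cut_pos,
                "gc_fraction": round(c.gc_fraction, 4),
                "snp_distance": c.snp_distance,
            }
            for c in cands
        ]
    )
    with open(path, "w") as fh:
        fh.write(_GUIDE_HEADER)
        df.to_csv(fh, sep="\t", index=False)
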