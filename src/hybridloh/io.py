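"""Readers and writers for the on-disk formats.

Internal coordinates are 1-based inclusive everywhere; BED files on disk
follow the 0-based half-open convention and are converted at this
boundary.  SNP count tables and ledgers are plain TSV with a comment
header stating the coordinate convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError

COUNTS_HEADER = "# hybridloh snp-count-table v1; coordinates 1-based inclusive"

COUNT_COLUMNS = ["chrom", "pos", "allele_W", "allele_Y", "count_W", "count_Y"]


def write_snp_counts(counts: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(COUNTS_HEADER + "\n")
        counts.to_csv(fh, sep="\t", index=False)


def read_snp_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"count table missing columns: {missing}")
    return df


def write_vcf(counts: pd.DataFrame, chromosome_lengths: dict, path,
              sample: str = "hybrid", haplotypes=("W", "Y")) -> None:
    """Emit the count table as VCF records with per-allele depths (AD)."""
    import pysam

    hapW, hapY = haplotypes
    header = pysam.VariantHeader()
    header.add_line("##source=hybridloh")
    for chrom, length in chromosome_lengths.items():
        header.contigs.add(chrom, length=int(length))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allele-specific read depths")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for _, row in counts.iterrows():
            rec = vf.new_record(contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                                alleles=(row[f"allele_{hapW}"], row[f"allele_{hapY}"]))
            rec.samples[sample]["GT"] = (0, 1)
            rec.samples[sample]["AD"] = (int(row[f"count_{hapW}"]), int(row[f"count_{hapY}"]))
            vf.write(rec)


def read_bed(path, cls_from_name: bool = True) -> pd.DataFrame:
    """Read a BED file into 1-based inclusive intervals (chrom, start, end, cls)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise InputError("BED needs at least 3 columns")
    out = pd.DataFrame({
        "chrom": df[0],
        "start": df[1].astype(np.int64) + 1,
        "end": df[2].astype(np.int64),
    })
    out["cls"] = df[3] if (cls_from_name and df.shape[1] >= 4) else ""
    return out


def write_bed(intervals: pd.DataFrame, path, name_col: str = "cls") -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    df = pd.DataFrame({
        "chrom": intervals["chrom"],
        "start": intervals["start"].astype(np.int64) - 1,
        "end": intervals["end"].astype(np.int64),
        "name": intervals[name_col] if name_col in intervals else ".",
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def write_events(events_frame: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# hybridloh loh-events v1; coordinates 1-based inclusive\n")
        events_frame.to_csv(fh, sep="\t", index=False)


def write_fasta(sequences: dict, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
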