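"""Readers and writers for the pipeline's interchange formats.

Regions travel as BED (0-based half-open, name column = region_id), counts
and most tables as TSV, sequences as FASTA (via Biopython), transcript
models as a TSV with interval-list columns encoded ``start-end;start-end``.
"""

from __future__ import annotations

import pandas as pd

from .annotation import TranscriptModel
from .region_core import REGION_COLUMNS


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ / broadPeak; column 4 (when present) becomes region_id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    if df.shape[1] >= 4:
        out["region_id"] = df.iloc[:, 3].astype(str)
    else:
        out["region_id"] = [f"region_{i + 1:05d}" for i in range(len(out))]
    if not (out["start"] < out["end"]).all():
        bad = out.index[~(out["start"] < out["end"])][0]
        raise ValueError(f"{path}: malformed coordinates at data line {bad + 1}")
    return out[REGION_COLUMNS]


def write_bed(regions: pd.DataFrame, path) -> None:
    regions[REGION_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_counts(counts, path) -> None:
    counts.counts.rename_axis("region_id").to_csv(path, sep="\t")


def read_counts(path, sample_meta=None):
    from .region_core import RegionCountMatrix, make_sample_meta

    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = sample_meta if sample_meta is not None else make_sample_meta(df.columns)
    return RegionCountMatrix(df, meta)


def write_reads(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def read_reads(path) -> pd.DataFrame:
    reads = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    required = {"chrom", "start", "strand"}
    missing = required - set(reads.columns)
    if missing:
        raise ValueError(f"{path}: read table missing column(s) {sorted(missing)}")
    return reads


def read_bam_reads(path, sample: str) -> pd.DataFrame:
    """Mapped reads from a BAM as the plain read table (requires pysam)."""
    import pysam

    rows = []
    with pysam.AlignmentFile(path, "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            rows.append(
                (aln.reference_name, aln.reference_start, aln.reference_end,
                 "-" if aln.is_reverse else "+", sample)
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "sample"])


def _encode_intervals(intervals) -> str:
    return ";".join(f"{s}-{e}" for s, e in intervals)


def _decode_intervals(text) -> list[tuple[int, int]]:
    if not isinstance(text, str) or not text:
        return []
    return [tuple(int(x) for x in part.split("-")) for part in text.split(";")]


def write_transcripts(transcripts: list[TranscriptModel], path) -> None:
    rows = [
        {
            "transcript_id": t.transcript_id, "gene_id": t.gene_id, "chrom": t.chrom,
            "strand": t.strand, "tss": t.tss, "tes": t.tes,
            "exons": _encode_intervals(t.exons),
            "utr5": _encode_intervals(t.utr5), "utr3": _encode_intervals(t.utr3),
        }
        for t in transcripts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_transcripts(path) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str}, keep_default_na=False)
    return [
        TranscriptModel(
            transcript_id=str(r["transcript_id"]), gene_id=str(r["gene_id"]),
            chrom=str(r["chrom"]), strand=str(r["strand"]),
            tss=int(r["tss"]), tes=int(r["tes"]),
            exons=_decode_intervals(r["exons"]),
            utr5=_decode_intervals(r["utr5"]), utr3=_decode_intervals(r["utr3"]),
        )
        for _, r in df.iterrows()
    ]


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.rename_axis("gene_id").to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_fasta(sequences: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=rid, description="") for rid, s in sequences.items()]
    seqio_write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def read_state_segments(path, cell_type: str = "") -> pd.DataFrame:
    """chromHMM-dialect BED: chrom, start, end, state label in column 4."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    if df.shape[1] < 4:
        raise ValueError(f"{path}: state segmentation needs 4 columns")
    out = df.iloc[:, :4].copy()
    out.columns = ["chrom", "start", "end", "state_label"]
    out["cell_type"] = cell_type
    return out
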