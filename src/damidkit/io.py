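"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA (optionally gzipped) for genomes, SAM/BAM or a 5-column BED-like TSV
for alignments, BED3/4/5 for intervals and fragment maps, bedGraph for
per-fragment signal, JSON for reports and provenance.  All interval formats
are 0-based half-open.
"""

from __future__ import annotations

import gzip
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .digest import FragmentMap, GenomeIndex

log = logging.getLogger("damidkit")

ALN_COLUMNS = ["chrom", "start", "end", "mapq", "flag"]

# SAM flag bits used by the QC filter
FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> GenomeIndex:
    with _open_text(path) as handle:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeIndex(seqs)


def write_fasta(genome: GenomeIndex, path, width: int = 80) -> None:
    with _open_text(path, "wt") as out:
        for chrom in genome.chroms:
            out.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# alignments


def read_alignments(path) -> pd.DataFrame:
    """Read alignments into a DataFrame with columns chrom,start,end,mapq,flag.

    SAM/BAM is parsed with pysam; anything else is treated as a 5-column
    BED-like TSV.  Unmapped records get chrom '*' and start/end 0.
    """
    path = Path(path)
    if path.suffix in {".sam", ".bam", ".cram"}:
        mode = "rb" if path.suffix != ".sam" else "r"
        rows = []
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
            for rec in af.fetch(until_eof=True):
                if rec.is_unmapped:
                    rows.append(("*", 0, 0, rec.mapping_quality, rec.flag))
                else:
                    rows.append(
                        (
                            rec.reference_name,
                            rec.reference_start,
                            rec.reference_end
                            if rec.reference_end is not None
                            else rec.reference_start + rec.query_length,
                            rec.mapping_quality,
                            rec.flag,
                        )
                    )
        return pd.DataFrame(rows, columns=ALN_COLUMNS)
    df = pd.read_csv(
        path, sep="\t", header=None, names=ALN_COLUMNS, comment="#", dtype={0: str}
    )
    if df[["start", "end", "mapq", "flag"]].isna().any().any():
        raise ValueError(f"malformed alignment table {path}")
    return df.astype({"start": np.int64, "end": np.int64, "mapq": int, "flag": int})


def write_alignments_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=ALN_COLUMNS)


def write_sam(df: pd.DataFrame, path, chrom_lengths: dict[str, int]) -> None:
    """Write alignments as a minimal SAM file (for interchange and tests)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, row in enumerate(df.itertuples(index=False)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i}"
            a.flag = int(row.flag)
            length = max(int(row.end) - int(row.start), 1)
            a.query_sequence = "N" * length
            a.mapping_quality = int(row.mapq)
            if row.chrom == "*" or (int(row.flag) & FLAG_UNMAPPED):
                a.is_unmapped = True
            else:
                a.reference_name = str(row.chrom)
                a.reference_start = int(row.start)
                a.cigarstring = f"{length}M"
            out.write(a)


# ---------------------------------------------------------------------------
# BED / bedGraph


def read_bed(path, value_col: str | None = None) -> pd.DataFrame:
    """Read a BED3+ file.  Malformed lines raise with their line number.

    Returns a DataFrame with chrom,start,end plus 'name' and ``value_col``
    when present.  Lines out of coordinate order are sorted with a warning.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), *parts[3:]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    ncol = max((len(r) for r in rows), default=3)
    names = ["chrom", "start", "end", "name", "score", "strand"][:ncol]
    df = pd.DataFrame(rows, columns=names)
    if value_col and "name" in df.columns and ncol == 4:
        df = df.rename(columns={"name": value_col})
        df[value_col] = df[value_col].astype(float)
    sorted_df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if not df.reset_index(drop=True).equals(sorted_df):
        log.warning("%s: intervals out of order; sorted on read", path)
    return sorted_df


def write_bed(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    cols = columns or [c for c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def fragment_map_to_bed(fmap: FragmentMap, path) -> None:
    fmap.to_dataframe().to_csv(path, sep="\t", header=False, index=False)


def fragment_map_from_bed(path, mode: str = "dpnI", bin_size: int | None = None) -> FragmentMap:
    df = read_bed(path)
    chroms = list(dict.fromkeys(df["chrom"]))
    starts = {c: df.loc[df.chrom == c, "start"].to_numpy(np.int64) for c in chroms}
    ends = {c: df.loc[df.chrom == c, "end"].to_numpy(np.int64) for c in chroms}
    return FragmentMap(chroms, starts, ends, mode=mode, bin_size=bin_size)


def write_bedgraph(fmap: FragmentMap, values: np.ndarray, path) -> None:
    """Per-fragment signal as bedGraph (variable-width intervals).

    For display the output is typically converted with
    ``wigToBigWig <bedGraph> <chrom.sizes> <out.bw>`` (external tool).
    """
    df = fmap.to_dataframe()[["chrom", "start", "end"]]
    df["value"] = np.asarray(values, dtype=float)
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bedgraph(path) -> pd.DataFrame:
    return read_bed(path, value_col="value")


def write_json(obj, path) -> None:
    with open(path, "w") as out:
        json.dump(obj, out, indent=2, sort_keys=True, default=_json_default)
        out.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
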