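"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-separated with a header row, UTF-8, no quoting, "." for
missing values.  Sequences travel as FASTA (via Biopython); intervals as BED6
(0-based half-open); SNP panels as a VCF-style TSV with columns CHROM, POS
(1-based), REF, ALT followed by one haploid call column per inbred line
("0" = reference allele, "1" = alternate allele, "." = missing).

Every reader validates the invariants of the table it loads and raises
:class:`TableFormatError` naming the file and offending row.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .windows import windows_from_labels

SPIKEIN_ID = "SPIKEIN"

__all__ = [
    "TableFormatError",
    "SnpTable",
    "SPIKEIN_ID",
    "read_fasta",
    "write_fasta",
    "read_collapsed_reads",
    "read_bed",
    "write_bed",
    "read_time_course",
    "write_time_course",
    "read_snp_tsv",
    "write_snp_tsv",
    "read_gene_classes",
    "write_gene_classes",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_kinetic_truth",
    "write_kinetic_truth",
]


class TableFormatError(ValueError):
    """A file failed validation; the message names file, row, and rule."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_collapsed_reads(path: str | Path, fmt: str = "fasta") -> list[tuple[str, int]]:
    """Read small-RNA reads as (sequence, multiplicity) pairs.

    FASTA headers may carry a collapsed count suffix (">seq1_x123"); FASTQ reads
    count one each and identical sequences are collapsed on read.
    """
    if fmt == "fasta":
        out = []
        for rec in SeqIO.parse(str(path), "fasta"):
            count = 1
            head = rec.id
            if "_x" in head:
                tail = head.rsplit("_x", 1)[1]
                if tail.isdigit():
                    count = int(tail)
            out.append((str(rec.seq).upper(), count))
        return out
    if fmt == "fastq":
        tally: dict[str, int] = {}
        for rec in SeqIO.parse(str(path), "fastq"):
            s = str(rec.seq).upper()
            tally[s] = tally.get(s, 0) + 1
        return sorted(tally.items())
    raise ValueError(f"unsupported read format {fmt!r}")


# ---------------------------------------------------------------------------
# BED6


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=_BED_COLS, comment="#", dtype={"chrom": str, "name": str})
    for i, row in df.iterrows():
        if not row["end"] > row["start"]:
            raise TableFormatError(
                f"{path}: row {i + 1}: BED interval end ({row['end']}) <= start ({row['start']})"
            )
        if row["strand"] not in ("+", "-", "."):
            raise TableFormatError(f"{path}: row {i + 1}: bad strand {row['strand']!r}")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, _BED_COLS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Gene x window tables (counts, RPTS, pri-density)


def read_time_course(path: str | Path, nonnegative: bool = True) -> pd.DataFrame:
    """Read a gene x time-window table; columns must be window labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    windows_from_labels(list(df.columns))  # validates labels and ordering
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise TableFormatError(f"{path}: row {bad!r}: missing value")
    if nonnegative and (df.to_numpy() < 0).any():
        bad = df.index[(df < 0).any(axis=1)][0]
        raise TableFormatError(f"{path}: row {bad!r}: negative value")
    return df


def write_time_course(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# SNP panel


@dataclass
class SnpTable:
    """A biallelic SNP panel with per-line haploid calls.

    ``df`` has columns chrom, pos (1-based), ref, alt; ``calls`` is an int8
    matrix (sites x lines) with 0 = ref, 1 = alt, -1 = missing; ``lines`` names
    the panel columns.
    """

    df: pd.DataFrame
    calls: np.ndarray
    lines: list[str]

    def __post_init__(self) -> None:
        if len(self.df) != self.calls.shape[0] or len(self.lines) != self.calls.shape[1]:
            raise ValueError("SnpTable dimensions inconsistent")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def site_ids(self) -> pd.Series:
        return self.df["chrom"].astype(str) + ":" + self.df["pos"].astype(str)


def read_snp_tsv(path: str | Path) -> SnpTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["CHROM", "POS", "REF", "ALT"]
    if list(df.columns[:4]) != required:
        raise TableFormatError(f"{path}: header must start with {required}, got {list(df.columns[:4])}")
    lines = list(df.columns[4:])
    if not lines:
        raise TableFormatError(f"{path}: no line call columns")
    meta = pd.DataFrame(
        {
            "chrom": df["CHROM"].astype(str),
            "pos": pd.to_numeric(df["POS"]).astype(np.int64),
            "ref": df["REF"].str.upper(),
            "alt": df["ALT"].str.upper(),
        }
    )
    for i, row in meta.iterrows():
        if row["ref"] == row["alt"]:
            raise TableFormatError(f"{path}: row {i + 2}: REF equals ALT ({row['ref']})")
        if len(row["ref"]) != 1 or len(row["alt"]) != 1:
            raise TableFormatError(f"{path}: row {i + 2}: only biallelic SNPs supported")
    raw = df[lines].to_numpy(dtype=object)
    calls = np.full(raw.shape, -1, dtype=np.int8)
    calls[raw == "0"] = 0
    calls[raw == "1"] = 1
    bad = ~np.isin(raw, ["0", "1", "."])
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise TableFormatError(
            f"{path}: row {r + 2}: bad call {raw[r, c]!r} in column {lines[c]} (expected 0, 1 or .)"
        )
    return SnpTable(df=meta, calls=calls, lines=lines)


def write_snp_tsv(snps: SnpTable, path: str | Path) -> None:
    call_strs = np.full(snps.calls.shape, ".", dtype=object)
    call_strs[snps.calls == 0] = "0"
    call_strs[snps.calls == 1] = "1"
    out = pd.DataFrame(call_strs, columns=snps.lines)
    out.insert(0, "ALT", snps.df["alt"].to_numpy())
    out.insert(0, "REF", snps.df["ref"].to_numpy())
    out.insert(0, "POS", snps.df["pos"].to_numpy())
    out.insert(0, "CHROM", snps.df["chrom"].to_numpy())
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Small named tables


def read_gene_classes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "gene_class": str})
    for col in ("gene", "gene_class"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    bad = ~df["gene_class"].isin(["maternal", "zygotic"])
    if bad.any():
        i = int(np.argwhere(bad.to_numpy())[0][0])
        raise TableFormatError(
            f"{path}: row {i + 2}: gene_class must be maternal or zygotic, got {df['gene_class'].iloc[i]!r}"
        )
    return df


def write_gene_classes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("site_id", "outgroup_allele"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    return dict(zip(df["site_id"], df["outgroup_allele"].str.upper()))


def write_ortholog_map(mapping: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"site_id": list(mapping.keys()), "outgroup_allele": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def read_kinetic_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "pulses": str})
    for col in ("gene", "a_per_h", "b", "M0", "pulses"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    return df


def write_kinetic_truth(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def parse_pulse_spec(spec: str) -> list[tuple[float, float, float]]:
    """Parse "start:end:level;start:end:level" pulse strings (empty -> no pulses)."""
    if not spec or spec == ".":
        return []
    out = []
    for piece in spec.split(";"):
        parts = piece.split(":")
        if len(parts) != 3:
            raise ValueError(f"bad pulse piece {piece!r}")
        out.append((float(parts[0]), float(parts[1]), float(parts[2])))
    return out


def format_pulse_spec(pulses: Iterable[tuple[float, float, float]]) -> str:
    pieces = [f"{s:.17g}:{e:.17g}:{lv:.17g}" for s, e, lv in pulses]
    return ";".join(pieces) if pieces else "."
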