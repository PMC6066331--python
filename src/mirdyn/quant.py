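"""Small-RNA read classification and spike-in (RPTS) normalization.

Reads are assigned to the four library-composition categories — abundant
non-coding RNA, miRNA, endo-siRNA + piRNA, and other — by sequential exact
matching against reference sequence sets without double counting.  2S rRNA
reads are removed before anything else; reads matching a spike-in oligo are
tallied separately and excluded from the categories.  Transposon-matching reads
are split by length: 21 nt = siRNA, 23-30 nt = piRNA (22 nt reads fall through
to "other").

Expression values are reported as RPTS (reads per thousand spike-in reads):
count / spike-in count x 1000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SPIKEIN_ID

__all__ = [
    "ReferenceSets",
    "CategoryCounts",
    "classify_reads",
    "count_mirna_reads",
    "rpts_normalize",
    "composition_fractions",
    "composition_summary",
]

MIN_READ_LEN, MAX_READ_LEN = 18, 30


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class ReferenceSets:
    """Reference sequences for sequential read classification."""

    rrna_2s: Sequence[str] = ()
    abundant_ncrna: Sequence[str] = ()
    mirna_arms: Mapping[str, Sequence[str]] = field(default_factory=dict)
    te_seqs: Sequence[str] = ()
    spikein_seqs: Sequence[str] = ()
    genome_seqs: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.rrna_2s = [_norm(s) for s in self.rrna_2s]
        self.abundant_ncrna = [_norm(s) for s in self.abundant_ncrna]
        self.mirna_arms = {g: [_norm(s) for s in arms] for g, arms in self.mirna_arms.items()}
        self.te_seqs = [_norm(s) for s in self.te_seqs]
        self.spikein_seqs = [_norm(s) for s in self.spikein_seqs]
        if self.genome_seqs is not None:
            self.genome_seqs = [_norm(s) for s in self.genome_seqs]
        everything = (
            set(self.rrna_2s) | set(self.abundant_ncrna) | set(self.te_seqs)
            | {s for arms in self.mirna_arms.values() for s in arms}
        )
        for sp in self.spikein_seqs:
            if any(sp in ref or ref in sp for ref in everything):
                raise ValueError("spike-in sequences must be disjoint from all other references")

    @property
    def empty(self) -> bool:
        return not (
            self.rrna_2s or self.abundant_ncrna or self.mirna_arms
            or self.te_seqs or self.spikein_seqs
        )


@dataclass
class CategoryCounts:
    """Read tallies for one library.

    The four composition categories are ``abundant_ncrna``, ``mirna``,
    ``sirna + pirna`` and ``other``; 2S rRNA, spike-in, length-filtered and
    unmatched reads are accounted for separately so that all tallies sum to the
    input read total.
    """

    abundant_ncrna: int = 0
    mirna: int = 0
    sirna: int = 0
    pirna: int = 0
    other: int = 0
    spikein: int = 0
    excluded_2s: int = 0
    length_filtered: int = 0
    unmatched: int = 0

    @property
    def sirna_pirna(self) -> int:
        return self.sirna + self.pirna

    @property
    def category_total(self) -> int:
        return self.abundant_ncrna + self.mirna + self.sirna_pirna + self.other

    @property
    def total(self) -> int:
        return (
            self.category_total + self.spikein + self.excluded_2s
            + self.length_filtered + self.unmatched
        )


def _matches(read: str, refs: Iterable[str]) -> bool:
    return any(read in ref for ref in refs)


def classify_reads(
    reads: Iterable[tuple[str, int]], refs: ReferenceSets
) -> CategoryCounts:
    """Sequentially classify collapsed reads (sequence, multiplicity) pairs.

    Matching is exact full-read substring containment in a reference sequence.
    Precedence after 2S removal and spike-in extraction: abundant ncRNA >
    miRNA > transposon > other.  When ``genome_seqs`` is supplied, "other"
    means genome-matching but category-less and the rest is ``unmatched``;
    without a genome set all residual reads count as "other".
    """
    reads = list(reads)
    if refs.empty and reads:
        raise ValueError("cannot classify reads against empty reference sets")
    arm_seqs = [s for arms in refs.mirna_arms.values() for s in arms]
    cc = CategoryCounts()
    for seq, count in reads:
        if count < 0:
            raise ValueError(f"negative read count for {seq!r}")
        s = _norm(seq)
        if not (MIN_READ_LEN <= len(s) <= MAX_READ_LEN):
            cc.length_filtered += count
            continue
        if _matches(s, refs.rrna_2s):
            cc.excluded_2s += count
        elif _matches(s, refs.spikein_seqs):
            cc.spikein += count
        elif _matches(s, refs.abundant_ncrna):
            cc.abundant_ncrna += count
        elif _matches(s, arm_seqs):
            cc.mirna += count
        elif _matches(s, refs.te_seqs):
            if len(s) == 21:
                cc.sirna += count
            elif 23 <= len(s) <= 30:
                cc.pirna += count
            else:  # 18-20 and 22 nt transposon reads carry no class label
                cc.other += count
        elif refs.genome_seqs is None:
            cc.other += count
        elif _matches(s, refs.genome_seqs):
            cc.other += count
        else:
            cc.unmatched += count
    return cc


def count_mirna_reads(
    reads: Iterable[tuple[str, int]],
    mirna_arms: Mapping[str, Sequence[str]],
    per_arm: bool = False,
) -> pd.Series:
    """Per-gene miRNA read counts (both arms summed unless ``per_arm``).

    A read matching arms of several genes is assigned to the first matching
    gene in mapping order, mirroring the no-double-counting contract.
    """
    arm_map = {g: [_norm(s) for s in arms] for g, arms in mirna_arms.items()}
    if per_arm:
        keys = [(g, i) for g, arms in arm_map.items() for i in range(len(arms))]
        tally = {k: 0 for k in keys}
        for seq, count in reads:
            s = _norm(seq)
            for g, arms in arm_map.items():
                hit = next((i for i, a in enumerate(arms) if s in a), None)
                if hit is not None:
                    tally[(g, hit)] += count
                    break
        idx = pd.MultiIndex.from_tuples(keys, names=["gene", "arm"])
        return pd.Series([tally[k] for k in keys], index=idx, name="count")
    tally = {g: 0 for g in arm_map}
    for seq, count in reads:
        s = _norm(seq)
        for g, arms in arm_map.items():
            if _matches(s, arms):
                tally[g] += count
                break
    return pd.Series(tally, name="count").rename_axis("gene")


def rpts_normalize(
    raw_counts: pd.DataFrame, spikein_counts: pd.Series | None = None
) -> pd.DataFrame:
    """Convert a gene x library count table to RPTS.

    ``spikein_counts`` gives the spike-in read count per library (column); when
    omitted, the reserved ``SPIKEIN`` row of the table is used and dropped from
    the output.  RPTS = count / spike-in x 1000; a zero or missing spike-in
    count raises an error naming the library.
    """
    counts = raw_counts
    if spikein_counts is None:
        if SPIKEIN_ID not in counts.index:
            raise ValueError(f"no spike-in counts given and no {SPIKEIN_ID!r} row present")
        spikein_counts = counts.loc[SPIKEIN_ID]
        counts = counts.drop(index=SPIKEIN_ID)
    for lib in counts.columns:
        if lib not in spikein_counts.index or not spikein_counts[lib] > 0:
            raise ValueError(f"library {lib!r} has zero or missing spike-in count")
    return counts * 1000.0 / spikein_counts.astype(float)


def composition_fractions(cc: CategoryCounts) -> dict[str, float]:
    """Fractions of the four composition categories (sum to one)."""
    total = cc.category_total
    if total == 0:
        raise ValueError("no categorized reads; fractions undefined")
    return {
        "abundant_ncrna": cc.abundant_ncrna / total,
        "mirna": cc.mirna / total,
        "sirna_pirna": cc.sirna_pirna / total,
        "other": cc.other / total,
    }


def composition_summary(replicates: Sequence[CategoryCounts]) -> pd.DataFrame:
    """Replicate mean and standard error of the mean of category fractions."""
    if not replicates:
        raise ValueError("no replicates")
    rows = [composition_fractions(cc) for cc in replicates]
    df = pd.DataFrame(rows)
    n = len(df)
    sem = df.std(ddof=1) / math.sqrt(n) if n > 1 else pd.Series(np.nan, index=df.columns)
    return pd.DataFrame({"mean": df.mean(), "sem": sem}).rename_axis("category")
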