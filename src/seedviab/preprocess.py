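"""FASTQ to raw count table: adapter trimming, collapsing, rare-read filter.

Small-RNA libraries are 3'-adapter-ligated; each read is the insert
followed by (part of) the adapter.  Trimming is exact-substring with a
terminal partial match, quality scores are ignored, and unique trimmed
sequences are collapsed into a sequence-by-sample integer count table.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import AlphabetError
from .seedcore import SEED_LENGTH, normalize_sequence

logger = logging.getLogger(__name__)

#: minimum insert length carrying a position 2-7 seed
MIN_READ_LENGTH = SEED_LENGTH + 1


@dataclass
class TrimStats:
    """Per-sample accounting of reads dropped during trimming."""

    n_reads: int = 0
    n_trimmed: int = 0
    n_untrimmed: int = 0
    n_too_short: int = 0
    n_bad_alphabet: int = 0


def read_fastq_sequences(path: str | PathLike) -> Iterator[str]:
    """Yield normalized (RNA-space) sequences from a FASTQ file.

    Gzip-compressed files are detected by the ``.gz`` suffix.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fastq"):
            yield str(record.seq)


def trim_adapter(read: str, adapter: str, min_overlap: int = 4) -> str | None:
    """Trim the 3' adapter off ``read``; return the insert or ``None``.

    Scans left to right for the leftmost position where the remainder of
    the read equals a prefix of the adapter, requiring at least
    ``min_overlap`` matching characters (a full internal adapter match
    always qualifies).  Returns ``None`` when no adapter is found or the
    trimmed insert is shorter than 7 nt; untrimmable reads are counted by
    the caller, never raised.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n = len(read)
    for i in range(n - min_overlap + 1):
        k = min(len(adapter), n - i)
        if read[i : i + k] == adapter[:k]:
            return read[:i] if i >= MIN_READ_LENGTH else None
    return None


def trim_sample(
    reads: Iterable[str], adapter: str, min_overlap: int = 4
) -> tuple[list[str], TrimStats]:
    """Normalize and adapter-trim one sample's reads, with accounting."""
    adapter = normalize_sequence(adapter)
    stats = TrimStats()
    kept: list[str] = []
    for read in reads:
        stats.n_reads += 1
        try:
            norm = normalize_sequence(read)
        except AlphabetError:
            stats.n_bad_alphabet += 1
            continue
        insert = trim_adapter(norm, adapter, min_overlap)
        if insert is None:
            # distinguishes adapter-dimers (insert too short) from no-adapter reads
            if any(
                norm[i : i + min(len(adapter), len(norm) - i)]
                == adapter[: min(len(adapter), len(norm) - i)]
                for i in range(len(norm) - min_overlap + 1)
            ):
                stats.n_too_short += 1
            else:
                stats.n_untrimmed += 1
            continue
        stats.n_trimmed += 1
        kept.append(insert)
    return kept, stats


def collapse_counts(sample_reads: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Collapse per-sample read multisets into a sequence-by-sample table.

    One row per distinct sequence across all samples; deterministic row
    order: descending total count, then lexicographic sequence.
    """
    if not sample_reads:
        raise ValueError("at least one sample is required")
    counters = {sample: Counter(reads) for sample, reads in sample_reads.items()}
    for sample, counter in counters.items():
        if not counter:
            logger.warning("sample %s contributed zero reads; zero column retained", sample)
    table = pd.DataFrame(counters).fillna(0).astype(int)
    table = table.reindex(columns=list(sample_reads))
    table.index.name = "sequence"
    return sort_count_table(table)


def sort_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Canonical row order: descending total count, sequence tie-break."""
    totals = table.sum(axis=1)
    order = sorted(table.index, key=lambda s: (-totals[s], s))
    return table.loc[order]


def filter_rare(table: pd.DataFrame, min_total: int = 6) -> pd.DataFrame:
    """Drop rows whose total count across samples is below ``min_total``.

    The threshold is inclusive (total >= min_total is kept) and applies to
    the all-sample total, not per-sample counts.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.sum(axis=1) >= min_total
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_rare removed %d rows with total < %d", n_removed, min_total)
    return table.loc[keep]


def fastq_to_counts(
    fastq_paths: Mapping[str, str | PathLike],
    adapter: str,
    min_overlap: int = 4,
    min_total: int = 6,
) -> tuple[pd.DataFrame, dict[str, TrimStats]]:
    """Full preprocessing: read, trim, collapse and rare-filter per-sample FASTQ."""
    trimmed: dict[str, list[str]] = {}
    stats: dict[str, TrimStats] = {}
    for sample, path in fastq_paths.items():
        trimmed[sample], stats[sample] = trim_sample(
            read_fastq_sequences(path), adapter, min_overlap
        )
        s = stats[sample]
        logger.info(
            "sample %s: %d reads, %d trimmed, %d untrimmed, %d too short",
            sample, s.n_reads, s.n_trimmed, s.n_untrimmed, s.n_too_short,
        )
    return filter_rare(collapse_counts(trimmed), min_total), stats


def write_count_table(table: pd.DataFrame, path: str | PathLike) -> None:
    """Write a count table as TSV (first column ``sequence``)."""
    table.to_csv(path, sep="\t", float_format="%.10g")


def read_count_table(path: str | PathLike) -> pd.DataFrame:
    """Read and validate a sequence-by-sample count table TSV."""
    table = pd.read_csv(path, sep="\t", index_col="sequence")
    seqs = [normalize_sequence(s) for s in table.index.astype(str)]
    table.index = pd.Index(seqs, name="sequence")
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"duplicate sequence row {dup!r} in {path}")
    if (table.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    return table
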