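"""Read preparation: adapter trimming, size parsing, dereplication.

Small-RNA libraries sequence a short insert followed by the 3' adapter, so
the insert is recovered by locating the leftmost exact occurrence of an
adapter prefix.  Reads whose trimmed insert falls in the small-RNA window
(default 18-25 nt) are kept and collapsed to unique sequences with
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 25


@dataclass
class PrepReport:
    """Per-library bookkeeping for the preparation stage.

    ``srna_fraction`` is the fraction of input reads whose trimmed insert
    falls in the small-RNA size window; it is 0 with ``empty=True`` when
    the library had no reads at all.
    """

    total_reads: int = 0
    adapter_trimmed: int = 0
    size_passing: int = 0
    empty: bool = False

    @property
    def srna_fraction(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return self.size_passing / self.total_reads

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "adapter_trimmed": self.adapter_trimmed,
            "size_passing": self.size_passing,
            "srna_fraction": self.srna_fraction,
            "empty": self.empty,
        }


def trim_adapter(read: str, adapter: str, min_overlap: int = 5) -> str:
    """Truncate ``read`` at the leftmost exact match of an adapter prefix.

    The match may be the full adapter (internal occurrence) or a prefix of
    length >= ``min_overlap`` ending at the 3' end of the read (adapter
    running off the read).  No mismatches are tolerated.  Returns the read
    unchanged when no such occurrence exists; an empty read trims to the
    empty string.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not read:
        return ""
    n = len(read)
    full = read.find(adapter)
    if full != -1:
        return read[:full]
    # partial adapter at the 3' end only: overlap length limited by both
    # the remaining read suffix and the adapter itself
    best = None
    max_ov = min(len(adapter) - 1, n)
    for start in range(n - min_overlap, -1, -1):
        ov = n - start
        if ov > max_ov:
            break
        if read[start:] == adapter[:ov]:
            best = start
    if best is not None:
        return read[:best]
    return read


def parse_size(
    reads: Iterable[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[str], PrepReport]:
    """Keep reads with length in ``[min_len, max_len]``; count the rest."""
    kept: list[str] = []
    report = PrepReport()
    for read in reads:
        report.total_reads += 1
        if min_len <= len(read) <= max_len:
            kept.append(read)
            report.size_passing += 1
    report.empty = report.total_reads == 0
    return kept, report


def dereplicate(reads: Iterable[str], sample_id: str | None = None) -> pd.DataFrame:
    """Collapse identical sequences into (sequence, frequency) rows.

    Total frequency is conserved: it equals the number of input reads.
    Rows are sorted by descending frequency, then sequence, for determinism.
    """
    counts: dict[str, int] = {}
    for seq in reads:
        counts[seq] = counts.get(seq, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["sequence", "frequency"],
    )
    if sample_id is not None:
        table["sample_id"] = sample_id
    return table


def prepare_fastq(
    fastq_path: str | Path,
    adapter: str,
    min_overlap: int = 5,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    sample_id: str | None = None,
) -> tuple[pd.DataFrame, PrepReport]:
    """FASTQ -> dereplicated small-RNA table + :class:`PrepReport`."""
    report = PrepReport()
    kept: list[str] = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        report.total_reads += 1
        raw = str(rec.seq).upper()
        trimmed = trim_adapter(raw, adapter, min_overlap)
        if len(trimmed) < len(raw):
            report.adapter_trimmed += 1
        if min_len <= len(trimmed) <= max_len:
            kept.append(trimmed)
            report.size_passing += 1
    report.empty = report.total_reads == 0
    return dereplicate(kept, sample_id=sample_id), report
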