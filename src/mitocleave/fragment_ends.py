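"""Fragment end reconstruction from alignments and per-junction event counting.

Short-read libraries: a properly-paired fragment is reconstructed from the
leftmost mate as the outer span ``[POS, POS + TLEN - 1]`` (1-based inclusive),
so the unsequenced inner gap of a pair counts as covered.  Long reads: one
fragment per retained read, ``[POS, POS + reference-consumed CIGAR length - 1]``.

Per-junction event counts (junction ``s`` = bond between positions ``s-1``
and ``s``):

* ``n_start[s]``       fragments starting exactly at ``s``
* ``n_end_before[s]``  fragments ending exactly at ``s-1``
* ``n_span[s]``        fragments with start <= s-1 and end >= s

A fragment contributes to at most one of the three at any junction; their sum
is the total coverage of the junction (fragments touching the bond from either
side).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .annotation import MT_CONTIG_NAMES, MT_LENGTH


class ContigMismatchError(ValueError):
    """Alignment record on a contig other than the expected mitochondrial one."""


@dataclass
class FragmentEndTable:
    """Per-fragment start/end coordinates for one sample (1-based inclusive)."""

    sample_id: str
    start: np.ndarray
    end: np.ndarray
    source: str = "short_read"  # or "long_read"
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if self.start.shape != self.end.shape:
            raise ValueError("start/end length mismatch")
        if self.start.size and (
            np.any(self.start > self.end) or np.any(self.start < 1)
        ):
            raise ValueError("invalid fragment coordinates")

    def __len__(self) -> int:
        return self.start.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_id, "start": self.start, "end": self.end}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, source: str = "short_read") -> "FragmentEndTable":
        df = pd.read_csv(path, sep="\t")
        sample = str(df["sample_id"].iloc[0]) if len(df) else Path(path).stem
        return cls(sample, df["start"].to_numpy(), df["end"].to_numpy(), source=source)


def _check_contig(name: str | None, contig: str | None) -> None:
    if name is None:
        return
    accepted = {contig} if contig else MT_CONTIG_NAMES
    if name not in accepted:
        raise ContigMismatchError(
            f"alignment on contig {name!r}; expected {sorted(accepted)}"
        )


def _open_alignments(alignments):
    if isinstance(alignments, (str, Path)):
        return pysam.AlignmentFile(str(alignments), check_sq=False), True
    return alignments, False


def extract_short_read_ends(
    alignments,
    sample_id: str | None = None,
    require_proper_pair: bool = True,
    unique_mapq: int | None = 255,
    max_insert: int | None = None,
    contig: str | None = None,
    genome_length: int = MT_LENGTH,
) -> FragmentEndTable:
    """Reconstruct fragments from paired-end alignments (one row per fragment).

    Each properly paired, uniquely mapped leftmost mate (TLEN > 0) yields the
    fragment ``[POS, POS + TLEN - 1]``.  Secondary/supplementary/unmapped
    records and the rightmost mates are skipped; paired records with TLEN == 0
    and fragments running past the contig end (circular-origin pairs) are
    skipped and tallied in the QC dict.

    ``unique_mapq`` is the aligner's unique-mapping quality (255 for STAR);
    ``None`` disables the uniqueness filter.
    """
    stream, close = _open_alignments(alignments)
    qc = {
        "records": 0,
        "unmapped": 0,
        "secondary_supplementary": 0,
        "not_proper_pair": 0,
        "not_unique": 0,
        "tlen_zero": 0,
        "mate_counted": 0,
        "too_long": 0,
        "past_contig_end": 0,
        "fragments": 0,
    }
    starts: list[int] = []
    ends: list[int] = []
    try:
        for read in stream.fetch(until_eof=True):
            qc["records"] += 1
            if read.is_unmapped:
                qc["unmapped"] += 1
                continue
            _check_contig(read.reference_name, contig)
            if read.is_secondary or read.is_supplementary:
                qc["secondary_supplementary"] += 1
                continue
            if require_proper_pair and not read.is_proper_pair:
                qc["not_proper_pair"] += 1
                continue
            if unique_mapq is not None and read.mapping_quality != unique_mapq:
                qc["not_unique"] += 1
                continue
            tlen = read.template_length
            if tlen < 0:
                qc["mate_counted"] += 1
                continue
            if tlen == 0:
                qc["tlen_zero"] += 1
                continue
            if max_insert is not None and tlen > max_insert:
                qc["too_long"] += 1
                continue
            start = read.reference_start + 1  # pysam is 0-based
            end = start + tlen - 1
            if end > genome_length:
                qc["past_contig_end"] += 1
                continue
            starts.append(start)
            ends.append(end)
    finally:
        if close:
            stream.close()
    qc["fragments"] = len(starts)
    if sample_id is None:
        sample_id = getattr(stream, "filename", b"sample")
        sample_id = Path(
            sample_id.decode() if isinstance(sample_id, bytes) else str(sample_id)
        ).stem
    return FragmentEndTable(sample_id, np.array(starts, dtype=np.int64),
                            np.array(ends, dtype=np.int64), "short_read", qc)


def extract_long_read_ends(
    alignments,
    sample_id: str | None = None,
    min_mapq: int = 30,
    competing_mapq: dict[str, int] | None = None,
    contig: str | None = None,
    genome_length: int = MT_LENGTH,
) -> FragmentEndTable:
    """One fragment per retained long read, ends from the CIGAR reference span.

    Keeps primary alignments with MAPQ strictly greater than ``min_mapq`` and
    no supplementary segments elsewhere in the mitochondrial genome (SA tag).
    ``competing_mapq`` maps read name -> best nuclear mapping quality; reads
    with a nuclear alignment of equal or greater MAPQ are removed.  When the
    table is absent that filter is skipped with a warning (a single-contig
    stream cannot self-detect nuclear hits).
    """
    stream, close = _open_alignments(alignments)
    if competing_mapq is None:
        warnings.warn(
            "no nuclear competing-alignment table supplied; "
            "skipping the nuclear-MAPQ filter",
            stacklevel=2,
        )
    qc = {
        "records": 0,
        "unmapped": 0,
        "secondary_supplementary": 0,
        "low_mapq": 0,
        "split_alignment": 0,
        "nuclear_competitor": 0,
        "missing_cigar": 0,
        "fragments": 0,
    }
    starts: list[int] = []
    ends: list[int] = []
    try:
        for read in stream.fetch(until_eof=True):
            qc["records"] += 1
            if read.is_unmapped:
                qc["unmapped"] += 1
                continue
            _check_contig(read.reference_name, contig)
            if read.is_secondary or read.is_supplementary:
                qc["secondary_supplementary"] += 1
                continue
            if read.mapping_quality <= min_mapq:
                qc["low_mapq"] += 1
                continue
            if read.has_tag("SA"):
                qc["split_alignment"] += 1
                continue
            if (
                competing_mapq is not None
                and competing_mapq.get(read.query_name, -1) >= read.mapping_quality
            ):
                qc["nuclear_competitor"] += 1
                continue
            if read.cigartuples is None:
                qc["missing_cigar"] += 1
                continue
            start = read.reference_start + 1
            end = read.reference_end  # 0-based exclusive == 1-based inclusive
            if end is None:
                qc["missing_cigar"] += 1
                continue
            starts.append(start)
            ends.append(min(end, genome_length))
    finally:
        if close:
            stream.close()
    qc["fragments"] = len(starts)
    if sample_id is None:
        sample_id = "long_read_sample"
    return FragmentEndTable(sample_id, np.array(starts, dtype=np.int64),
                            np.array(ends, dtype=np.int64), "long_read", qc)


@dataclass
class SiteEventCounts:
    """Per-junction start/end/span counts; arrays indexed by junction coordinate.

    Index 0 and 1 are padding (junctions live in ``[2, L]``).
    """

    sample_id: str
    n_start: np.ndarray
    n_end_before: np.ndarray
    n_span: np.ndarray
    genome_length: int

    @property
    def coverage(self) -> np.ndarray:
        """Total fragments across each junction (processed + spanning)."""
        return self.n_start + self.n_end_before + self.n_span

    @property
    def junctions(self) -> np.ndarray:
        return np.arange(2, self.genome_length + 1)


def count_site_events(
    table: FragmentEndTable, genome_length: int = MT_LENGTH
) -> SiteEventCounts:
    """Tabulate per-junction start/end-before/span counts for one sample.

    Linear-time: start and end histograms plus prefix sums give, for junction
    ``s``, ``n_span[s] = #{start <= s-1} - #{end <= s-1}`` (every fragment with
    end <= s-1 also started at or before s-1).
    """
    L = genome_length
    size = L + 2
    starts = table.start
    ends = table.end
    if starts.size and (starts.min() < 1 or ends.max() > L):
        raise ValueError("fragment coordinates outside [1, genome_length]")
    start_hist = np.bincount(starts, minlength=size)[:size]
    end_hist = np.bincount(ends, minlength=size)[:size]

    n_start = start_hist.copy()
    n_start[:2] = 0  # a start at position 1 touches no junction

    n_end_before = np.zeros(size, dtype=np.int64)
    n_end_before[1:] = end_hist[:-1]  # end == s-1
    n_end_before[:2] = 0

    cum_start = np.cumsum(start_hist)
    cum_end = np.cumsum(end_hist)
    n_span = np.zeros(size, dtype=np.int64)
    # n_span[s] = starts<=s-1 minus ends<=s-1, for s in [2, L]
    s = np.arange(2, L + 1)
    n_span[s] = cum_start[s - 1] - cum_end[s - 1]

    return SiteEventCounts(
        table.sample_id,
        n_start[: L + 1],
        n_end_before[: L + 1],
        n_span[: L + 1],
        L,
    )
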