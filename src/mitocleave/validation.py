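"""Orthogonal-platform validation of candidate cleavage sites.

Three independent checks are supported:

* replication of the discovery site list in an independent cohort processed
  with identical parameters;
* the ribo-depleted-library rule: a site is supported if *any* sample shows a
  cleavage ratio above 10% at *any* junction within 3 bp of it;
* the long-read rule: read start/end positions with heavy support
  (>= 200 reads and in the top 1/50 of positions genome-wide) are taken as
  transcript termini, and a site is supported when a terminus lies within
  3 bp.  Direct-RNA nanopore libraries truncate mitochondrial transcripts
  10-15 bp downstream of gene 5' ends, so sites within 3 bp of those windows
  are masked before the long-read comparison.

A site counts as validated overall when it passes the ribo-depleted rule or
the (truncation-masked) long-read rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRecord, coding_genes
from .cleavage_ratio import CleavageRatioTrack

MATCH_WINDOW = 3
LONG_READ_MIN_SUPPORT = 200
LONG_READ_TOP_FRACTION = 1.0 / 50.0
TRUNCATION_OFFSETS = (10, 15)


def _junctions(sites: Iterable) -> list[int]:
    out = []
    for s in sites:
        out.append(int(getattr(s, "junction", s)))
    return out


def replicate_sites(
    discovery_sites: Sequence,
    replication_sites: Sequence,
    match_window: int = 0,
) -> list[int]:
    """Discovery junctions with a replication junction within ``match_window`` bp."""
    disc = _junctions(discovery_sites)
    rep = np.asarray(sorted(_junctions(replication_sites)), dtype=np.int64)
    if rep.size == 0:
        return []
    out = []
    for j in disc:
        i = np.searchsorted(rep, j)
        near = [rep[k] for k in (i - 1, i) if 0 <= k < rep.size]
        if near and min(abs(j - r) for r in near) <= match_window:
            out.append(j)
    return out


def validate_ratio_threshold(
    sites: Sequence,
    sample_tracks: Sequence[CleavageRatioTrack],
    threshold: float = 0.10,
    window: int = MATCH_WINDOW,
) -> dict[int, bool]:
    """Site validated iff ANY sample has ratio > threshold at ANY junction
    within ``window`` bp of the site."""
    flags: dict[int, bool] = {}
    if not sample_tracks:
        return {j: False for j in _junctions(sites)}
    L = sample_tracks[0].genome_length
    for j in _junctions(sites):
        lo, hi = max(2, j - window), min(L, j + window)
        ok = False
        for t in sample_tracks:
            seg = t.ratio[lo : hi + 1]
            with np.errstate(invalid="ignore"):
                if np.any(seg > threshold):
                    ok = True
                    break
        flags[j] = ok
    return flags


def long_read_terminal_sites(
    profile: np.ndarray,
    min_support: int = LONG_READ_MIN_SUPPORT,
    top_fraction: float = LONG_READ_TOP_FRACTION,
) -> np.ndarray:
    """Positions that are heavily-supported long-read termini.

    ``profile`` is a 1-based array (index = reference position; index 0 is
    padding) of pooled read start + end counts.  A position qualifies when its
    support is at least ``min_support`` AND at least the ``1 - top_fraction``
    quantile of support over all genome positions (ties at the quantile kept).
    """
    support = np.asarray(profile, dtype=np.int64)
    values = support[1:]  # all L genome positions, including zero-support ones
    q = np.quantile(values, 1.0 - top_fraction)
    keep = (support >= min_support) & (support >= q)
    keep[0] = False
    return np.flatnonzero(keep)


def validate_long_read(
    sites: Sequence,
    terminal_sites: np.ndarray,
    window: int = MATCH_WINDOW,
) -> dict[int, bool]:
    """Site validated iff any terminal position lies within ``window`` bp.

    A cleavage at junction ``s`` leaves termini at positions ``s-1`` (upstream
    3' end) and ``s`` (downstream 5' start); distance is measured to the
    nearer of the two anchors.
    """
    term = np.asarray(sorted(terminal_sites), dtype=np.int64)
    flags: dict[int, bool] = {}
    for j in _junctions(sites):
        if term.size == 0:
            flags[j] = False
            continue
        i = np.searchsorted(term, j)
        near = [term[k] for k in (i - 2, i - 1, i, i + 1) if 0 <= k < term.size]
        d = min(min(abs(p - j), abs(p - (j - 1))) for p in near)
        flags[j] = bool(d <= window)
    return flags


def truncation_intervals(
    genes: Sequence[GeneRecord],
    offset_range: tuple[int, int] = TRUNCATION_OFFSETS,
) -> list[tuple[int, int]]:
    """Strand-aware [5' end + 10, 5' end + 15] intervals for every gene."""
    lo_off, hi_off = offset_range
    out = []
    for g in coding_genes(genes):
        if g.strand == "+":
            out.append((g.start + lo_off, g.start + hi_off))
        else:
            out.append((g.end - hi_off, g.end - lo_off))
    return out


def mask_truncation_regions(
    sites: Sequence,
    genes: Sequence[GeneRecord],
    offset_range: tuple[int, int] = TRUNCATION_OFFSETS,
    window: int = MATCH_WINDOW,
) -> list[int]:
    """Remove sites within ``window`` bp of any nanopore truncation interval."""
    intervals = truncation_intervals(genes, offset_range)
    kept = []
    for j in _junctions(sites):
        masked = any(lo - window <= j <= hi + window for lo, hi in intervals)
        if not masked:
            kept.append(j)
    return kept


@dataclass
class ValidationReport:
    """Per-site validation flags; overall = ribo-depleted OR masked long-read."""

    table: pd.DataFrame

    @property
    def n_validated(self) -> int:
        return int(self.table["overall_validated"].sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def build_validation_report(
    sites: Sequence,
    replication_sites: Sequence | None = None,
    rrna_depleted_tracks: Sequence[CleavageRatioTrack] | None = None,
    long_read_profile: np.ndarray | None = None,
    genes: Sequence[GeneRecord] | None = None,
    threshold: float = 0.10,
    window: int = MATCH_WINDOW,
    match_window: int = 0,
    min_support: int = LONG_READ_MIN_SUPPORT,
    top_fraction: float = LONG_READ_TOP_FRACTION,
) -> ValidationReport:
    """Assemble all validation flags for a site list (absent inputs -> False)."""
    junctions = _junctions(sites)
    replicated = set(
        replicate_sites(junctions, replication_sites, match_window)
        if replication_sites is not None
        else []
    )
    rrna = (
        validate_ratio_threshold(junctions, rrna_depleted_tracks, threshold, window)
        if rrna_depleted_tracks
        else {j: False for j in junctions}
    )
    if long_read_profile is not None:
        term = long_read_terminal_sites(long_read_profile, min_support, top_fraction)
        lr = validate_long_read(junctions, term, window)
    else:
        lr = {j: False for j in junctions}
    unmasked = set(
        mask_truncation_regions(junctions, genes, window=window)
        if genes is not None
        else junctions
    )
    rows = []
    for j in junctions:
        masked = j not in unmasked
        lr_ok = bool(lr[j]) and not masked
        rows.append(
            {
                "junction": j,
                "replicated": j in replicated,
                "rrna_depleted": bool(rrna[j]),
                "long_read": lr_ok,
                "truncation_masked": masked,
                "overall_validated": bool(rrna[j]) or lr_ok,
            }
        )
    return ValidationReport(pd.DataFrame(rows))
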