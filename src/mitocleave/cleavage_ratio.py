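"""The cleavage-ratio statistic.

For a junction ``s`` the cleavage ratio is the fraction of fragments touching
the junction that are *processed* there -- i.e. start exactly at ``s`` or end
exactly at ``s-1`` -- out of all fragments across the junction (processed plus
spanning).  Read ends stack at genuine transcript termini, so junctions where
the polycistronic precursor is cleaved show elevated ratios relative to the
random library-fragmentation baseline.

Undefined ratios (zero coverage) propagate as NaN, never as 0, so downstream
presence filters can distinguish no-signal from no-data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fragment_ends import SiteEventCounts


@dataclass
class CleavageRatioTrack:
    """Per-junction cleavage ratio and coverage for one sample.

    Arrays are indexed by junction coordinate (indices 0-1 are padding; valid
    junctions are ``[2, L]``).  ``ratio`` is NaN wherever coverage is 0.
    """

    sample_id: str
    ratio: np.ndarray
    coverage: np.ndarray
    genome_length: int

    @property
    def junctions(self) -> np.ndarray:
        return np.arange(2, self.genome_length + 1)

    def defined(self) -> np.ndarray:
        """Boolean mask (junction-indexed) of junctions with defined ratio."""
        return ~np.isnan(self.ratio)

    def to_frame(self, drop_undefined: bool = True) -> pd.DataFrame:
        j = self.junctions
        df = pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "junction": j,
                "ratio": self.ratio[j],
                "coverage": self.coverage[j],
            }
        )
        if drop_undefined:
            df = df[df["ratio"].notna()].reset_index(drop=True)
        return df

    def to_tsv(self, path: str | Path, drop_undefined: bool = True) -> None:
        self.to_frame(drop_undefined).to_csv(path, sep="\t", index=False)

    def to_bedgraph(self, path: str | Path, contig: str = "MT") -> None:
        """Junction s -> 0-based half-open interval [s-1, s)."""
        with open(path, "w") as fh:
            for j in self.junctions:
                r = self.ratio[j]
                if not np.isnan(r):
                    fh.write(f"{contig}\t{j - 1}\t{j}\t{r:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, genome_length: int) -> "CleavageRatioTrack":
        df = pd.read_csv(path, sep="\t")
        ratio = np.full(genome_length + 1, np.nan)
        coverage = np.zeros(genome_length + 1, dtype=np.int64)
        j = df["junction"].to_numpy()
        ratio[j] = df["ratio"].to_numpy()
        coverage[j] = df["coverage"].to_numpy()
        sample = str(df["sample_id"].iloc[0]) if len(df) else Path(path).stem
        return cls(sample, ratio, coverage, genome_length)


def compute_ratio_track(counts: SiteEventCounts) -> CleavageRatioTrack:
    """ratio[s] = (n_start[s] + n_end_before[s]) / coverage[s]; NaN at coverage 0."""
    processed = (counts.n_start + counts.n_end_before).astype(float)
    coverage = counts.coverage
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = processed / coverage
    ratio[coverage == 0] = np.nan
    ratio[:2] = np.nan
    return CleavageRatioTrack(
        counts.sample_id, ratio, coverage, counts.genome_length
    )
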