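"""Candidate cleavage-site discovery across a cohort of ratio tracks.

Per-sample detection (ratio > 0.1 at >= 20x coverage), transitive merging of
nearby detections (within 5 bp, keeping the highest-ratio junction as the
peak), a cross-sample presence filter (peak present in >= 50% of samples with
data at the site), an empirical background model from random junctions far
from gene boundaries, and a one-sided Welch t-test of each gene boundary's
peak ratios against that background with Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import BoundaryRegion
from .cleavage_ratio import CleavageRatioTrack

RATIO_THRESHOLD = 0.1
MIN_COVERAGE = 20
MERGE_WINDOW = 5
MIN_PRESENCE = 0.5
PEAK_WINDOW = 3  # +/- bp used for boundary/background peak extraction


@dataclass
class CandidateSite:
    """A merged, cross-sample-filtered putative cleavage site."""

    junction: int
    representative_ratio: float
    per_sample: pd.DataFrame  # sample_id, ratio, coverage, detected
    presence_fraction: float
    cluster: tuple[int, ...] = ()
    classification: str | None = None
    boundary_distance: int | None = None
    provenance: str = "discovery"

    @property
    def mean_coverage(self) -> float:
        return float(self.per_sample["coverage"].mean())


@dataclass
class BackgroundModel:
    """Pooled per-site-per-sample peak ratios at junctions far from boundaries."""

    mean: float
    sd: float
    pool: np.ndarray
    n_sites: int
    min_dist: int | None = None


@dataclass
class BoundaryTestResult:
    boundary: BoundaryRegion
    peak_junction: int
    boundary_ratios: np.ndarray
    t: float
    p: float
    significant: bool
    alpha_corrected: float


# ---------------------------------------------------------------------------


def detect_sample_sites(
    track: CleavageRatioTrack,
    ratio_threshold: float = RATIO_THRESHOLD,
    min_coverage: int = MIN_COVERAGE,
) -> np.ndarray:
    """Junctions with defined ratio > threshold and coverage >= min_coverage."""
    with np.errstate(invalid="ignore"):
        mask = (track.ratio > ratio_threshold) & (track.coverage >= min_coverage)
    mask[:2] = False
    return np.flatnonzero(mask)


def merge_peaks(
    junctions: Sequence[int],
    ratios: Mapping[int, float] | np.ndarray,
    window: int = MERGE_WINDOW,
) -> list[tuple[int, tuple[int, ...]]]:
    """Transitively cluster junctions within ``window`` bp; keep the peak.

    Chain rule: a-b and b-c each within the window merge all three.  Each
    cluster is represented by its highest-ratio junction (ties broken toward
    the lower coordinate).  Returns ``(representative, cluster_members)``
    pairs sorted by representative.
    """
    junctions = np.sort(np.asarray(list(junctions), dtype=np.int64))
    if junctions.size == 0:
        return []
    get = lambda j: float(ratios[j])  # noqa: E731  (works for dict and array)
    breaks = np.flatnonzero(np.diff(junctions) > window)
    out = []
    for cluster in np.split(junctions, breaks + 1):
        vals = np.array([get(j) for j in cluster])
        rep = int(cluster[int(np.argmax(vals))])  # argmax -> first/lowest on ties
        out.append((rep, tuple(int(j) for j in cluster)))
    return out


def cross_sample_filter(
    tracks: Sequence[CleavageRatioTrack],
    ratio_threshold: float = RATIO_THRESHOLD,
    min_coverage: int = MIN_COVERAGE,
    merge_window: int = MERGE_WINDOW,
    min_presence: float = MIN_PRESENCE,
    provenance: str = "discovery",
) -> list[CandidateSite]:
    """Detect per sample, merge the cohort union of detections, filter by presence.

    A sample "has" a merged peak if any junction of the peak's cluster was
    detected in that sample; the presence denominator is the number of samples
    with a defined ratio at the representative junction.  The merge score of a
    junction is its cohort mean ratio over samples where it is defined.
    """
    if not tracks:
        raise ValueError("cross_sample_filter requires at least one sample")
    L = tracks[0].genome_length
    detections = [set(map(int, detect_sample_sites(t, ratio_threshold, min_coverage)))
                  for t in tracks]
    union = sorted(set().union(*detections))
    if not union:
        return []
    ratio_stack = np.stack([t.ratio for t in tracks])  # samples x (L+1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_ratio = np.nanmean(ratio_stack, axis=0)
    sites = []
    sample_ids = [t.sample_id for t in tracks]
    for rep, cluster in merge_peaks(union, mean_ratio, merge_window):
        detected = np.array(
            [bool(det.intersection(cluster)) for det in detections]
        )
        defined = ~np.isnan(ratio_stack[:, rep])
        denom = int(defined.sum())
        if denom == 0:
            continue
        presence = float(detected[defined].sum()) / denom
        if presence < min_presence:
            continue
        per_sample = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "ratio": ratio_stack[:, rep],
                "coverage": [int(t.coverage[rep]) for t in tracks],
                "detected": detected,
            }
        )
        sites.append(
            CandidateSite(
                junction=rep,
                representative_ratio=float(mean_ratio[rep]),
                per_sample=per_sample,
                presence_fraction=presence,
                cluster=cluster,
                provenance=provenance,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Background model and boundary tests


def _window_peak_ratios(
    tracks: Sequence[CleavageRatioTrack], junction: int, window: int
) -> np.ndarray:
    """Per-sample max defined ratio within +/- window bp of a junction (NaN if none)."""
    L = tracks[0].genome_length
    lo = max(2, junction - window)
    hi = min(L, junction + window)
    out = np.full(len(tracks), np.nan)
    for i, t in enumerate(tracks):
        seg = t.ratio[lo : hi + 1]
        if np.any(~np.isnan(seg)):
            out[i] = np.nanmax(seg)
    return out


def estimate_background(
    tracks: Sequence[CleavageRatioTrack],
    background_sites: Iterable[int],
    window: int = PEAK_WINDOW,
    min_dist: int | None = None,
) -> BackgroundModel:
    """Pool per-site-per-sample peak ratios (max within +/- window, mirroring
    the boundary procedure) across background sites and samples."""
    background_sites = list(background_sites)
    if not tracks or not background_sites:
        raise ValueError("need at least one track and one background site")
    pools = [
        _window_peak_ratios(tracks, s, window) for s in background_sites
    ]
    pool = np.concatenate(pools)
    pool = pool[~np.isnan(pool)]
    if pool.size == 0:
        raise ValueError("all background ratios are undefined")
    sd = float(np.std(pool, ddof=1)) if pool.size > 1 else 0.0
    return BackgroundModel(
        float(pool.mean()), sd, pool, len(background_sites), min_dist
    )


def one_sided_welch_greater(
    sample_a: np.ndarray, sample_b: np.ndarray
) -> tuple[float, float]:
    """Welch t-test of H1: mean(a) > mean(b), degenerate variance handled.

    With zero variance in both groups the t statistic is undefined; by
    convention p = 0.0 when mean(a) > mean(b) and p = 1.0 otherwise (no
    evidence), with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        warnings.warn("zero variance in both groups; degenerate t-test", stacklevel=2)
        if a.mean() > b.mean():
            return np.inf, 0.0
        return -np.inf if a.mean() < b.mean() else 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(t), float(p)


def boundary_test(
    boundary: BoundaryRegion,
    tracks: Sequence[CleavageRatioTrack],
    background: BackgroundModel,
    n_boundaries_for_correction: int = 28,
    alpha: float = 0.05,
) -> BoundaryTestResult:
    """One-sided test that a gene boundary's peak ratios exceed background.

    Per sample, the maximum defined ratio within the boundary window is taken
    as the boundary's cleavage ratio; those per-sample values are compared
    against the pooled background ratios with a one-sided Welch t-test, and
    significance is assessed at ``alpha / n_boundaries_for_correction``.
    """
    lo, hi = boundary.window
    half = max(boundary.junction_site - lo, hi - boundary.junction_site)
    vals = _window_peak_ratios(tracks, boundary.junction_site, half)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError(
            f"boundary {boundary.junction_site}: fewer than 2 defined ratios"
        )
    # peak junction: cohort-mean argmax within the window
    L = tracks[0].genome_length
    wlo, whi = max(2, lo), min(L, hi)
    stack = np.stack([t.ratio[wlo : whi + 1] for t in tracks])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_prof = np.nanmean(stack, axis=0)
    peak = wlo + int(np.nanargmax(mean_prof)) if np.any(~np.isnan(mean_prof)) else boundary.junction_site
    t, p = one_sided_welch_greater(vals, background.pool)
    alpha_c = alpha / n_boundaries_for_correction
    return BoundaryTestResult(boundary, peak, vals, t, p, bool(p < alpha_c), alpha_c)


def boundary_report(
    boundaries: Sequence[BoundaryRegion],
    tracks: Sequence[CleavageRatioTrack],
    background: BackgroundModel,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run :func:`boundary_test` over all boundaries, correcting for their count."""
    rows = []
    for b in boundaries:
        try:
            res = boundary_test(b, tracks, background, len(boundaries), alpha)
        except ValueError:
            continue
        rows.append(
            {
                "junction": b.junction_site,
                "upstream_gene": b.flanking_genes[0],
                "downstream_gene": b.flanking_genes[1],
                "tRNA_flanked": b.trna_flanked,
                "peak_junction": res.peak_junction,
                "mean_boundary_ratio": float(res.boundary_ratios.mean()),
                "t": res.t,
                "p": res.p,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)


def sites_to_frame(sites: Sequence[CandidateSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "junction": [s.junction for s in sites],
            "representative_ratio": [s.representative_ratio for s in sites],
            "presence_fraction": [s.presence_fraction for s in sites],
            "mean_coverage": [s.mean_coverage for s in sites],
            "classification": [s.classification for s in sites],
            "boundary_distance": [s.boundary_distance for s in sites],
            "provenance": [s.provenance for s in sites],
        }
    )
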