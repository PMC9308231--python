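"""Mitochondrial gene annotation: records, boundary regions, site classification.

The human mitochondrial genome (rCRS, 16,569 bp) is almost entirely coding:
2 rRNAs, 22 tRNAs and 13 mRNAs packed back-to-back, several of them
overlapping, plus the non-coding control region (D-loop).  Post-transcriptional
cleavage of the polycistronic primary transcript happens at the junctions
between these genes ("punctuation" by the interspersed tRNAs), so the unit of
interest throughout this package is the *junction*: the inter-nucleotide bond
between reference positions ``s-1`` and ``s``, written as the integer ``s``
with valid range ``[2, L]``.  Feature coordinates themselves are 1-based
inclusive (GFF convention).

The genome is treated as linear; there is no wrap-around junction at 1/L.
The control region absorbs the artificial break: junctions upstream of the
first gene (positions 1-576 precede MT-TF) classify as control region.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: rCRS mitochondrial genome length (NC_012920.1).
MT_LENGTH = 16569

#: Contig aliases accepted as "the" mitochondrial contig.
MT_CONTIG_NAMES = frozenset({"MT", "chrM", "chrMT", "M", "NC_012920.1", "NC_012920"})

#: Token selecting the packaged rCRS gene table in :func:`load_annotation`.
BUILTIN = "rcrs"

VALID_BIOTYPES = frozenset({"mRNA", "rRNA", "tRNA", "control_region"})

#: Default half-width of a boundary region window (bp on each side of the junction).
BOUNDARY_WINDOW = 3


class AnnotationError(ValueError):
    """Malformed or empty annotation input."""


class EmptyAnnotationError(AnnotationError):
    """No mitochondrial features found in the source."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated mitochondrial feature (1-based inclusive coordinates)."""

    name: str
    biotype: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.biotype not in VALID_BIOTYPES:
            raise AnnotationError(f"{self.name}: unknown biotype {self.biotype!r}")
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"{self.name}: invalid coordinates {self.start}-{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.name}: invalid strand {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """Reference position of the 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class BoundaryRegion:
    """An inter-gene junction with its +/- ``window`` bp search window.

    ``junction_site`` is a junction coordinate; ``window`` is the closed
    interval of junction coordinates ``[junction_site - w, junction_site + w]``
    (clipped to ``[2, L]``).
    """

    junction_site: int
    window: tuple[int, int]
    flanking_genes: tuple[str, str]
    trna_flanked: bool

    def distance(self, site: int) -> int:
        """Distance (bp) from ``site`` to this region's window (0 if inside)."""
        lo, hi = self.window
        return max(0, lo - site, site - hi)


# ---------------------------------------------------------------------------
# Loading


def _records_from_frame(df: pd.DataFrame) -> list[GeneRecord]:
    records = [
        GeneRecord(str(r.name_), str(r.biotype), int(r.start), int(r.end), str(r.strand))
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    names = [g.name for g in records]
    if len(set(names)) != len(names):
        raise AnnotationError("duplicate gene names in annotation")
    return sorted(records, key=lambda g: (g.start, g.end))


def _load_builtin() -> list[GeneRecord]:
    with resources.files("mitocleave.data").joinpath("rcrs_genes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return _records_from_frame(df)


_GFF_BIOTYPE_MAP = {
    "Mt_tRNA": "tRNA",
    "Mt_rRNA": "rRNA",
    "protein_coding": "mRNA",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "mRNA": "mRNA",
}


def _load_gff(path: str | Path, genome_length: int) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records: list[GeneRecord] = []
    max_end = 0
    for feat in db.all_features():
        if feat.seqid not in MT_CONTIG_NAMES:
            continue
        ftype = feat.featuretype.lower()
        if ftype in {"d_loop", "d-loop"}:
            biotype = "control_region"
        elif ftype == "gene":
            raw = (
                feat.attributes.get("gene_biotype")
                or feat.attributes.get("gene_type")
                or feat.attributes.get("biotype")
                or [""]
            )[0]
            biotype = _GFF_BIOTYPE_MAP.get(raw)
            if biotype is None:
                continue
        else:
            continue
        name = (
            feat.attributes.get("gene_name")
            or feat.attributes.get("Name")
            or feat.attributes.get("gene_id")
            or [feat.id]
        )[0]
        if feat.start > feat.end or feat.start < 1 or feat.end > genome_length:
            raise AnnotationError(
                f"{name}: invalid coordinates {feat.start}-{feat.end}"
            )
        records.append(
            GeneRecord(name, biotype, int(feat.start), int(feat.end), feat.strand or "+")
        )
        max_end = max(max_end, int(feat.end))
    if not records:
        raise EmptyAnnotationError(f"no mitochondrial features in {path}")
    if not any(g.biotype == "control_region" for g in records) and max_end < genome_length:
        records.append(
            GeneRecord("control_region", "control_region", max_end + 1, genome_length, "+")
        )
    names = [g.name for g in records]
    if len(set(names)) != len(names):
        raise AnnotationError("duplicate gene names in annotation")
    return sorted(records, key=lambda g: (g.start, g.end))


def load_annotation(
    source: str | Path = BUILTIN, genome_length: int = MT_LENGTH
) -> list[GeneRecord]:
    """Load mitochondrial gene records plus one control-region record.

    Parameters
    ----------
    source
        The token ``"rcrs"`` selects the packaged rCRS gene table (37 genes and
        the D-loop); otherwise a path to a GFF3/GTF file containing MT-contig
        features.
    genome_length
        Length of the mitochondrial reference (coordinate validation).

    Returns
    -------
    list of :class:`GeneRecord`, sorted by start coordinate.
    """
    if isinstance(source, str) and source == BUILTIN:
        return _load_builtin()
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    return _load_gff(path, genome_length)


def coding_genes(genes: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Genes only (control-region records removed)."""
    return [g for g in genes if g.biotype != "control_region"]


# ---------------------------------------------------------------------------
# Boundary enumeration


def enumerate_boundaries(
    genes: Sequence[GeneRecord],
    biotypes: Iterable[str] = ("mRNA", "rRNA"),
    window: int = BOUNDARY_WINDOW,
    genome_length: int = MT_LENGTH,
) -> list[BoundaryRegion]:
    """Enumerate distinct gene-boundary regions for the requested biotypes.

    Each selected gene contributes its 5' junction (``start``) and its 3'
    junction (``end + 1``).  Two gene-end junctions describe the *same*
    boundary when one lies within the other's +/- ``window`` bp search window
    (this is how the shared ATP6/CO3 junction and the abutting ND5/ND6
    junction each count once, while boundaries separated further -- even those
    of overlapping gene pairs like ND4L/ND4 -- stay distinct).  The merged
    region is anchored at the downstream gene's 5' junction.
    """
    biotypes = set(biotypes)
    bad = biotypes - {"mRNA", "rRNA", "tRNA"}
    if bad:
        raise AnnotationError(f"invalid boundary biotypes: {sorted(bad)}")
    selected = [g for g in genes if g.biotype in biotypes]
    if not selected:
        return []
    all_genes = sorted(coding_genes(genes), key=lambda g: (g.start, g.end))

    # (junction, is_five_prime, gene) events for each selected gene end
    events: list[tuple[int, bool, GeneRecord]] = []
    for g in selected:
        events.append((g.start, True, g))
        events.append((g.end + 1, False, g))
    events.sort(key=lambda e: e[0])

    # transitive clustering: |delta junction| <= window
    clusters: list[list[tuple[int, bool, GeneRecord]]] = []
    for ev in events:
        if clusters and ev[0] - clusters[-1][-1][0] <= window:
            clusters[-1].append(ev)
        else:
            clusters.append([ev])

    regions = []
    for cluster in clusters:
        five = [e for e in cluster if e[1]]
        if five:
            # anchor at the downstream-most gene's 5' end
            junction = max(five, key=lambda e: e[2].start)[0]
        else:
            junction = min(e[0] for e in cluster)
        lo = max(2, junction - window)
        hi = min(genome_length, junction + window)
        upstream = [e[2].name for e in cluster if not e[1]]
        downstream = [e[2].name for e in cluster if e[1]]
        if not upstream:
            prev = [g.name for g in all_genes if g.end < junction]
            upstream = [prev[-1]] if prev else [downstream[0]]
        if not downstream:
            nxt = [g.name for g in all_genes if g.start >= junction]
            downstream = [nxt[0]] if nxt else [upstream[0]]
        trna = any(
            g.biotype == "tRNA" and g.start - 1 <= junction <= g.end + 1
            for g in all_genes
        )
        regions.append(
            BoundaryRegion(junction, (lo, hi), (upstream[0], downstream[0]), trna)
        )
    # clustering can in principle assign identical anchors; deduplicate
    seen: dict[int, BoundaryRegion] = {}
    for r in regions:
        seen.setdefault(r.junction_site, r)
    return sorted(seen.values(), key=lambda r: r.junction_site)


# ---------------------------------------------------------------------------
# Site classification


#: classification labels, in precedence order
CLASS_LABELS = (
    "exact_boundary",
    "near_boundary",
    "within_mRNA",
    "within_rRNA",
    "within_tRNA",
    "control_region",
)


def classify_site(
    site: int,
    genes: Sequence[GeneRecord],
    boundaries: Sequence[BoundaryRegion],
    near_dist: int = 10,
    genome_length: int = MT_LENGTH,
) -> tuple[str, int]:
    """Classify a junction coordinate against genes and boundary regions.

    Returns ``(label, distance_to_nearest_boundary_junction)``.  Precedence:
    ``exact_boundary`` (the site *is* a boundary junction) > ``near_boundary``
    (within ``near_dist`` bp of a boundary window) > containment in a feature.
    Junctions in small inter-gene gaps take the class of the nearest gene;
    junctions outside the annotated gene span fall to the control region
    (which wraps the linear origin of the circular genome).
    """
    if not (2 <= site <= genome_length):
        raise ValueError(f"site {site} outside junction range [2, {genome_length}]")
    if boundaries:
        dist_junction = min(abs(site - b.junction_site) for b in boundaries)
        dist_window = min(b.distance(site) for b in boundaries)
    else:
        dist_junction = dist_window = genome_length
    if dist_junction == 0:
        return "exact_boundary", 0
    if dist_window <= near_dist:
        return "near_boundary", dist_junction

    gene_list = coding_genes(genes)
    # junction s is inside a gene if the gene covers both s-1 and s
    containing = [g for g in gene_list if g.start < site <= g.end]
    if containing:
        g = min(containing, key=len)  # most specific feature on overlaps
        return f"within_{g.biotype}", dist_junction
    control = [g for g in genes if g.biotype == "control_region"]
    if control and any(g.start < site <= g.end + 1 for g in control):
        return "control_region", dist_junction
    first = min(g.start for g in gene_list) if gene_list else 1
    last = max(g.end for g in gene_list) if gene_list else genome_length
    if site <= first or site > last:
        return "control_region", dist_junction
    # small inter-gene gap: take the nearest gene's biotype
    nearest = min(gene_list, key=lambda g: min(abs(site - g.start), abs(site - g.end - 1)))
    return f"within_{nearest.biotype}", dist_junction


# ---------------------------------------------------------------------------
# Background site sampling


class SamplingError(ValueError):
    """Eligible background set smaller than the requested sample."""


def background_eligible_junctions(
    boundaries: Sequence[BoundaryRegion],
    min_dist: int = 50,
    genome_length: int = MT_LENGTH,
) -> np.ndarray:
    """All junctions more than ``min_dist`` bp from every boundary window."""
    ok = np.ones(genome_length + 1, dtype=bool)
    ok[:2] = False
    for b in boundaries:
        lo, hi = b.window
        ok[max(0, lo - min_dist): hi + min_dist + 1] = False
    return np.flatnonzero(ok)


def sample_background_sites(
    boundaries: Sequence[BoundaryRegion],
    n: int = 100,
    min_dist: int = 50,
    rng_seed: int | np.random.Generator | None = None,
    genome_length: int = MT_LENGTH,
) -> np.ndarray:
    """Sample ``n`` distinct junctions > ``min_dist`` bp from every boundary window.

    Reproducible for a fixed ``rng_seed``; raises :class:`SamplingError` when
    fewer than ``n`` junctions are eligible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    eligible = background_eligible_junctions(boundaries, min_dist, genome_length)
    if eligible.size < n:
        raise SamplingError(
            f"only {eligible.size} junctions are > {min_dist} bp from boundaries; "
            f"cannot sample {n}"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return np.sort(rng.choice(eligible, size=n, replace=False))


# ---------------------------------------------------------------------------
# Exports


def boundaries_to_frame(boundaries: Sequence[BoundaryRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "junction": [b.junction_site for b in boundaries],
            "window_lo": [b.window[0] for b in boundaries],
            "window_hi": [b.window[1] for b in boundaries],
            "upstream_gene": [b.flanking_genes[0] for b in boundaries],
            "downstream_gene": [b.flanking_genes[1] for b in boundaries],
            "tRNA_flanked": [b.trna_flanked for b in boundaries],
        }
    )


def junctions_to_bed(
    junctions: Iterable[int], path: str | Path, contig: str = "MT", names=None
) -> None:
    """Write junctions as BED (junction s -> 0-based half-open [s-1, s))."""
    junctions = list(junctions)
    if names is None:
        names = [f"junction_{s}" for s in junctions]
    with open(path, "w") as fh:
        for s, name in zip(junctions, names):
            fh.write(f"{contig}\t{s - 1}\t{s}\t{name}\n")
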