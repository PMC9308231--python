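"""Synthetic polycistronic RNA-seq data with known cleavage truth.

The generator emulates the biology and library chemistry that give rise to
read-end stacking:

1. full-length polycistronic molecules spanning the whole reference;
2. site-specific cleavage -- each molecule is cut independently at each truth
   junction with that junction's cleavage probability ``f`` (cleavage before
   fragmentation, the biological order);
3. random library fragmentation -- each resulting molecule is chopped
   left-to-right into fragments whose lengths are drawn from a clipped normal
   distribution (default mean 180, sd 40, clipped to [50, 400], mimicking a
   100 bp paired-end library); the trailing remnant is merged into the last
   fragment so molecule termini are never lost.

Fragment tables can be written as properly-paired SAM records with POS/TLEN
consistent with the short-read extraction conventions.  Cohort simulation
layers a genotype -> cleavage-probability dosage model, expression and
covariate sidecar tables, and an exposure/mediator/outcome chain for
mediation tests.  Everything is deterministic under a fixed seed.

PolyA selection and sequence-level fragmentation bias are deliberately not
modelled (see docs/methods.md for what that implies about the tests).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .annotation import MT_LENGTH
from .fragment_ends import FragmentEndTable

FRAG_MEAN = 180.0
FRAG_SD = 40.0
FRAG_MIN = 50
FRAG_MAX = 400
READ_LENGTH = 100
DEPTH = 300


@dataclass
class SimulationTruth:
    """Ground truth for one sample's simulation."""

    genome_length: int = MT_LENGTH
    sites: list[tuple[int, float]] = field(default_factory=list)  # (junction, f)
    frag_mean: float = FRAG_MEAN
    frag_sd: float = FRAG_SD
    frag_min: int = FRAG_MIN
    frag_max: int = FRAG_MAX
    read_length: int = READ_LENGTH
    depth: int = DEPTH
    seed: int | None = None

    def validate(self) -> None:
        L = self.genome_length
        if L < 10:
            raise ValueError("genome_length too small")
        for j, f in self.sites:
            if not (2 <= j <= L):
                raise ValueError(f"junction {j} outside [2, {L}]")
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"cleavage probability {f} outside [0, 1]")
        if not (self.frag_min <= self.frag_mean <= self.frag_max):
            raise ValueError("need frag_min <= frag_mean <= frag_max")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def _fragment_segment(
    start: int, end: int, truth: SimulationTruth, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Chop molecule [start, end] left-to-right into size-distributed pieces."""
    length = end - start + 1
    if length <= truth.frag_max:
        return np.array([start]), np.array([end])
    k = int(np.ceil(length / truth.frag_min)) + 2  # enough draws even at all-min sizes
    sizes = np.clip(
        np.rint(rng.normal(truth.frag_mean, truth.frag_sd, size=k)),
        truth.frag_min,
        truth.frag_max,
    ).astype(np.int64)
    bounds = start - 1 + np.cumsum(sizes)
    n_full = int(np.searchsorted(bounds, end))
    starts = np.empty(n_full + 1, dtype=np.int64)
    ends = np.empty(n_full + 1, dtype=np.int64)
    starts[0] = start
    starts[1:] = bounds[:n_full] + 1
    ends[:n_full] = bounds[:n_full]
    ends[n_full] = end
    # merge a sub-minimum trailing remnant into the previous fragment
    if n_full and ends[n_full] - starts[n_full] + 1 < truth.frag_min:
        starts = starts[:n_full]
        ends = ends[:n_full]
        ends[-1] = end
    return starts, ends


def _molecules(
    truth: SimulationTruth, n_molecules: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Cleave full-length transcripts into molecules per the truth junctions."""
    sites = sorted(truth.sites)
    junctions = np.array([j for j, _ in sites], dtype=np.int64)
    probs = np.array([f for _, f in sites], dtype=float)
    segments: list[tuple[int, int]] = []
    for _ in range(n_molecules):
        if junctions.size:
            cut = junctions[rng.random(junctions.size) < probs]
        else:
            cut = np.empty(0, dtype=np.int64)
        prev = 1
        for j in cut:
            segments.append((prev, int(j) - 1))
            prev = int(j)
        segments.append((prev, truth.genome_length))
    return segments


def simulate_sample(
    truth: SimulationTruth,
    sample_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> FragmentEndTable:
    """Simulate one sample's fragment table (cleave, then random-fragment).

    ``truth.depth`` full-length molecules are generated, so expected coverage
    at every junction is ~``depth``.  Deterministic for a fixed
    ``truth.seed`` (or a caller-supplied generator).
    """
    truth.validate()
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    segments = _molecules(truth, truth.depth, rng)
    all_starts = []
    all_ends = []
    for s, e in segments:
        st, en = _fragment_segment(s, e, truth, rng)
        all_starts.append(st)
        all_ends.append(en)
    starts = np.concatenate(all_starts)
    ends = np.concatenate(all_ends)
    order = np.lexsort((ends, starts))
    return FragmentEndTable(
        sample_id,
        starts[order],
        ends[order],
        source="short_read",
        qc={"molecules": truth.depth, "segments": len(segments)},
    )


def write_sam(
    table: FragmentEndTable,
    path: str | Path,
    read_length: int = READ_LENGTH,
    genome_length: int = MT_LENGTH,
    contig: str = "MT",
) -> None:
    """Emit each fragment as a properly-paired read pair (POS/TLEN outer span).

    Mates carry MAPQ 255 (the STAR unique-mapping value) and flat CIGARs; the
    leftmost mate's TLEN equals the fragment length, so the short-read
    extraction round-trips exactly.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": contig, "LN": genome_length}],
        }
    )
    reads = []
    for i, (s, e) in enumerate(zip(table.start, table.end)):
        s, e = int(s), int(e)
        tlen = e - s + 1
        rlen = min(read_length, tlen)
        name = f"{table.sample_id}.frag{i}"
        r1 = pysam.AlignedSegment(header)
        r1.query_name = name
        r1.flag = 0x1 | 0x2 | 0x20 | 0x40
        r1.reference_id = 0
        r1.reference_start = s - 1
        r1.mapping_quality = 255
        r1.cigarstring = f"{rlen}M"
        r1.next_reference_id = 0
        r1.next_reference_start = e - rlen
        r1.template_length = tlen
        r1.query_sequence = "A" * rlen
        r1.query_qualities = pysam.qualitystring_to_array("I" * rlen)
        r2 = pysam.AlignedSegment(header)
        r2.query_name = name
        r2.flag = 0x1 | 0x2 | 0x10 | 0x80
        r2.reference_id = 0
        r2.reference_start = e - rlen
        r2.mapping_quality = 255
        r2.cigarstring = f"{rlen}M"
        r2.next_reference_id = 0
        r2.next_reference_start = s - 1
        r2.template_length = -tlen
        r2.query_sequence = "A" * rlen
        r2.query_qualities = pysam.qualitystring_to_array("I" * rlen)
        reads.append(r1)
        reads.append(r2)
    reads.sort(key=lambda r: (r.reference_start, r.query_name, r.flag))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            out.write(r)


def simulate_long_read_profile(
    truth: SimulationTruth,
    n_reads: int = 10000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-position start+end support from full-length cleaved molecules.

    Each of ``n_reads`` polycistronic molecules is cleaved per the truth; each
    resulting molecule contributes its terminal positions (start and end) to
    the pooled profile (1-based array, index 0 padding).
    """
    truth.validate()
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    profile = np.zeros(truth.genome_length + 1, dtype=np.int64)
    for s, e in _molecules(truth, n_reads, rng):
        profile[s] += 1
        profile[e] += 1
    return profile


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortTruth:
    """Cohort-level generative model: genotype -> cleavage rate -> downstream.

    Per sample, the cleavage probability at effect site ``i`` is
    ``f = base_f[i] + dosage_beta[i] * dosage + noise``, clipped to [0, 1];
    dosages are Binomial(2, maf).  The optional mediation chain generates
    ``M = a*X + e_m`` and ``Y = b*M + c*X + e_y`` with X the standardized
    dosage at the first effect site.
    """

    base: SimulationTruth
    dosage_beta: dict[int, float] = field(default_factory=dict)  # junction -> beta
    maf: float = 0.3
    f_noise_sd: float = 0.02
    mediation_a: float = 0.0
    mediation_b: float = 0.0
    mediation_direct: float = 0.0
    mediation_noise_sd: float = 0.2
    n_expression_genes: int = 20
    expression_effect: float = 0.0  # expression of gene 0 per unit f at site 0

    def validate(self) -> None:
        self.base.validate()
        if not (0 < self.maf < 1):
            raise ValueError("maf must be in (0, 1)")
        known = {j for j, _ in self.base.sites}
        for j in self.dosage_beta:
            if j not in known:
                raise ValueError(f"dosage effect at unknown junction {j}")


@dataclass
class CohortResult:
    tables: list[FragmentEndTable]
    sample_f: pd.DataFrame  # samples x site junctions (true per-sample f)
    genotypes: pd.DataFrame  # samples x sites with dosage effects
    expression: pd.DataFrame
    covariates: pd.DataFrame
    mediation: pd.DataFrame  # columns X, M, Y
    truth: CohortTruth


def simulate_cohort(
    cohort: CohortTruth,
    n_samples: int,
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> CohortResult:
    """Simulate a cohort of fragment tables plus phenotype/genotype sidecars."""
    cohort.validate()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed if seed is not None else cohort.base.seed)
    base_sites = sorted(cohort.base.sites)
    junctions = [j for j, _ in base_sites]
    effect_sites = [j for j in junctions if j in cohort.dosage_beta]

    dosages = rng.binomial(2, cohort.maf, size=(n_samples, len(effect_sites))).astype(
        float
    )
    f_rows = []
    tables = []
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    for i in range(n_samples):
        fs = {}
        sites_i = []
        for j, f0 in base_sites:
            f = f0
            if j in cohort.dosage_beta:
                d = dosages[i, effect_sites.index(j)]
                f = f + cohort.dosage_beta[j] * d
            if cohort.f_noise_sd > 0:
                f = f + rng.normal(0.0, cohort.f_noise_sd)
            f = float(np.clip(f, 0.0, 1.0))
            fs[j] = f
            sites_i.append((j, f))
        truth_i = dataclasses.replace(cohort.base, sites=sites_i, seed=None)
        tables.append(simulate_sample(truth_i, sample_ids[i], rng))
        f_rows.append(fs)
    sample_index = pd.Index(sample_ids, name="sample_id")
    sample_f = pd.DataFrame(f_rows, index=sample_index)
    genotypes = pd.DataFrame(
        dosages, index=sample_index, columns=[f"var_{j}" for j in effect_sites]
    )

    # expression sidecar: gene_000 optionally tracks the true f at site 0
    expr = rng.normal(0.0, 1.0, size=(n_samples, cohort.n_expression_genes))
    if cohort.expression_effect != 0.0 and junctions:
        f0 = sample_f[junctions[0]].to_numpy()
        expr[:, 0] += cohort.expression_effect * (f0 - f0.mean())
    expression = pd.DataFrame(
        expr,
        index=sample_index,
        columns=[f"gene_{g:03d}" for g in range(cohort.n_expression_genes)],
    )
    covariates = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n_samples, 10)),
        index=sample_index,
        columns=[f"peer_{k + 1}" for k in range(10)],
    )

    # mediation chain on the first effect site's dosage
    if effect_sites:
        Xm = dosages[:, 0]
        Xm = (Xm - Xm.mean()) / (Xm.std() if Xm.std() > 0 else 1.0)
    else:
        Xm = rng.normal(0.0, 1.0, n_samples)
    M = cohort.mediation_a * Xm + rng.normal(0, cohort.mediation_noise_sd, n_samples)
    Y = (
        cohort.mediation_b * M
        + cohort.mediation_direct * Xm
        + rng.normal(0, cohort.mediation_noise_sd, n_samples)
    )
    mediation = pd.DataFrame({"X": Xm, "M": M, "Y": Y}, index=sample_index)

    result = CohortResult(
        tables, sample_f, genotypes, expression, covariates, mediation, cohort
    )
    if outdir is not None:
        _write_cohort(result, Path(outdir))
    return result


def _write_cohort(result: CohortResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for t in result.tables:
        t.to_tsv(outdir / f"{t.sample_id}.fragments.tsv")
    result.genotypes.to_csv(outdir / "genotypes.tsv", sep="\t")
    result.expression.to_csv(outdir / "expression.tsv", sep="\t")
    result.covariates.to_csv(outdir / "covariates.tsv", sep="\t")
    result.mediation.to_csv(outdir / "mediation.tsv", sep="\t")
    result.sample_f.to_csv(outdir / "true_cleavage_probabilities.tsv", sep="\t")
    truth = {
        "genome_length": result.truth.base.genome_length,
        "sites": [[int(j), float(f)] for j, f in result.truth.base.sites],
        "dosage_beta": {str(k): v for k, v in result.truth.dosage_beta.items()},
        "maf": result.truth.maf,
        "f_noise_sd": result.truth.f_noise_sd,
        "depth": result.truth.base.depth,
        "n_samples": len(result.tables),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def expected_processed_fraction(
    truth: SimulationTruth,
    junction: int,
    n_molecules: int = 200000,
    rng: np.random.Generator | None = None,
) -> float:
    """Brute-force molecule-level tally of the expected cleaved fraction.

    The fraction of simulated molecules whose boundary falls exactly at
    ``junction`` -- an oracle for the generator, independent of the
    fragmentation and counting pipeline.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    f = dict(truth.sites).get(junction, 0.0)
    draws = rng.random(n_molecules) < f
    return int(draws.sum()) / n_molecules
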