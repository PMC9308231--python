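import numpy as np
import pytest

from mitocleave import (
    CleavageRatioTrack,
    GeneRecord,
    enumerate_boundaries,
    load_annotation,
)


@pytest.fixture(scope="session")
def rcrs_genes():
    return load_annotation()


@pytest.fixture(scope="session")
def mrna_rrna_boundaries(rcrs_genes):
    return enumerate_boundaries(rcrs_genes, ("mRNA", "rRNA"))


@pytest.fixture
def toy_genes():
    """Small linear annotation on a 1000 bp toy genome."""
    return [
        GeneRecord("tA", "tRNA", 100, 170, "+"),
        GeneRecord("mA", "mRNA", 171, 400, "+"),
        GeneRecord("tB", "tRNA", 401, 470, "-"),
        GeneRecord("rA", "rRNA", 480, 700, "+"),
        GeneRecord("ctrl", "control_region", 701, 1000, "+"),
    ]


def make_track(sample_id, genome_length, ratios=None, coverage=None,
               default_ratio=np.nan, default_coverage=0):
    """Build a ratio track from sparse {junction: value} dicts."""
    ratio = np.full(genome_length + 1, default_ratio, dtype=float)
    cov = np.full(genome_length + 1, default_coverage, dtype=np.int64)
    ratio[:2] = np.nan
    cov[:2] = 0
    for j, r in (ratios or {}).items():
        ratio[j] = r
    for j, c in (coverage or {}).items():
        cov[j] = c
    ratio[cov == 0] = np.nan
    return CleavageRatioTrack(sample_id, ratio, cov, genome_length)


@pytest.fixture
def track_factory():
    return make_track
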