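"""Fragment-end extraction from SAM records and per-junction event counting."""

import numpy as np
import pysam
import pytest

from mitocleave import (
    FragmentEndTable,
    count_site_events,
    extract_long_read_ends,
    extract_short_read_ends,
)
from mitocleave.fragment_ends import ContigMismatchError

L = 1000


def sam_header(contig="MT", length=16569):
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": contig, "LN": length}]}
    )


def make_read(header, name, pos, tlen=0, flag=0x1 | 0x2 | 0x40, mapq=255,
              cigar="50M", tags=None):
    r = pysam.AlignedSegment(header)
    r.query_name = name
    r.flag = flag
    r.reference_id = 0
    r.reference_start = pos - 1  # 1-based in, 0-based stored
    r.mapping_quality = mapq
    r.cigarstring = cigar
    r.template_length = tlen
    r.query_sequence = "A" * sum(n for op, n in r.cigartuples or [] if op in (0, 1, 4))
    if tags:
        for k, v in tags.items():
            r.set_tag(k, v)
    return r


def write_sam(path, reads, header):
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            fh.write(r)
    return str(path)


class TestShortReadExtraction:
    def test_pos_tlen_outer_span(self, tmp_path):
        """A proper pair's fragment is [POS, POS + TLEN - 1]."""
        h = sam_header()
        path = write_sam(tmp_path / "a.sam", [make_read(h, "q", 100, 200)], h)
        t = extract_short_read_ends(path, sample_id="s")
        assert t.start.tolist() == [100]
        assert t.end.tolist() == [299]

    def test_rightmost_mate_not_double_counted(self, tmp_path):
        h = sam_header()
        reads = [
            make_read(h, "q", 100, 200, flag=0x1 | 0x2 | 0x40),
            make_read(h, "q", 250, -200, flag=0x1 | 0x2 | 0x80 | 0x10),
        ]
        t = extract_short_read_ends(write_sam(tmp_path / "a.sam", reads, h))
        assert len(t) == 1

    def test_pair_stream_counts_only_proper_pairs(self, tmp_path):
        h = sam_header()
        reads = []
        for i in range(5):
            pos = 100 + 50 * i
            reads.append(make_read(h, f"p{i}", pos, 180))
            reads.append(make_read(h, f"p{i}", pos + 130, -180,
                                   flag=0x1 | 0x2 | 0x80 | 0x10))
        # two unpaired/improper reads
        reads.append(make_read(h, "u1", 500, 0, flag=0x1 | 0x40))
        reads.append(make_read(h, "u2", 600, 0, flag=0x1 | 0x40))
        t = extract_short_read_ends(write_sam(tmp_path / "a.sam", reads, h))
        assert len(t) == 5
        assert t.qc["not_proper_pair"] == 2

    def test_tlen_zero_tallied(self, tmp_path):
        h = sam_header()
        reads = [make_read(h, "z", 100, 0)]
        t = extract_short_read_ends(write_sam(tmp_path / "a.sam", reads, h))
        assert len(t) == 0
        assert t.qc["tlen_zero"] == 1

    def test_non_unique_mapq_filtered(self, tmp_path):
        h = sam_header()
        reads = [make_read(h, "m", 100, 200, mapq=3)]
        t = extract_short_read_ends(write_sam(tmp_path / "a.sam", reads, h))
        assert len(t) == 0
        t2 = extract_short_read_ends(write_sam(tmp_path / "b.sam", reads, h),
                                     unique_mapq=None)
        assert len(t2) == 1

    def test_unexpected_contig_raises(self, tmp_path):
        h = sam_header(contig="chr7")
        reads = [make_read(h, "q", 100, 200)]
        with pytest.raises(ContigMismatchError):
            extract_short_read_ends(write_sam(tmp_path / "a.sam", reads, h))

    def test_fragment_past_contig_end_skipped(self, tmp_path):
        h = sam_header()
        reads = [make_read(h, "q", 16500, 200)]
        t = extract_short_read_ends(write_sam(tmp_path / "a.sam", reads, h))
        assert len(t) == 0
        assert t.qc["past_contig_end"] == 1


class TestLongReadExtraction:
    def make(self, tmp_path, reads):
        h = sam_header()
        return write_sam(tmp_path / "lr.sam", reads, h)

    def test_pure_match_cigar(self, tmp_path):
        h = sam_header()
        path = self.make(tmp_path, [make_read(h, "r", 5, flag=0, mapq=40,
                                              cigar="10M")])
        with pytest.warns(UserWarning):
            t = extract_long_read_ends(path)
        assert (t.start.tolist(), t.end.tolist()) == ([5], [14])

    @pytest.mark.parametrize(
        "cigar,end",
        [("5M2D5M", 16), ("4S10M", 14), ("3M2I3M", 10), ("5M100N5M", 114)],
    )
    def test_reference_consuming_cigar_ops(self, tmp_path, cigar, end):
        """End = POS + (M/D/N/=/X lengths) - 1; S and I consume no reference."""
        h = sam_header()
        path = self.make(tmp_path, [make_read(h, "r", 5, flag=0, mapq=40,
                                              cigar=cigar)])
        with pytest.warns(UserWarning):
            t = extract_long_read_ends(path)
        assert t.end.tolist() == [end]

    def test_mapq_strictly_greater_than_threshold(self, tmp_path):
        h = sam_header()
        path = self.make(tmp_path, [
            make_read(h, "lo", 5, flag=0, mapq=30, cigar="10M"),
            make_read(h, "hi", 5, flag=0, mapq=31, cigar="10M"),
        ])
        with pytest.warns(UserWarning):
            t = extract_long_read_ends(path, min_mapq=30)
        assert len(t) == 1 and t.qc["low_mapq"] == 1

    def test_split_and_secondary_removed(self, tmp_path):
        h = sam_header()
        path = self.make(tmp_path, [
            make_read(h, "sa", 5, flag=0, mapq=40, cigar="10M",
                      tags={"SA": "MT,500,+,10M,40,0;"}),
            make_read(h, "sec", 5, flag=0x100, mapq=40, cigar="10M"),
            make_read(h, "sup", 5, flag=0x800, mapq=40, cigar="10M"),
        ])
        with pytest.warns(UserWarning):
            t = extract_long_read_ends(path)
        assert len(t) == 0

    def test_nuclear_competitor_filter(self, tmp_path):
        h = sam_header()
        path = self.make(tmp_path, [
            make_read(h, "beat", 5, flag=0, mapq=40, cigar="10M"),
            make_read(h, "kept", 50, flag=0, mapq=40, cigar="10M"),
        ])
        t = extract_long_read_ends(path, competing_mapq={"beat": 60, "kept": 10})
        assert t.start.tolist() == [50]
        assert t.qc["nuclear_competitor"] == 1

    def test_relaxing_mapq_is_monotone(self, tmp_path):
        h = sam_header()
        reads = [make_read(h, f"r{q}", 5 + q, flag=0, mapq=q, cigar="10M")
                 for q in (10, 25, 35, 50, 60)]
        path = self.make(tmp_path, reads)
        kept = []
        for thr in (60, 50, 35, 25, 10, 0):
            with pytest.warns(UserWarning):
                t = extract_long_read_ends(path, min_mapq=thr)
            kept.append(set(t.start.tolist()))
        for small, big in zip(kept, kept[1:]):
            assert small <= big


def brute_force_counts(starts, ends, genome_length):
    """Independent O(fragments x junctions) tabulation straight from the definitions."""
    ns = np.zeros(genome_length + 1, dtype=int)
    ne = np.zeros(genome_length + 1, dtype=int)
    nsp = np.zeros(genome_length + 1, dtype=int)
    for s, e in zip(starts, ends):
        for j in range(2, genome_length + 1):
            if s == j:
                ns[j] += 1
            if e == j - 1:
                ne[j] += 1
            if s <= j - 1 and e >= j:
                nsp[j] += 1
    return ns, ne, nsp


class TestCountSiteEvents:
    def test_single_fragment(self):
        t = FragmentEndTable("s", [10], [20])
        c = count_site_events(t, 30)
        assert c.n_start[10] == 1
        assert c.n_end_before[21] == 1
        assert all(c.n_span[j] == 1 for j in range(11, 21))
        assert c.n_start.sum() == 1 and c.n_end_before.sum() == 1

    def test_empty_table(self):
        c = count_site_events(FragmentEndTable("s", [], []), 50)
        assert c.coverage.sum() == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 100))
        Lt = 120
        starts = rng.integers(1, Lt + 1, size=n)
        lengths = rng.integers(0, 40, size=n)
        ends = np.minimum(starts + lengths, Lt)
        c = count_site_events(FragmentEndTable("s", starts, ends), Lt)
        ns, ne, nsp = brute_force_counts(starts, ends, Lt)
        assert np.array_equal(c.n_start, ns)
        assert np.array_equal(c.n_end_before, ne)
        assert np.array_equal(c.n_span, nsp)

    def test_counts_partition_touching_fragments(self):
        """n_start + n_end_before + n_span at s equals the number of fragments
        with start <= s and end >= s-1 (every fragment touching the bond)."""
        rng = np.random.default_rng(42)
        starts = rng.integers(1, 100, size=60)
        ends = starts + rng.integers(0, 30, size=60)
        Lt = int(ends.max()) + 5
        c = count_site_events(FragmentEndTable("s", starts, ends), Lt)
        for j in range(2, Lt + 1):
            touching = int(np.sum((starts <= j) & (ends >= j - 1)))
            assert c.coverage[j] == touching

    def test_out_of_range_fragments_rejected(self):
        with pytest.raises(ValueError):
            count_site_events(FragmentEndTable("s", [10], [200]), 100)
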