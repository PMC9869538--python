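import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grhl2net.io_formats import GenomicInterval, ValidationError
from grhl2net.motif_context import (
    IUPAC,
    MotifHit,
    MotifPattern,
    flank_cooccurrence,
    motif_coverage_matrix,
    scan_motif,
)


def naive_scan(seq, pattern):
    """Per-position oracle: test IUPAC membership at every offset on both
    strands, deduplicating double-strand hits to '+'."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    fwd = pattern.consensus
    rev = "".join(
        {"A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R", "W": "W",
         "S": "S", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}[c]
        for c in reversed(fwd)
    )
    k = len(fwd)
    hits = []
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        f = all(window[j] in IUPAC[fwd[j]] for j in range(k))
        r = all(window[j] in IUPAC[rev[j]] for j in range(k))
        if f:
            hits.append((i, "+"))
        elif r:
            hits.append((i, "-"))
    return hits


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestScanMotif:
    def test_palindromic_grhl2_motif_reported_once_plus_strand(self):
        hits = scan_motif("TTTAACCGGTTGGG", MotifPattern("GRHL2", "AACCGGTT"))
        assert len(hits) == 1
        assert (hits[0].interval.start, hits[0].strand) == (3, "+")

    def test_degenerate_code_expansion(self):
        pattern = MotifPattern("FOXA1", "TGTTTRC")
        assert [h.strand for h in scan_motif("TGTTTAC", pattern)] == ["+"]
        assert [h.strand for h in scan_motif("TGTTTGC", pattern)] == ["+"]
        assert scan_motif("TGTTTCCAAA", pattern) == []

    def test_reverse_complement_hit_reported_minus_strand(self):
        # reverse complement of AACCTG is CAGGTT
        hits = scan_motif("TTCAGGTTTT", MotifPattern("m", "AACCTG"))
        assert len(hits) == 1
        assert (hits[0].interval.start, hits[0].strand) == (2, "-")

    def test_overlapping_hits_all_reported(self):
        hits = scan_motif("AAAAAA", MotifPattern("m", "AAAA"))
        assert [h.interval.start for h in hits] == [0, 1, 2]

    def test_invalid_iupac_code_rejected(self):
        with pytest.raises(ValidationError):
            MotifPattern("bad", "ACGX")
        with pytest.raises(ValidationError):
            MotifPattern("short", "ACG")

    def test_matches_naive_per_position_oracle(self):
        rng = np.random.default_rng(31)
        seq = random_seq(rng, 20_000)
        for consensus in ("AACCGGTT", "AGGTCANNNTGACCT", "TGTTTRC", "WGATAR"):
            pattern = MotifPattern("m", consensus)
            got = [(h.interval.start, h.strand) for h in scan_motif(seq, pattern)]
            assert got == naive_scan(seq, pattern), consensus

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        seq=st.text(alphabet="ACGT", min_size=10, max_size=200),
        consensus=st.text(alphabet="ACGTRYWSKMN", min_size=4, max_size=8),
    )
    def test_scan_matches_oracle_for_arbitrary_patterns(self, seq, consensus):
        pattern = MotifPattern("m", consensus)
        got = [(h.interval.start, h.strand) for h in scan_motif(seq, pattern)]
        assert got == naive_scan(seq, pattern)

    def test_hit_count_matches_analytic_expectation(self):
        # expected hits on i.i.d. uniform sequence:
        # (n - k + 1) * p_match * (2 - is_palindrome)
        rng = np.random.default_rng(32)
        seq = random_seq(rng, 200_000)
        for consensus in ("AACCGGTT", "TGTTTRC"):
            pattern = MotifPattern("m", consensus)
            n_pos = len(seq) - len(pattern) + 1
            p = pattern.match_probability
            expect = n_pos * p * (2 - pattern.is_palindromic)
            sd = np.sqrt(expect)
            got = len(scan_motif(seq, pattern))
            assert abs(got - expect) < 3 * sd, consensus


class TestFlankCooccurrence:
    def test_site_inside_flank_window_flags_peak(self):
        peaks = [GenomicInterval("chr1", 1000, 1200, name="p")]
        fraction, flagged = flank_cooccurrence(
            peaks, [GenomicInterval("chr1", 2100, 2108)], flank_bp=1000
        )
        assert fraction == 1.0 and len(flagged) == 1

    def test_flank_window_is_half_open(self):
        peaks = [GenomicInterval("chr1", 1000, 1200, name="p")]
        # window is [0, 2200); a site starting at 2200 does not overlap
        fraction, _ = flank_cooccurrence(
            peaks, [GenomicInterval("chr1", 2200, 2208)], flank_bp=1000
        )
        assert fraction == 0.0
        fraction, _ = flank_cooccurrence(
            peaks, [GenomicInterval("chr1", 2199, 2207)], flank_bp=1000
        )
        assert fraction == 1.0

    def test_zero_flank_equals_plain_overlap(self):
        peaks = [
            GenomicInterval("chr1", 100, 200, name="a"),
            GenomicInterval("chr1", 300, 400, name="b"),
        ]
        sites = [GenomicInterval("chr1", 150, 160)]
        fraction, flagged = flank_cooccurrence(peaks, sites, flank_bp=0)
        assert fraction == 0.5
        assert [p.name for p in flagged] == ["a"]

    def test_fraction_non_decreasing_in_flank(self):
        rng = np.random.default_rng(33)
        peaks = sorted(
            (GenomicInterval("chr1", int(s), int(s) + 200, name=f"p{i}")
             for i, s in enumerate(rng.integers(0, 500_000, 100))),
            key=lambda p: p.start,
        )
        sites = sorted(
            (GenomicInterval("chr1", int(s), int(s) + 8)
             for s in rng.integers(0, 500_000, 50)),
            key=lambda s: s.start,
        )
        fractions = [
            flank_cooccurrence(peaks, sites, flank_bp=f)[0]
            for f in (0, 100, 500, 1000, 5000)
        ]
        assert fractions == sorted(fractions)

    def test_empty_peaks_rejected_empty_sites_zero(self):
        with pytest.raises(ValidationError):
            flank_cooccurrence([], [])
        fraction, flagged = flank_cooccurrence(
            [GenomicInterval("chr1", 0, 10)], []
        )
        assert (fraction, flagged) == (0.0, [])

    def test_planted_flags_recovered_exactly(self):
        from grhl2net.synthetic_data import (
            simulate_flanking_sites,
            simulate_genome,
            simulate_peaksets,
        )

        sizes = {"chr1": 4_000_000, "chr2": 3_000_000}
        genome, _ = simulate_genome(50, sizes, seed=41)
        peaksets, _ = simulate_peaksets(genome, 500, 1.0, 0.0, seed=42)
        sites, truth = simulate_flanking_sites(
            peaksets, rate=0.1, chrom_sizes=sizes, seed=43
        )
        fraction, flagged = flank_cooccurrence(peaksets["MCF7"], sites, 1000)
        assert {p.name for p in flagged} == set(truth.flagged_peak_ids)


class TestCoverageMatrix:
    def test_site_inside_wide_peak_gives_all_ones_row(self):
        site = MotifHit(
            GenomicInterval("chr1", 5000, 5008, "+", name="s"), "m", "+"
        )
        peaks = [GenomicInterval("chr1", 1000, 10000)]
        matrix, names = motif_coverage_matrix([site], peaks, 2000, 50)
        assert matrix.shape == (1, 80)
        assert matrix.all() and names == ["s"]

    def test_site_with_no_nearby_peak_gives_zero_row(self):
        site = MotifHit(
            GenomicInterval("chr1", 50_000, 50_008, "+", name="s"), "m", "+"
        )
        matrix, _ = motif_coverage_matrix(
            [site], [GenomicInterval("chr1", 1000, 1200)], 2000, 50
        )
        assert not matrix.any()

    def test_minus_strand_site_flips_bin_axis(self):
        peaks = [GenomicInterval("chr1", 5100, 5300)]  # downstream of center
        plus = MotifHit(GenomicInterval("chr1", 4996, 5004, "+", name="p"), "m", "+")
        minus = MotifHit(GenomicInterval("chr1", 4996, 5004, "-", name="n"), "m", "-")
        m_plus, _ = motif_coverage_matrix([plus], peaks, 1000, 100)
        m_minus, _ = motif_coverage_matrix([minus], peaks, 1000, 100)
        assert np.array_equal(m_plus[0], m_minus[0][::-1])

    def test_matches_per_bp_boolean_oracle(self):
        rng = np.random.default_rng(34)
        peaks = sorted(
            (GenomicInterval("chr1", int(s), int(s) + int(rng.integers(50, 600)))
             for s in rng.integers(0, 40_000, 30)),
            key=lambda p: p.start,
        )
        mask = np.zeros(60_000, dtype=bool)
        for p in peaks:
            mask[p.start:p.end] = True
        halfwidth, binsize = 2000, 50
        sites = [
            MotifHit(
                GenomicInterval("chr1", int(s), int(s) + 8,
                                "+" if rng.random() < 0.5 else "-",
                                name=f"s{i}"),
                "m",
                "+" if rng.random() < 0.5 else "-",
            )
            for i, s in enumerate(rng.integers(3000, 37_000, 10))
        ]
        matrix, names = motif_coverage_matrix(sites, peaks, halfwidth, binsize)
        by_name = {s.interval.name: s for s in sites}
        for row, name in zip(matrix, names):
            site = by_name[name]
            center = site.interval.midpoint
            nbins = 2 * halfwidth // binsize
            expected = np.zeros(nbins, dtype=np.int8)
            for b in range(nbins):
                lo = center - halfwidth + b * binsize
                hi = lo + binsize
                col = b if site.strand != "-" else nbins - 1 - b
                expected[col] = mask[lo:hi].any()
            assert np.array_equal(row, expected), name
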