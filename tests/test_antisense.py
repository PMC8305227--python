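import numpy as np
import pytest

from cernet.antisense import (
    OverlapPair,
    classify_overlap,
    find_overlaps,
    overlap_length_vs_correlation,
    summarize_classes,
)
from cernet.io import CernetError, GeneLocus


def random_loci(rng, n, prefix, cls, n_chroms=3, chrom_len=100_000):
    loci = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, chrom_len - 5000))
        length = int(rng.integers(200, 5000))
        strand = "+" if rng.integers(0, 2) else "-"
        n_iso = int(rng.integers(1, 4))
        isoforms = []
        for _ in range(n_iso):
            s = start + int(rng.integers(0, length // 2))
            e = s + int(rng.integers(100, length))
            isoforms.append((s, e))
        loci.append(GeneLocus(f"{prefix}{i:03d}", cls, chrom, strand,
                              tuple(sorted(isoforms))))
    return loci


def brute_force_pairs(lnc_loci, mrna_loci):
    """O(n^2) all-pairs isoform-overlap oracle."""
    found = set()
    for a in lnc_loci:
        for b in mrna_loci:
            if a.chrom != b.chrom or a.strand == b.strand:
                continue
            if any(
                min(e1, e2) - max(s1, s2) > 0
                for s1, e1 in a.isoforms
                for s2, e2 in b.isoforms
            ):
                found.add((a.gene_id, b.gene_id))
    return found


def terminus_oracle(lnc, mrna):
    """Classification via explicit terminus location (independent route)."""
    (ls, le), (ms, me) = lnc.span, mrna.span
    if ms <= ls and le <= me:
        return "lncRNA_within_mRNA"
    if ls <= ms and me <= le:
        return "mRNA_within_lncRNA"
    lo, hi = max(ls, ms), min(le, me)

    def termini(g):
        s, e = g.span
        return (s, e - 1) if g.strand == "+" else (e - 1, s)  # (5', 3')

    l5, l3 = termini(lnc)
    m5, m3 = termini(mrna)
    inside = lambda x: lo <= x < hi
    if inside(l3) and inside(m3):
        return "convergent"
    if inside(l5) and inside(m5):
        return "divergent"
    raise AssertionError("impossible geometry")


def simple_pair(lnc_span, lnc_strand, m_span, m_strand, chrom="chr1"):
    lnc = GeneLocus("L", "lncRNA", chrom, lnc_strand, (lnc_span,))
    m = GeneLocus("M", "mRNA", chrom, m_strand, (m_span,))
    pairs = find_overlaps([lnc], [m])
    return pairs[0] if pairs else None


class TestFindOverlaps:
    def test_basic_overlap_length(self):
        pair = simple_pair((100, 500), "+", (400, 800), "-")
        assert pair is not None
        assert pair.overlap_min == pair.overlap_max == 100
        assert pair.overlap_mean == 100.0

    def test_same_strand_overlap_excluded(self):
        assert simple_pair((100, 500), "+", (400, 800), "+") is None

    def test_different_chromosome_excluded(self):
        lnc = GeneLocus("L", "lncRNA", "chr1", "+", ((100, 500),))
        m = GeneLocus("M", "mRNA", "chr2", "-", ((100, 500),))
        assert find_overlaps([lnc], [m]) == []

    def test_matches_quadratic_oracle_on_random_loci(self, rng):
        lnc_loci = random_loci(rng, 100, "L", "lncRNA")
        mrna_loci = random_loci(rng, 100, "M", "mRNA")
        got = {(p.lnc.gene_id, p.mrna.gene_id)
               for p in find_overlaps(lnc_loci, mrna_loci)}
        assert got == brute_force_pairs(lnc_loci, mrna_loci)

    def test_symmetric_up_to_label_swap(self, rng):
        """Swapping which list is 'lncRNA' relabels but keeps the pair set."""
        a = random_loci(rng, 40, "A", "lncRNA")
        b = random_loci(rng, 40, "B", "mRNA")
        fwd = {(p.lnc.gene_id, p.mrna.gene_id) for p in find_overlaps(a, b)}
        rev = {(p.mrna.gene_id, p.lnc.gene_id) for p in find_overlaps(b, a)}
        assert fwd == rev


class TestClassifyOverlap:
    def test_convergent_tail_to_tail(self):
        # + strand mRNA ends inside - strand lncRNA: both 3' ends shared
        pair = simple_pair((400, 800), "-", (100, 500), "+")
        assert classify_overlap(pair) == "convergent"

    def test_divergent_head_to_head(self):
        pair = simple_pair((400, 800), "+", (100, 500), "-")
        assert classify_overlap(pair) == "divergent"

    def test_containment_beats_terminus_classes(self):
        pair = simple_pair((200, 300), "-", (100, 500), "+")
        assert classify_overlap(pair) == "lncRNA_within_mRNA"
        assert pair.total_containment
        pair2 = simple_pair((100, 500), "-", (200, 300), "+")
        assert classify_overlap(pair2) == "mRNA_within_lncRNA"

    def test_identical_spans_degenerate_tiebreak(self):
        pair = simple_pair((100, 500), "-", (100, 500), "+")
        assert classify_overlap(pair) == "lncRNA_within_mRNA"
        assert pair.degenerate

    def test_matches_terminus_oracle_on_random_geometry(self, rng):
        """Exhaustive cross-check on 10,000 random opposite-strand pairs;
        classes are also exhaustive and mutually exclusive."""
        checked = 0
        while checked < 10_000:
            s1 = int(rng.integers(0, 5000))
            e1 = s1 + int(rng.integers(100, 3000))
            s2 = int(rng.integers(max(0, s1 - 3000), e1))
            e2 = s2 + int(rng.integers(100, 3000))
            if min(e1, e2) - max(s1, s2) <= 0:
                continue
            strand = "+" if rng.integers(0, 2) else "-"
            anti = "-" if strand == "+" else "+"
            pair = simple_pair((s1, e1), strand, (s2, e2), anti)
            assert pair is not None
            got = classify_overlap(pair)
            assert got == terminus_oracle(pair.lnc, pair.mrna)
            checked += 1


class TestSummarizeClasses:
    def _pairs_with_classes(self, counts):
        pairs = []
        i = 0
        for cls, n in counts.items():
            for _ in range(n):
                lnc = GeneLocus(f"L{i}", "lncRNA", "chr1", "+", ((0, 100),))
                m = GeneLocus(f"M{i}", "mRNA", "chr1", "-", ((50, 150),))
                p = OverlapPair(lnc=lnc, mrna=m, overlap_mean=50.0,
                                overlap_min=50, overlap_max=50,
                                n_overlapping_isoform_pairs=1)
                p.overlap_class = cls
                p.total_containment = cls.endswith("within_mRNA") or \
                    cls.endswith("within_lncRNA")
                pairs.append(p)
                i += 1
        return pairs

    def test_reference_cohort_percentages(self):
        """The published 198-pair class counts give the published percents."""
        pairs = self._pairs_with_classes(
            {"convergent": 60, "divergent": 83,
             "lncRNA_within_mRNA": 40, "mRNA_within_lncRNA": 15})
        s = summarize_classes(pairs)
        assert s.total == 198
        got = dict(zip(s.classes["class"], s.classes["percent"]))
        assert got == {"convergent": 30.3, "divergent": 41.9,
                       "lncRNA_within_mRNA": 20.2, "mRNA_within_lncRNA": 7.6}
        assert (s.partial, s.containment) == (143, 55)
        assert (s.partial_percent, s.containment_percent) == (72.2, 27.8)
        assert abs(sum(got.values()) - 100.0) <= 0.2

    def test_single_pair_is_hundred_percent(self):
        pairs = self._pairs_with_classes({"divergent": 1})
        s = summarize_classes(pairs)
        assert s.total == 1
        got = dict(zip(s.classes["class"], s.classes["percent"]))
        assert got["divergent"] == 100.0

    def test_empty_input_total_zero(self):
        s = summarize_classes([])
        assert s.total == 0
        assert s.classes["count"].sum() == 0


class TestOverlapLengthVsCorrelation:
    def _pair(self, i, mean, mn, mx, expr_r):
        lnc = GeneLocus(f"L{i}", "lncRNA", "chr1", "+", ((0, 1000),))
        m = GeneLocus(f"M{i}", "mRNA", "chr1", "-", ((500, 1500),))
        p = OverlapPair(lnc=lnc, mrna=m, overlap_mean=mean, overlap_min=mn,
                        overlap_max=mx, n_overlapping_isoform_pairs=1)
        p.expression_r = expr_r
        return p

    def test_constructed_negative_slope_recovered(self, rng):
        """expression_r = -0.001*mean_length + noise -> r_mean < 0 and equal
        to a direct recomputation."""
        lengths = rng.integers(100, 5000, size=40)
        noise = 0.05 * rng.standard_normal(40)
        pairs = [
            self._pair(i, float(L), int(L) - 10, int(L) + 10,
                       float(-0.001 * L + eps))
            for i, (L, eps) in enumerate(zip(lengths, noise))
        ]
        out = overlap_length_vs_correlation(pairs)
        assert out["r_mean"] < 0
        direct = np.corrcoef([p.overlap_mean for p in pairs],
                             [p.expression_r for p in pairs])[0, 1]
        assert out["r_mean"] == pytest.approx(direct, abs=1e-12)

    def test_min_equals_mean_gives_identical_coefficient(self, rng):
        pairs = [
            self._pair(i, float(L), int(L), int(L), float(rng.standard_normal()))
            for i, L in enumerate(rng.integers(100, 5000, size=10))
        ]
        out = overlap_length_vs_correlation(pairs)
        assert out["r_min"] == pytest.approx(out["r_mean"], abs=1e-12)
        assert out["r_max"] == pytest.approx(out["r_mean"], abs=1e-12)

    def test_equal_lengths_flagged_missing(self):
        pairs = [self._pair(i, 100.0, 100, 100, 0.1 * i) for i in range(5)]
        out = overlap_length_vs_correlation(pairs)
        assert np.isnan(out["r_mean"])

    def test_too_few_pairs_is_error(self):
        pairs = [self._pair(0, 100.0, 90, 110, 0.5)]
        with pytest.raises(CernetError, match=">= 3"):
            overlap_length_vs_correlation(pairs)
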