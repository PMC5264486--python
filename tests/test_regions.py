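import numpy as np
import pytest

import histact as h
from histact.regions import _region_bins


def make_records(entries, bin_size=200):
    return [h.SignalRecord(c, b * bin_size, m, n) for c, b, m, n in entries]


class TestBinarize:
    def test_presence_rule(self):
        recs = make_records([("chr1", 0, "m", 0), ("chr1", 1, "m", 1), ("chr1", 2, "m", 347)])
        bsm = h.binarize(recs)
        assert bsm.value("chr1", 0, "m") == 0
        assert bsm.value("chr1", 1, "m") == 1
        assert bsm.value("chr1", 2, "m") == 1  # huge counts collapse to presence

    def test_count_threshold(self):
        recs = make_records([("chr1", 0, "m", 2), ("chr1", 1, "m", 3)])
        bsm = h.binarize(recs, threshold=2)
        assert bsm.value("chr1", 0, "m") == 0
        assert bsm.value("chr1", 1, "m") == 1

    def test_absent_cells_are_zero(self):
        bsm = h.binarize(make_records([("chr1", 0, "m", 1)]))
        assert bsm.value("chr1", 99, "m") == 0
        assert bsm.value("chrX", 0, "m") == 0

    def test_matches_per_record_oracle(self):
        rng = np.random.default_rng(5)
        recs = make_records(
            [
                (f"chr{int(rng.integers(1, 3))}", int(b), f"m{int(m)}", int(c))
                for b, m, c in zip(
                    rng.integers(0, 30, 200), rng.integers(0, 4, 200), rng.integers(0, 4, 200)
                )
            ]
        )
        thr = 1
        bsm = h.binarize(recs, threshold=thr)
        # independent per-record comparison: a cell is 1 iff some record exceeds thr
        for rec in recs:
            expected = any(
                r.count > thr
                for r in recs
                if (r.chrom, r.bin_start, r.modification)
                == (rec.chrom, rec.bin_start, rec.modification)
            )
            assert bsm.value(rec.chrom, rec.bin_start // 200, rec.modification) == int(expected)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            h.binarize([], threshold=-1)


class TestGeneRegions:
    def test_plus_strand(self):
        g = h.GeneAnnotation("g", "chr1", "+", 1000, 9000)
        got = dict((lab, b) for lab, _, b in h.gene_regions(g))
        assert got["TSS"] == 5
        assert got["TSS-1"] == 4
        assert got["TSS+1"] == 6
        assert got["TTS"] == 45
        assert got["TTS+1"] == 46

    def test_minus_strand_mirrors(self):
        g = h.GeneAnnotation("g", "chr1", "-", 9000, 1000)
        got = dict((lab, b) for lab, _, b in h.gene_regions(g))
        assert got["TSS"] == 45
        assert got["TSS-1"] == 46  # upstream = higher coordinate on '-'
        assert got["TSS+1"] == 44
        assert got["TTS"] == 5
        assert got["TTS+1"] == 4

    def test_off_chromosome_bins_missing(self):
        g = h.GeneAnnotation("g", "chr1", "+", 100, 3000)
        regions = h.gene_regions(g)
        missing = [lab for lab, _, b in regions if b is None]
        assert missing == [f"TSS-{k}" for k in range(10, 0, -1)]

    @pytest.mark.parametrize("strand,tss,tts", [("+", 5000, 9000), ("-", 9000, 5000)])
    def test_always_24_regions(self, strand, tss, tts):
        g = h.GeneAnnotation("g", "chr1", strand, tss, tts)
        assert len(h.gene_regions(g)) == 24


class TestFeatureMatrix:
    def test_936_features_for_39_modifications(self):
        mods = [f"mod{i:02d}" for i in range(39)]
        bsm = h.binarize([], modifications=mods)
        genes = [h.GeneAnnotation("g1", "chr1", "+", 5000, 9000)]
        fm = h.build_feature_matrix(bsm, genes)
        assert fm.values.shape == (1, 936)
        assert fm.n_features == 24 * 39

    def test_empty_signal_gives_zeros_without_mask(self):
        bsm = h.binarize([], modifications=["m"])
        genes = [h.GeneAnnotation("g1", "chr1", "+", 5000, 9000)]
        with pytest.warns(UserWarning, match="absent"):
            fm = h.build_feature_matrix(bsm, genes)
        # no chromosome data at all -> fully masked zero row
        assert fm.values.sum() == 0 and fm.mask.all()

    def test_zero_bins_not_masked_when_chromosome_known(self):
        bsm = h.binarize(make_records([("chr1", 60, "m", 0)]))
        genes = [h.GeneAnnotation("g1", "chr1", "+", 5000, 9000)]
        fm = h.build_feature_matrix(bsm, genes)
        assert fm.values.sum() == 0 and not fm.mask.any()

    def test_matches_per_gene_lookup_oracle(self, cd4_small):
        ds, fm, _ = cd4_small
        layout = h.default_layout()
        for gi in range(0, 40):  # direct double loop over genes and features
            gene = ds.genes[gi]
            regions = h.gene_regions(gene, layout)
            for lab, chrom, b in regions:
                for mod in fm.modifications:
                    col = fm.feature_index(lab, mod)
                    expected = 0 if b is None else ds.signal.value(chrom, b, mod)
                    assert fm.values[gi, col] == expected

    def test_mirror_consistency(self):
        """Reflecting the chromosome and flipping all strands leaves MATRIX 2
        unchanged."""
        rng = np.random.default_rng(3)
        L_bins = 200
        mods = ["mA", "mB"]
        entries = [
            ("chr1", int(b), mods[int(m)], 1)
            for b, m in zip(rng.integers(0, L_bins, 150), rng.integers(0, 2, 150))
        ]
        genes = [
            h.GeneAnnotation("g1", "chr1", "+", 50 * 200 + 100, 70 * 200 + 100),
            h.GeneAnnotation("g2", "chr1", "-", 130 * 200 + 100, 110 * 200 + 100),
        ]
        fm = h.build_feature_matrix(h.binarize(make_records(entries)), genes)

        refl_entries = [("chr1", L_bins - 1 - b, m, c) for _, b, m, c in entries]
        def reflect(g):
            flip = {"+": "-", "-": "+"}
            L = L_bins * 200
            return h.GeneAnnotation(g.gene_id, g.chrom, flip[g.strand], L - 1 - g.tss, L - 1 - g.tts)
        fm_r = h.build_feature_matrix(h.binarize(make_records(refl_entries)), [reflect(g) for g in genes])
        assert np.array_equal(fm.values, fm_r.values)
        assert np.array_equal(fm.mask, fm_r.mask)

    def test_region_and_modification_column_helpers(self, cd4_small):
        _, fm, _ = cd4_small
        cols = fm.region_columns("TSS")
        assert len(cols) == 39
        assert all(fm.feature_labels[c].startswith("TSS:") for c in cols)
        mcols = fm.modification_columns("H2BK5ac")
        assert len(mcols) == 24
        assert all(fm.feature_labels[c].endswith(":H2BK5ac") for c in mcols)
        with pytest.raises(KeyError):
            fm.region_columns("TSS-99")
        with pytest.raises(KeyError):
            fm.modification_columns("nope")


def test_layout_requires_24_labels():
    with pytest.raises(ValueError):
        h.RegionLayout(("TSS", "TTS"))
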