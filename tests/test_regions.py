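import numpy as np
import pandas as pd
import pytest

from driftscan import regions as rmod
from driftscan.regions import (CategoryEvidence, Region, build_evidence,
                               classify_region, merge_regions, name_region)


class TestNameRegion:
    @pytest.mark.parametrize("chrom,start,expected", [
        (2, 1_220_000, "SSC2:1"),
        (8, 80_670_000, "SSC8:80"),
        (1, 999_999, "SSC1:0"),
    ])
    def test_examples(self, chrom, start, expected):
        assert name_region(chrom, start) == expected

    def test_negative_start(self):
        with pytest.raises(ValueError):
            name_region(1, -5)


class TestRegionInvariants:
    def test_id_and_length(self):
        r = Region("2", 1_220_000, 1_530_000, {"hapFLK"})
        assert r.id == "SSC2:1"
        assert r.length_kb == 310

    def test_zero_length(self):
        r = Region("2", 145_180_000, 145_180_000, {"time-LWD+LS"})
        assert r.length_kb == 0


class TestMergeRegions:
    def test_within_test_gap_below_1mb_merges(self):
        out = merge_regions({"hapFLK": [("1", 100, 200),
                                        ("1", 800_200, 900_000)]})
        assert len(out) == 1
        assert out[0].start_bp == 100 and out[0].end_bp == 900_000

    def test_exactly_1mb_gap_stays_separate(self):
        out = merge_regions({"hapFLK": [("1", 100, 200),
                                        ("1", 1_000_200, 1_000_300)]})
        assert len(out) == 2

    def test_cross_test_needs_overlap(self):
        out = merge_regions({
            "hapFLK": [("1", 100, 500)],
            "time-LWD+LS": [("1", 400, 900)],     # overlaps
            "time-LWS+LS": [("1", 1_000, 1_200)]  # 100 bp gap: no merge
        })
        assert len(out) == 2
        first = out[0]
        assert first.tests == {"hapFLK", "time-LWD+LS"}
        assert (first.start_bp, first.end_bp) == (100, 900)

    def test_order_independent_and_idempotent(self):
        rng = np.random.default_rng(1)
        segs = []
        for _ in range(30):
            a = int(rng.integers(0, 10_000_000))
            segs.append(("1", a, a + int(rng.integers(1, 400_000))))
        base = merge_regions({"hapFLK": segs})

        def key(rs):
            return [(r.chrom, r.start_bp, r.end_bp, tuple(sorted(r.tests)))
                    for r in rs]

        for _ in range(5):
            perm = [segs[i] for i in rng.permutation(len(segs))]
            assert key(merge_regions({"hapFLK": perm})) == key(base)
        again = merge_regions({"hapFLK": [(r.chrom, r.start_bp, r.end_bp)
                                          for r in base]})
        assert key(again) == key(base)

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            merge_regions({"bogus": [("1", 1, 2)]})


class TestClassifyRegion:
    def test_convergent_pattern(self):
        ev = CategoryEvidence(shift_d=0.6, shift_s=0.55, same_target=True,
                              hapflk_significant=False)
        assert classify_region(ev) == "conv"

    def test_divergent_pattern(self):
        ev = CategoryEvidence(shift_d=0.4, shift_s=0.55, same_target=False,
                              hapflk_significant=True)
        assert classify_region(ev) == "div"

    def test_line_specific_pattern(self):
        ev = CategoryEvidence(shift_d=0.5, shift_s=0.02, same_target=False,
                              hapflk_significant=False)
        assert classify_region(ev) == "LWD"

    def test_conv_subcategory(self):
        ev = CategoryEvidence(shift_d=0.8, shift_s=0.4, same_target=True,
                              hapflk_significant=False)
        assert classify_region(ev) == "conv(LWD)"

    def test_unresolved_when_no_evidence(self):
        ev = CategoryEvidence(shift_d=0.05, shift_s=0.03, same_target=False,
                              hapflk_significant=False, sig_d=False,
                              sig_s=False, sug_d=False, sug_s=False)
        assert classify_region(ev) == "unresolved"

    def test_invalid_shift_rejected(self):
        with pytest.raises(ValueError):
            CategoryEvidence(shift_d=1.5, shift_s=0.0, same_target=False,
                             hapflk_significant=False)


class TestBuildEvidence:
    def make_tracks(self, f_anc, f_lwd, f_lws, p_d, p_s):
        n = len(f_anc)
        return pd.DataFrame({
            "chrom": "1", "pos": np.arange(1, n + 1) * 1000,
            "flk": np.ones(n), "hapflk": np.ones(n),
            "tlwd_p": p_d, "tlws_p": p_s,
            "f_anc": f_anc, "f_lwd": f_lwd, "f_lws": f_lws})

    def test_focal_snp_drives_shifts(self):
        region = Region("1", 1000, 5000, {"time-LWD+LS"})
        tracks = self.make_tracks(
            f_anc=[0.2, 0.2, 0.2, 0.2, 0.2],
            f_lwd=[0.25, 0.9, 0.3, 0.2, 0.2],
            f_lws=[0.2, 0.25, 0.2, 0.9, 0.2],
            p_d=[0.5, 1e-6, 0.5, 0.5, 0.5],
            p_s=[0.5, 0.9, 0.5, 0.5, 0.5])
        ev = build_evidence(region, tracks)
        # focal = site 2 (strongest combined temporal evidence)
        assert ev.shift_d == pytest.approx(0.7)
        assert ev.shift_s == pytest.approx(0.05)
        assert ev.sig_d and not ev.sig_s
        assert classify_region(ev) == "LWD"

    def test_opposite_directions_mark_different_targets(self):
        region = Region("1", 1000, 3000, {"hapFLK"})
        tracks = self.make_tracks(
            f_anc=[0.5, 0.5, 0.5], f_lwd=[0.95, 0.9, 0.5],
            f_lws=[0.1, 0.05, 0.5],
            p_d=[1e-4, 1e-3, 0.5], p_s=[1e-3, 1e-4, 0.5])
        ev = build_evidence(region, tracks)
        assert not ev.same_target
        assert classify_region(ev) == "div"
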