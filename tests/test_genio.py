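import numpy as np
import pytest

from driftscan import genio

from conftest import make_matrix

M = genio.MISSING


class TestAlleleFreqs:
    def test_all_het(self):
        g = make_matrix(np.full((3, 5), 1), ["P"] * 5)
        f = genio.allele_freqs(g, ["P"])
        assert np.allclose(f.freq, 0.5)

    def test_missing_excluded(self):
        d = np.full((1, 10), 2, dtype=np.int8)
        d[0, 0] = M
        g = make_matrix(d, ["P"] * 10)
        f = genio.allele_freqs(g, ["P"])
        assert f.freq[0, 0] == 1.0
        assert f.call_rate[0, 0] == 0.9

    def test_fuzz_matches_recount(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(50, 12)).astype(np.int8)
        d[rng.random(d.shape) < 0.15] = M
        pops = ["A"] * 5 + ["B"] * 7
        g = make_matrix(d, pops)
        f = genio.allele_freqs(g, ["A", "B"])
        for j, idx in ((0, slice(0, 5)), (1, slice(5, 12))):
            sub = d[:, idx]
            for v in range(50):
                row = sub[v][sub[v] != M]
                if row.size:
                    assert np.isclose(f.freq[v, j], row.sum() / (2 * row.size))
                else:
                    assert np.isnan(f.freq[v, j])
        assert np.nanmin(f.freq) >= 0 and np.nanmax(f.freq) <= 1


class TestMafFilter:
    @pytest.mark.parametrize("freq,expected", [(0.95, False), (0.101, True),
                                               (0.10, False), (0.5, True)])
    def test_strictness(self, freq, expected):
        n = 1000  # large sample so the realised frequency is exact
        d = np.zeros((1, n), dtype=np.int8)
        d[0, :int(round(freq * n))] = 2
        g = make_matrix(d, ["P"] * n)
        f = genio.allele_freqs(g, ["P"])
        mask = genio.maf_filter(f, ["P"], 0.10)
        assert mask[0] == expected

    def test_matches_bruteforce_pooled(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(80, 10)).astype(np.int8)
        g = make_matrix(d, ["A"] * 4 + ["B"] * 6)
        f = genio.allele_freqs(g, ["A", "B"])
        mask = genio.maf_filter(f, ["A", "B"], 0.1)
        for v in range(80):
            p = d[v].sum() / 20
            assert mask[v] == (min(p, 1 - p) > 0.1)

    def test_empty_pops_rejected(self):
        g = make_matrix(np.zeros((2, 2), dtype=np.int8), ["A", "A"])
        f = genio.allele_freqs(g, ["A"])
        with pytest.raises(ValueError):
            genio.maf_filter(f, [], 0.1)


class TestDiversitySummary:
    def test_private_to_anc_only(self):
        # variant seen 0/1 only in ANC; fixed ref elsewhere
        d = np.array([[1, 0, 0, 0]], dtype=np.int8)
        g = make_matrix(d, ["ANC", "ANC", "LWD", "LWS"])
        out = genio.diversity_summary(g).set_index("population")
        assert out.loc["ANC", "pct_polymorphic"] == 100.0
        assert out.loc["ANC", "pct_private"] == 100.0
        assert out.loc["LWD", "pct_polymorphic"] == 0.0
        assert out.loc["LWD", "pct_private"] == 0.0

    def test_monomorphic_counts_nowhere(self):
        d = np.zeros((4, 6), dtype=np.int8)
        g = make_matrix(d, ["A"] * 3 + ["B"] * 3)
        out = genio.diversity_summary(g)
        assert (out["pct_polymorphic"] == 0).all()

    def test_matches_bruteforce(self, neutral_matrix):
        out = genio.diversity_summary(neutral_matrix).set_index("population")
        d = neutral_matrix.dosage
        pops = np.array([neutral_matrix.populations[s]
                         for s in neutral_matrix.samples])
        total_alt = np.where(d == M, 0, d).sum(axis=1)
        total_called = 2 * (d != M).sum(axis=1)
        minor_is_alt = 2 * total_alt <= total_called
        for pop in ("ANC", "LWD", "LWS"):
            sub = d[:, pops == pop]
            alt = np.where(sub == M, 0, sub).sum(axis=1)
            called = 2 * (sub != M).sum(axis=1)
            poly = (alt > 0) & (alt < called)
            assert np.isclose(out.loc[pop, "pct_polymorphic"],
                              100 * poly.mean())


class TestIbsMds:
    def test_duplicate_samples_coincide(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 3, size=(100, 3)).astype(np.int8)
        d = np.hstack([base, base[:, :1]])   # sample 3 duplicates sample 0
        g = make_matrix(d, ["P"] * 4)
        dist, _ = genio.ibs_distance(g, min_sites=10)
        assert dist[0, 3] == 0
        coords = genio.ibs_mds(g, k=2)
        assert np.allclose(coords.iloc[0, 2:].to_numpy(float),
                           coords.iloc[3, 2:].to_numpy(float), atol=1e-9)

    def test_collinear_distances_recovered_in_1d(self):
        # three points on a line: distances 1, 2, 3
        dist = np.array([[0, 1.0, 3.0], [1.0, 0, 2.0], [3.0, 2.0, 0]])
        coords = genio.classical_mds(dist, 1)[:, 0]
        rec = np.abs(coords[:, None] - coords[None, :])
        assert np.allclose(rec, dist, atol=1e-9)

    def test_populations_cluster(self, neutral_matrix):
        from sklearn.metrics import silhouette_score
        coords = genio.ibs_mds(neutral_matrix, k=2)
        score = silhouette_score(coords[["C1", "C2"]],
                                 coords["population"])
        assert score > 0

    def test_symmetry_and_range(self, neutral_matrix):
        dist, rel = genio.ibs_distance(neutral_matrix)
        assert np.allclose(dist, dist.T)
        assert np.allclose(np.diag(dist), 0)
        assert np.nanmin(dist) >= 0 and np.nanmax(dist) <= 1


class TestWindowedMissingness:
    def test_no_missing(self):
        g = make_matrix(np.ones((5, 4), dtype=np.int8), ["P"] * 4,
                        pos=[100, 500, 2500, 3000, 5000])
        out = genio.windowed_missingness(g, 2000)
        assert (out.dropna()["missing_frac"] == 0).all()

    def test_quarter_missing(self):
        d = np.ones((4, 10), dtype=np.int8)
        d[0] = M   # one fully missing variant of 4 in the same window
        g = make_matrix(d, ["P"] * 10, pos=[10, 20, 30, 40])
        out = genio.windowed_missingness(g, 2000)
        assert out.iloc[0]["missing_frac"] == 0.25

    def test_fuzz_matches_recount(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(60, 8)).astype(np.int8)
        d[rng.random(d.shape) < 0.2] = M
        pos = np.sort(rng.choice(np.arange(1, 10001), 60, replace=False))
        g = make_matrix(d, ["P"] * 8, pos=pos)
        out = genio.windowed_missingness(g, 2000)
        for _, row in out.iterrows():
            sel = (pos >= row["start"]) & (pos <= row["end"])
            if sel.any():
                assert np.isclose(row["missing_frac"],
                                  (d[sel] == M).mean())
            else:
                assert np.isnan(row["missing_frac"])


class TestReadVcf:
    def write(self, tmp_path, body):
        vcf = tmp_path / "t.vcf"
        header = ("##fileformat=VCFv4.2\n"
                  '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
                  "##contig=<ID=1>\n"
                  "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                  "\ts1\ts2\n")
        vcf.write_text(header + body)
        return vcf

    def test_missing_and_modes(self, tmp_path):
        body = ("1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t./.\n"
                "1\t200\t.\tA\tG,T\t.\t.\t.\tGT\t0/1\t0/2\n"   # triallelic
                "1\t300\t.\tA\tAT\t.\t.\t.\tGT\t1/1\t0/0\n")    # indel
        vcf = self.write(tmp_path, body)
        smap = {"s1": "P", "s2": "P"}
        hq = genio.read_vcf(vcf, smap, mode="HQ")
        assert len(hq.variants) == 1          # triallelic + indel dropped
        assert hq.dosage[0, 0] == 1 and hq.dosage[0, 1] == M
        av = genio.read_vcf(vcf, smap, mode="AV")
        assert len(av.variants) == 2          # biallelic indel kept
        assert list(av.variants["pos"]) == [100, 300]

    def test_unknown_sample_rejected(self, tmp_path):
        vcf = self.write(tmp_path, "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\n")
        with pytest.raises(ValueError, match="not in VCF header"):
            genio.read_vcf(vcf, {"nope": "P"})
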