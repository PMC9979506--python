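import numpy as np
import pandas as pd
import pytest

from driftscan import posthoc
from driftscan.regions import Region


@pytest.fixture()
def genes():
    return pd.DataFrame({
        "chrom": ["1"] * 5,
        "start": [1_000_000, 2_500_000, 2_560_000, 5_000_000, 9_000_000],
        "end":   [1_100_000, 2_550_000, 2_600_000, 5_050_000, 9_100_000],
        "gene":  ["G1", "G2", "G3", "G4", "G5"]})


class TestAssignGenes:
    def test_overlap(self, genes):
        region = Region("1", 1_050_000, 1_060_000)
        out, flanking = posthoc.assign_genes(region, genes)
        assert out == ["G1"] and not flanking

    def test_flanking_rule(self, genes):
        # empty region: G2 is 0.5 Mb to the left; G1 is 1.35 Mb beyond G2's
        # start so only G2 from that side... and G4 2.55 Mb to the right.
        region = Region("1", 3_050_000, 3_060_000)
        out, flanking = posthoc.assign_genes(region, genes)
        assert flanking
        assert "G3" in out          # nearest left gene at 0.45 Mb
        assert "G2" in out          # second left gene 10 kb beyond G3
        assert "G4" not in out      # right gene ~1.9 Mb away

    def test_far_genes_excluded(self, genes):
        region = Region("1", 7_000_000, 7_001_000)
        out, flanking = posthoc.assign_genes(region, genes)
        # left gene G4 1.95 Mb away, right gene G5 2 Mb away: none within 1 Mb
        assert out == [] and not flanking

    def test_max_four_flanking(self, genes):
        region = Region("1", 2_700_000, 2_710_000)
        out, _ = posthoc.assign_genes(region, genes)
        assert len(out) <= 4


class TestGtfParsing:
    def test_both_dialects(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            '1\tens\tgene\t100\t200\t.\t+\t.\tgene_id "g1"; gene_name "N1";\n'
            '1\tens\ttranscript\t100\t200\t.\t+\t.\tgene_id "g1";\n'
            "malformed line\n"
            "1\tens\tgene\t300\t400\t.\t-\t.\tID=g2;Name=N2\n")
        out = posthoc.read_gene_annotation(gtf)
        assert list(out["gene"]) == ["N1", "N2"]
        assert out.attrs["n_skipped"] == 1


class TestQtlEnrichment:
    def make(self, *rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "trait_category", "weight"])

    def test_direct_qtl_scores_five(self):
        regions = [Region("1", 1_000_000, 1_100_000, category="conv")]
        qtls = self.make(("1", 1_050_000, 1_060_000, "Both", 5))
        table, _ = posthoc.qtl_enrichment(regions, qtls)
        assert table.loc["Both", "conv"] == 5

    def test_indirect_within_2mb_adds_one(self):
        regions = [Region("1", 1_000_000, 1_100_000, category="conv")]
        qtls = self.make(("1", 1_050_000, 1_060_000, "Both", 5),
                         ("1", 3_000_000, 3_010_000, "Both", 1))  # 1.9 Mb
        table, _ = posthoc.qtl_enrichment(regions, qtls)
        assert table.loc["Both", "conv"] == 6

    def test_exactly_2mb_excluded(self):
        regions = [Region("1", 1_000_000, 1_100_000, category="conv")]
        qtls = self.make(("1", 3_100_000, 3_200_000, "Dam", 5))
        with pytest.raises(ValueError, match="no QTL within range"):
            posthoc.qtl_enrichment(regions, qtls)

    def test_bad_weight_rejected(self):
        regions = [Region("1", 1, 2, category="conv")]
        with pytest.raises(ValueError, match="weights"):
            posthoc.qtl_enrichment(regions, self.make(("1", 1, 2, "Dam", 3)))


class TestResiduals:
    def test_hand_computed_diagonal_table(self):
        table = pd.DataFrame([[10.0, 0.0], [0.0, 10.0]],
                             index=["t1", "t2"], columns=["c1", "c2"])
        r = posthoc.adjusted_residuals(table)
        expected = 5.0 / np.sqrt(5 * 0.5 * 0.5)
        assert r.loc["t1", "c1"] == pytest.approx(expected)
        assert r.loc["t1", "c2"] == pytest.approx(-expected)
        assert r.loc["t2", "c1"] == pytest.approx(-expected)

    def test_observed_minus_expected_sums_to_zero(self):
        rng = np.random.default_rng(1)
        O = pd.DataFrame(rng.integers(0, 30, (3, 4)).astype(float))
        N = O.to_numpy().sum()
        E = np.outer(O.sum(axis=1), O.sum(axis=0)) / N
        diff = O.to_numpy() - E
        assert np.allclose(diff.sum(axis=0), 0, atol=1e-9)
        assert np.allclose(diff.sum(axis=1), 0, atol=1e-9)
        r = posthoc.adjusted_residuals(O)
        assert np.all(np.sign(r.to_numpy()[diff != 0])
                      == np.sign(diff[diff != 0]))


class TestFunctionAssociation:
    def test_concentrated_function_positive_residual(self):
        gene_fun = pd.DataFrame({"gene": ["A", "B"], "function": ["f", "f"]})
        region_genes = pd.DataFrame({
            "gene": ["A", "B", "C", "D"],
            "region_id": ["r1", "r2", "r3", "r4"],
            "category": ["LWD", "LWD", "LWS", "LWS"]})
        gene_fun = pd.concat([gene_fun, pd.DataFrame(
            {"gene": ["C", "D"], "function": ["g", "g"]})])
        _, resid = posthoc.function_association(gene_fun, region_genes)
        assert resid.loc["f", "LWD"] > 0
        assert resid.loc["f", "LWS"] < 0

    def test_permutation_null_centres_at_zero(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        region_genes = pd.DataFrame({
            "gene": genes, "region_id": [f"r{i}" for i in range(40)],
            "category": ["LWD"] * 20 + ["LWS"] * 20})
        # signal: function f annotates LWD genes only
        signal = pd.DataFrame({"gene": genes[:10] + genes[20:30],
                               "function": ["f"] * 10 + ["g"] * 10})
        _, obs = posthoc.function_association(signal, region_genes)
        perm_max = []
        for _ in range(50):
            shuffled = signal.copy()
            shuffled["gene"] = rng.permutation(
                np.array(genes))[:len(signal)]
            try:
                _, r = posthoc.function_association(shuffled, region_genes)
                perm_max.append(np.abs(r.to_numpy()).max())
            except ValueError:
                continue
        assert np.abs(obs.to_numpy()).max() > np.quantile(perm_max, 0.95)


class TestAnnParsing:
    def test_worst_impact_across_transcripts(self):
        ann = ("G|missense_variant|MODERATE|X|X|transcript|T1|x|x|x|x|x|x|x|x,"
               "G|synonymous_variant|LOW|X|X|transcript|T2|x|x|x|x|x|x|x|x")
        assert posthoc.worst_impact(ann) == "MODERATE"

    def test_none_when_absent(self):
        assert posthoc.worst_impact(None) == "none"
        assert posthoc.worst_impact("garbage") == "none"


class TestPrioritizeVariants:
    def make_tracks(self, flk_vals, p_d=None):
        n = len(flk_vals)
        return pd.DataFrame({
            "chrom": "1", "pos": np.arange(1, n + 1) * 100,
            "flk": flk_vals,
            "tlwd_p": p_d if p_d is not None else np.full(n, 0.5),
            "tlws_p": np.full(n, 0.5)})

    def test_single_valid_max_is_sole_candidate(self):
        region = Region("1", 100, 300, category="div")
        tracks = self.make_tracks([10.0, 2.0, 1.0])
        out = posthoc.prioritize_variants(
            region, tracks, call_rate=np.ones(3),
            shift_d=np.array([0.5, 0.5, 0.5]),
            shift_s=np.array([-0.5, -0.5, -0.5]))
        assert out[0].status == "candidate"
        assert out[0].strategy == "statistical"
        assert [v.status for v in out[1:]] == ["valid", "valid"]

    def test_low_call_rate_invalidates_top(self):
        region = Region("1", 100, 300, category="div")
        tracks = self.make_tracks([10.0, 8.0, 1.0])
        out = posthoc.prioritize_variants(
            region, tracks, call_rate=np.array([0.2, 1.0, 1.0]),
            shift_d=np.full(3, 0.5), shift_s=np.full(3, -0.5))
        assert out[0].status == "invalid"
        assert out[1].status == "candidate"

    def test_functional_needs_impact(self):
        region = Region("1", 100, 400, category="div")
        tracks = self.make_tracks([10.0, 9.9, 8.5, 8.4])
        out = posthoc.prioritize_variants(
            region, tracks, call_rate=np.ones(4),
            shift_d=np.full(4, 0.5), shift_s=np.full(4, -0.5),
            impacts=["none", "none", "MODERATE", "none"], cap=2)
        assert out[0].strategy == "statistical"
        assert out[1].strategy == "statistical"
        assert out[2].strategy == "functional"   # >= 80% of max + impact
        assert out[3].status == "valid"          # same stat bracket, no impact

    def test_candidate_subset_of_valid(self):
        rng = np.random.default_rng(3)
        region = Region("1", 100, 2000, category="LWD")
        n = 15
        tracks = self.make_tracks(rng.uniform(0, 5, n),
                                  p_d=rng.uniform(1e-6, 1, n))
        out = posthoc.prioritize_variants(
            region, tracks, call_rate=rng.uniform(0.5, 1, n),
            shift_d=rng.uniform(-0.6, 0.6, n), shift_s=rng.normal(0, 0.1, n))
        for v in out:
            if v.status == "candidate":
                assert v.strategy in {"statistical", "functional"}
        assert sum(v.strategy == "statistical" for v in out) <= 3
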