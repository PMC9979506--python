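import numpy as np
import pytest

from driftscan import genio, simdata
from driftscan.flk import reynolds_distance


def test_large_ne_limit_no_drift():
    """With huge Ne and one generation, the three samples only differ by
    binomial sampling noise around the shared ancestral frequencies."""
    cfg = simdata.SimConfig(ne_anc=2000, ne_d=2000, ne_s=2000,
                            gens_pre_split=1, gens_post_split=1,
                            n_snps_per_chrom=300, burnin_gens=0, seed=7)
    haps, _ = simdata.simulate_design(cfg, [])
    g = genio.from_haplotypes(haps)
    f = genio.allele_freqs(g, ["ANC", "LWD", "LWS"])
    p = f.freq
    common = (p[:, 0] > 0.2) & (p[:, 0] < 0.8)
    for j in (1, 2):
        diff = p[common, j] - p[common, 0]
        # binomial sd at n = 20-26 alleles is ~0.1; no systematic drift
        assert np.abs(diff.mean()) < 0.03
        assert np.abs(diff).mean() < 0.15


def test_selection_orders_line_means():
    """Monte-Carlo oracle: s_d = 0.5, s_s = 0 leaves line D at higher mean
    final frequency than line S."""
    finals_d, finals_s = [], []
    for rep in range(40):
        cfg = simdata.SimConfig(n_snps_per_chrom=50, chrom_length_bp=500_000,
                                burnin_gens=10, seed=100 + rep)
        scen = [simdata.SelectionScenario("1", 250_000, s_d=0.5,
                                          label="line_d")]
        _, truth = simdata.simulate_design(cfg, scen)
        finals_d.append(truth.trajectories[0]["LWD"][-1])
        finals_s.append(truth.trajectories[0]["LWS"][-1])
    assert np.mean(finals_d) > np.mean(finals_s) + 0.1


def test_conv_scenario_exceeds_neutral_drift_quantile():
    """Both lines' frequency changes under convergent s = 0.3 exceed the
    97.5% quantile of matched neutral drift (neutral-simulation oracle)."""
    rng = np.random.default_rng(0)

    def drift_quantile(f0, ne, gens, n=4000):
        f = np.full(n, f0)
        for _ in range(gens):
            f = rng.binomial(2 * ne, f) / (2 * ne)
        return np.quantile(np.abs(f - f0), 0.975)

    hits_d = hits_s = 0
    n_rep = 10
    for rep in range(n_rep):
        cfg = simdata.SimConfig(n_snps_per_chrom=60, chrom_length_bp=500_000,
                                burnin_gens=10, seed=300 + rep)
        scen = [simdata.SelectionScenario("1", 250_000, s_d=0.3, s_s=0.3,
                                          label="conv")]
        _, truth = simdata.simulate_design(cfg, scen)
        tr = truth.trajectories[0]
        f0 = tr["LWD"][0]
        gens = cfg.total_gens
        q_d = drift_quantile(f0, cfg.ne_d, gens)
        q_s = drift_quantile(f0, cfg.ne_s, gens)
        hits_d += abs(tr["LWD"][-1] - f0) > q_d
        hits_s += abs(tr["LWS"][-1] - f0) > q_s
    assert hits_d >= 0.7 * n_rep
    assert hits_s >= 0.7 * n_rep


def test_vcf_roundtrip(tmp_path):
    cfg = simdata.SimConfig(n_snps_per_chrom=40, chrom_length_bp=100_000,
                            burnin_gens=5, seed=3)
    haps, _ = simdata.simulate_design(cfg, [])
    vcf = tmp_path / "sim.vcf"
    smap = tmp_path / "samples.tsv"
    simdata.write_vcf(haps, vcf)
    simdata.write_sample_map(haps, smap)
    g = genio.read_vcf(vcf, smap)
    direct = genio.from_haplotypes(haps)
    assert np.array_equal(g.dosage, direct.dosage)
    assert g.samples == direct.samples
    f = genio.allele_freqs(g)
    assert np.allclose(f.call_rate, 1.0)


def test_vcf_missingness_binomial(tmp_path):
    cfg = simdata.SimConfig(n_snps_per_chrom=300, chrom_length_bp=500_000,
                            burnin_gens=5, seed=5)
    haps, _ = simdata.simulate_design(cfg, [])
    vcf = tmp_path / "m.vcf"
    simdata.write_vcf(haps, vcf, missing_rate=0.1, seed=11)
    simdata.write_sample_map(haps, tmp_path / "s.tsv")
    g = genio.read_vcf(vcf, tmp_path / "s.tsv")
    frac = (g.dosage == genio.MISSING).mean()
    n = g.dosage.size
    se = np.sqrt(0.1 * 0.9 / n)
    assert abs(frac - 0.1) < 3 * se


class TestTemporalCounts:
    def test_zero_generations_independent_draws(self):
        c1, c2 = simdata.simulate_temporal_counts(
            80, 0.0, 0.4, 0, (50, 50), 20000, seed=1)
        # both are Binomial(100, 0.4); difference variance = 2 * npq / n^2
        d = c1 / 100 - c2 / 100
        expected = 2 * 0.4 * 0.6 / 100
        assert abs(d.var() / expected - 1) < 0.05
        assert abs(np.corrcoef(c1, c2)[0, 1]) < 0.03

    def test_neutral_drift_variance_formula(self):
        """Var(p2_hat - p1_hat) = drift variance + both sampling terms."""
        ne, gens, f0, ndip = 80, 25, 0.3, 50
        c1, c2 = simdata.simulate_temporal_counts(
            ne, 0.0, f0, gens, (ndip, ndip), 40000, seed=2)
        d = c2 / (2 * ndip) - c1 / (2 * ndip)
        decay = (1 - 1 / (2 * ne)) ** gens
        pq = f0 * (1 - f0)
        expected = (pq * (1 - decay)            # drift
                    + pq / (2 * ndip)           # sampling at time 1
                    + pq * decay / (2 * ndip))  # sampling at time 2
        assert abs(d.var() / expected - 1) < 0.05

    def test_deterministic_recursion_large_ne(self):
        ne, s, f0, gens = 10**6, 0.3, 0.1, 25
        _, c2 = simdata.simulate_temporal_counts(
            ne, s, f0, gens, (500, 500), 2000, seed=3)
        expected = simdata.deterministic_trajectory(f0, s, gens)[-1]
        assert abs(c2.mean() / 1000 - expected) < 0.01

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            simdata.simulate_temporal_counts(80, 0.1, 0.5, 0, (10, 10), 10)
        with pytest.raises(ValueError):
            simdata.simulate_temporal_counts(80, -1.5, 0.5, 5, (10, 10), 10)
        with pytest.raises(ValueError):
            simdata.simulate_temporal_counts(80, 0.0, 0.0, 5, (10, 10), 10)


def test_scenario_validation():
    with pytest.raises(ValueError):
        simdata.SelectionScenario("1", 100, s_d=0.3, s_s=0.3, label="div")
    with pytest.raises(ValueError):
        simdata.SelectionScenario("1", 100, s_d=-1.2, label="line_d")
    cfg = simdata.SimConfig(n_snps_per_chrom=20, chrom_length_bp=10_000,
                            burnin_gens=1, seed=1)
    with pytest.raises(ValueError, match="not on the simulated map"):
        simdata.simulate_design(cfg, [simdata.SelectionScenario(
            "9", 5_000, s_d=0.3, label="line_d")])
    with pytest.raises(ValueError, match="outside"):
        simdata.simulate_design(cfg, [simdata.SelectionScenario(
            "1", 99_999_999, s_d=0.3, label="line_d")])


def test_seeded_determinism():
    cfg = simdata.SimConfig(n_snps_per_chrom=80, chrom_length_bp=200_000,
                            burnin_gens=10, seed=9)
    scen = [simdata.SelectionScenario("1", 100_000, s_d=0.3, label="line_d")]
    h1, t1 = simdata.simulate_design(cfg, scen)
    h2, t2 = simdata.simulate_design(cfg, scen)
    assert np.array_equal(h1.pos, h2.pos)
    for pop in ("ANC", "LWD", "LWS"):
        assert np.array_equal(h1.haplotypes[pop], h2.haplotypes[pop])
    assert np.array_equal(t1.trajectories[0]["LWD"], t2.trajectories[0]["LWD"])


def test_line_divergence_grows_with_time():
    """Neutral between-line drift distance increases with the post-split
    time (monotone in expectation over replicate batches)."""
    def mean_dist(gens_post, reps=4):
        out = []
        for rep in range(reps):
            cfg = simdata.SimConfig(n_snps_per_chrom=150,
                                    chrom_length_bp=500_000, burnin_gens=20,
                                    gens_post_split=gens_post, seed=600 + rep)
            haps, _ = simdata.simulate_design(cfg, [])
            g = genio.from_haplotypes(haps)
            f = genio.allele_freqs(g, ["ANC", "LWD", "LWS"])
            mask = genio.maf_filter(f, ["ANC"], 0.05)
            out.append(reynolds_distance(f, "LWD", "LWS", mask))
        return np.mean(out)

    assert mean_dist(25) > mean_dist(3)
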