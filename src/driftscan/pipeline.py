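"""Scan orchestration, configuration and the packaged reference region table.

``run_scan`` chains the full analysis on an in-memory genotype matrix:
allele frequencies and MAF filters, population-tree estimation, the FLK and
hapFLK differentiation scans, the two temporal HMM tests with local-score
segmentation, region merging/naming and scenario classification.

The packaged reference table transcribes the 38 regions reported by the
published French Large White two-line scan; its aggregates (category counts,
median length, gene totals) serve as worked-example checks of the region
plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import flk as flk_mod
from . import genio, hapclust, localscore, wfhmm
from . import regions as regions_mod

TEST_ALIASES = {"LWD": "time-LWD+LS", "LWS": "time-LWS+LS",
                "hapFLK": "hapFLK"}


@dataclass
class PipelineConfig:
    """All tunables of the scan; defaults follow the published settings."""

    K: int = 10                 # haplotype clusters
    nfit: int = 10              # EM restarts averaged in hapFLK
    maf: float = 0.10           # MAF filter (strictly above)
    fdr: float = 0.20           # q-value cutoff for hapFLK
    fpr: float = 0.01           # chromosome-wide local-score FPR
    xi: float = 2.0             # local-score shift
    ne_d: int = 80              # temporal Ne of the dam line
    ne_s: int = 74              # temporal Ne of the sire line
    gens: int = 25              # generations between sampling times
    tau_hi: float = 0.2         # classification: "high" shift
    tau_lo: float = 0.1         # classification: "little" shift
    call_rate: float = 0.8      # variant validity threshold
    stat_cut: float = 0.95      # statistical candidate cut (fraction of max)
    func_cut: float = 0.80      # functional candidate cut
    cap: int = 3                # max statistical candidates per region
    ls_reps: int = 1000         # Monte-Carlo replicates for LS calibration
    seed: int = 0

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for key, val in asdict(self).items():
                fh.write(f"{key}={val}\n")

    @classmethod
    def read(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in
                 cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        casts = {"int": int, "float": float}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts[types[key]](val.strip())
        return cls(**kwargs)


def significant_segments(chrom: np.ndarray, pos: np.ndarray,
                         sig: np.ndarray) -> list[tuple[str, int, int]]:
    """Maximal runs of consecutive significant SNPs as (chrom, start, end)."""
    out = []
    for c in dict.fromkeys(chrom):
        m = chrom == c
        p, s = pos[m], sig[m]
        if not s.any():
            continue
        idx = np.flatnonzero(s)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for a, b in zip(starts, ends):
            out.append((str(c), int(p[idx[a]]), int(p[idx[b]])))
    return out


def run_scan(g: genio.GenotypeMatrix, config: PipelineConfig | None = None,
             g_av: genio.GenotypeMatrix | None = None,
             classify: bool = True, run_hapflk: bool = True,
             outdir: str | Path | None = None) -> dict:
    """Execute the full scan on a genotype matrix.

    ``g`` is the high-quality variant set used genome-wide; ``g_av``
    optionally supplies the all-variant set for region re-scans (defaults to
    ``g``).  Returns a dict with the per-test tables, the tree and the final
    region list; TSV artefacts are written when ``outdir`` is given.
    """
    cfg = config or PipelineConfig()
    g_av = g_av if g_av is not None else g
    pops = ["ANC", "LWD", "LWS"]
    freqs = genio.allele_freqs(g, pops)
    chrom = g.variants["chrom"].to_numpy()
    pos = g.variants["pos"].to_numpy()

    anc_mask = genio.maf_filter(freqs, ["ANC"], cfg.maf)
    tree = flk_mod.estimate_tree(freqs, ["LWD", "LWS"], "ANC", mask=anc_mask)

    results: dict = {"tree": tree, "config": cfg}
    per_test_segments: dict[str, list] = {}

    flk_res = flk_mod.flk_test(freqs, tree)
    flk_res.loc[~anc_mask, ["flk", "p", "p0_hat"]] = np.nan
    results["flk"] = flk_res

    if run_hapflk:
        sub = g.subset_variants(anc_mask)
        hap = hapclust.hapflk_test(sub, tree, K=cfg.K, nfit=cfg.nfit,
                                   seed=cfg.seed)
        results["hapflk"] = hap
        sig = (hap["q"] < cfg.fdr).to_numpy()
        per_test_segments["hapFLK"] = significant_segments(
            hap["chrom"].to_numpy(), hap["pos"].to_numpy(), sig)

    ia = freqs.pop_index("ANC")
    for line, ne, test in (("LWD", cfg.ne_d, "time-LWD+LS"),
                           ("LWS", cfg.ne_s, "time-LWS+LS")):
        il = freqs.pop_index(line)
        mask = genio.maf_filter(freqs, ["ANC", line], cfg.maf)
        res = wfhmm.temporal_test(
            freqs.alt_count[mask, ia], freqs.n_samples["ANC"],
            freqs.alt_count[mask, il], freqs.n_samples[line],
            ne=ne, gens=cfg.gens, randomize=True, seed=cfg.seed + 211,
            called1=freqs.called[mask, ia], called2=freqs.called[mask, il])
        res.insert(0, "chrom", chrom[mask])
        res.insert(1, "pos", pos[mask])
        results["tlwd" if line == "LWD" else "tlws"] = res

        # the Lindley stage uses the atom-randomised p-values: the threshold
        # calibration assumes uniform null p-values, which the conservative
        # discrete exact p-values are not
        segs = []
        for c, grp in res.groupby("chrom", sort=False):
            thr = localscore.calibrate_threshold(
                len(grp), cfg.xi, cfg.fpr, cfg.ls_reps, seed=cfg.seed + 17)
            for s in localscore.call_segments(
                    localscore.lindley(grp["p_rand"].to_numpy(), cfg.xi), thr,
                    grp["pos"].to_numpy()):
                segs.append((str(c), s.start_bp, s.end_bp))
        per_test_segments[test] = segs

    regions = regions_mod.merge_regions(
        {t: s for t, s in per_test_segments.items() if s})
    if classify:
        for region in regions:
            try:
                tracks, cfreqs, cpops = regions_mod.rescan_region(
                    region, g_av, tree, cfg.ne_d, cfg.ne_s, cfg.gens,
                    K=cfg.K, nfit=max(2, cfg.nfit // 5), seed=cfg.seed)
                ev = regions_mod.build_evidence(
                    region, tracks, cluster_freqs=cfreqs, pops=cpops,
                    xi=cfg.xi)
                region.category = regions_mod.classify_region(
                    ev, {"tau_hi": cfg.tau_hi, "tau_lo": cfg.tau_lo})
            except ValueError:
                region.category = "unresolved"
    results["regions"] = regions

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key in ("flk", "hapflk", "tlwd", "tlws"):
            if key in results:
                results[key].to_csv(outdir / f"{key}.tsv", sep="\t",
                                    index=False, float_format="%.6g")
        regions_mod.regions_to_frame(regions).to_csv(
            outdir / "regions.tsv", sep="\t", index=False,
            float_format="%.6g")
    return results


def _region_mask(g: genio.GenotypeMatrix, region) -> np.ndarray:
    return ((g.variants["chrom"] == region.chrom)
            & (g.variants["pos"] >= region.start_bp)
            & (g.variants["pos"] <= region.end_bp)).to_numpy()


# ---------------------------------------------------------------------------
# scenario-recovery harness (shared by the test suite and the acceptance
# script): one selected chromosome plus one neutral chromosome, dam/sire
# split at the first sampling time, 25 generations of line selection

SCENARIO_S = {"line_d": (0.3, 0.0), "line_s": (0.0, 0.3),
              "conv": (0.3, 0.3), "div": (0.3, -0.3)}
# divergent selection presupposes standing variation both alleles can be
# selected from, so the div scenario starts at an intermediate frequency
SCENARIO_F0 = {"line_d": 0.2, "line_s": 0.2, "conv": 0.2, "div": 0.5}


def scenario_replicate(label: str, seed: int, s: float = 0.3,
                       n_snps: int = 500, with_hapflk: bool | None = None,
                       max_tries: int = 5) -> dict:
    """Simulate one single-scenario design and run the scan on it.

    Returns a dict with keys ``detected`` (a region covers the selected
    locus +-250 kb), ``category`` (classification of that region, or None),
    ``locus`` and ``final_freqs``.  Replicates where the favoured allele was
    lost in every selected line (a failed sweep attempt: no signature
    exists) are redrawn with a shifted seed, as in establishment-conditioned
    sweep power studies.
    """
    from . import simdata

    s_d, s_s = SCENARIO_S[label]
    s_d, s_s = s_d and np.sign(s_d) * s, s_s and np.sign(s_s) * s
    if with_hapflk is None:
        with_hapflk = label == "div"
    for attempt in range(max_tries):
        rep_seed = seed + 100_000 * attempt
        cfg_sim = simdata.SimConfig(
            n_chrom=2, chrom_length_bp=2_000_000, n_snps_per_chrom=n_snps,
            gens_pre_split=0, gens_post_split=25, burnin_gens=120,
            seed=rep_seed)
        scen = [simdata.SelectionScenario("1", 1_000_000, s_d=s_d, s_s=s_s,
                                          label=label,
                                          f0=SCENARIO_F0[label])]
        haps, truth = simdata.simulate_design(cfg_sim, scen)
        traj = truth.trajectories[0]
        finals = {"LWD": float(traj["LWD"][-1]), "LWS": float(traj["LWS"][-1])}
        # every line under selection must have moved its favoured allele to
        # the majority side, else no signature exists to detect
        established = True
        for line, coef in (("LWD", s_d), ("LWS", s_s)):
            if coef > 0:
                established &= finals[line] >= 0.5
            elif coef < 0:
                established &= finals[line] <= 0.5
        if established:
            break
    g = genio.from_haplotypes(haps)
    cfg = PipelineConfig(nfit=2, ls_reps=1000, seed=rep_seed % 2**16)
    res = run_scan(g, cfg, run_hapflk=with_hapflk, classify=True)
    locus = truth.realized_bp[0]
    detected, category = False, None
    for r in res["regions"]:
        if (r.chrom == "1" and r.start_bp <= locus + 250_000
                and r.end_bp >= locus - 250_000):
            detected = True
            category = r.category
            break
    return {"detected": detected, "category": category, "locus": locus,
            "final_freqs": finals, "regions": res["regions"]}


# ---------------------------------------------------------------------------
# packaged reference table

def load_reference_regions() -> pd.DataFrame:
    """The 38 published candidate regions of the two-line Large White scan.

    Columns: id, chrom, start_mb, end_mb, length_kb, tests (canonical test
    names), category, n_genes, gene_names.
    """
    with resources.files("driftscan.data").joinpath(
            "reference_regions.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    required = {"id", "chrom", "start_mb", "end_mb", "length_kb", "tests",
                "category", "n_genes"}
    if not required <= set(df.columns):
        raise ValueError("malformed packaged region table")
    df["gene_names"] = df.get("gene_names", "").fillna("")
    df["tests"] = df["tests"].map(
        lambda t: ",".join(sorted(TEST_ALIASES[x] for x in t.split(","))))
    bad = set(df["category"]) - set(regions_mod.CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories in packaged table: {bad}")
    return df


def summarize_regions(df: pd.DataFrame) -> dict:
    """Aggregate a region table the way the published summary does."""
    top = df["category"].map(regions_mod.top_level_category)
    return {
        "n_regions": int(len(df)),
        "per_category": top.value_counts().to_dict(),
        "n_time_lws": int(df["tests"].str.contains("time-LWS").sum()),
        "n_time_lwd": int(df["tests"].str.contains("time-LWD").sum()),
        "n_hapflk": int(df["tests"].str.contains("hapFLK").sum()),
        "median_length_kb": float(df["length_kb"].median()),
        "total_genes": int(df["n_genes"].sum()),
        "max_genes": int(df["n_genes"].max()),
    }
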