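"""Characterise the candidate regions: genes, QTL enrichment, candidates.

Uses synthetic annotation resources generated alongside the simulation (a
gene map, a QTL table with trait categories, and a gene-to-function table;
all synthetic stand-ins for the Ensembl/QTLdb inputs a real analysis would
supply) to exercise the full downstream layer: gene assignment with the
flanking rule, trait x region-category contingency residuals, function
association, and statistical/functional candidate-variant prioritisation.

Writes results/posthoc/: region_genes.tsv, qtl_table.tsv, qtl_residuals.tsv,
function_residuals.tsv, candidates.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from driftscan import flk, genio, pipeline, posthoc
from driftscan.regions import regions_from_frame, rescan_region

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "sim"
OUT = BASE / "posthoc"
RNG = np.random.default_rng(77)

# dam-expected vs sire/both-expected chromosomes in the simulated design
TRAIT_OF_CHROM = {"1": "Both.Sire", "2": "Dam", "3": "Dam", "4": "Both.Sire"}


def synthetic_genes() -> pd.DataFrame:
    rows = []
    for chrom in "12345":
        for i in range(8):
            start = 150_000 + i * 240_000 + int(RNG.integers(0, 50_000))
            rows.append({"chrom": chrom, "start": start,
                         "end": start + int(RNG.integers(20_000, 60_000)),
                         "gene": f"G{chrom}_{i + 1}"})
    return pd.DataFrame(rows)


def synthetic_qtls(truth: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, sc in truth.iterrows():
        trait = TRAIT_OF_CHROM[str(sc["chrom"])]
        rows.append({"chrom": str(sc["chrom"]), "start": sc["pos"] - 50_000,
                     "end": sc["pos"] + 50_000, "trait_category": trait,
                     "weight": 5})
        rows.append({"chrom": str(sc["chrom"]),
                     "start": sc["pos"] + 800_000,
                     "end": sc["pos"] + 900_000, "trait_category": trait,
                     "weight": 1})
    # background QTL on the neutral chromosome
    rows.append({"chrom": "5", "start": 400_000, "end": 500_000,
                 "trait_category": "Both", "weight": 1})
    return pd.DataFrame(rows)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    g = genio.read_vcf(SIM / "genotypes.vcf", SIM / "samples.tsv")
    truth = pd.read_csv(SIM / "truth.tsv", sep="\t", dtype={"chrom": str})
    regions = regions_from_frame(
        pd.read_csv(BASE / "scan" / "regions.tsv", sep="\t",
                    dtype={"chrom": str}))
    genes = synthetic_genes()
    qtls = synthetic_qtls(truth)
    qtls.to_csv(OUT / "qtl_table.tsv", sep="\t", index=False)

    # gene content per region (flanking rule for gene-empty regions)
    gene_rows = []
    for r in regions:
        found, flanking = posthoc.assign_genes(r, genes)
        r.genes = found
        for gene in found:
            gene_rows.append({"region_id": r.id, "category": r.category,
                              "gene": gene, "flanking": flanking})
    region_genes = pd.DataFrame(gene_rows)
    region_genes.to_csv(OUT / "region_genes.tsv", sep="\t", index=False)
    print(f"{len(region_genes)} gene assignments over {len(regions)} regions")

    table, resid = posthoc.qtl_enrichment(regions, qtls)
    resid.to_csv(OUT / "qtl_residuals.tsv", sep="\t")
    print("QTL cumulated scores (trait x region category):")
    print(table.to_string(float_format="%.0f"))
    print("adjusted residuals:")
    print(resid.to_string(float_format="%+.2f"))

    # gene -> function table: growth everywhere, lactation on dam-expected
    # chromosomes, lipid metabolism on sire-expected ones
    fun_rows = []
    for _, row in region_genes.iterrows():
        chrom = row["region_id"].removeprefix("SSC").split(":")[0]
        fun_rows.append({"gene": row["gene"], "function": "growth"})
        if TRAIT_OF_CHROM.get(chrom) == "Dam":
            fun_rows.append({"gene": row["gene"], "function": "lactation"})
        elif TRAIT_OF_CHROM.get(chrom) == "Both.Sire":
            fun_rows.append({"gene": row["gene"],
                             "function": "lipid metabolism"})
    gene_functions = pd.DataFrame(fun_rows).drop_duplicates()
    try:
        _, fun_resid = posthoc.function_association(gene_functions,
                                                    region_genes)
        fun_resid.to_csv(OUT / "function_residuals.tsv", sep="\t")
        print("function x category residuals:")
        print(fun_resid.to_string(float_format="%+.2f"))
    except ValueError as exc:
        print(f"function association skipped: {exc}")

    # candidate variants per region, synthetic impact annotation: the
    # simulator has no functional classes, so impacts are MODIFIER except
    # for a MODERATE sprinkle
    freqs = genio.allele_freqs(g, ["ANC", "LWD", "LWS"])
    mask_all = genio.maf_filter(freqs, ["ANC"], 0.10)
    tree = flk.estimate_tree(freqs, ["LWD", "LWS"], "ANC", mask=mask_all)
    cfg = pipeline.PipelineConfig()
    cand_rows = []
    for r in regions:
        try:
            tracks, _, _ = rescan_region(r, g, tree, cfg.ne_d, cfg.ne_s,
                                         cfg.gens, K=cfg.K, nfit=2, seed=5)
        except ValueError:
            continue
        n = len(tracks)
        inside = ((g.variants["chrom"] == r.chrom)
                  & (g.variants["pos"] >= r.start_bp)
                  & (g.variants["pos"] <= r.end_bp)).to_numpy()
        call = (g.dosage[inside] != genio.MISSING).mean(axis=1)
        impacts = np.where(RNG.random(n) < 0.1, "MODERATE", "MODIFIER")
        cands = posthoc.prioritize_variants(
            r, tracks, call_rate=call,
            shift_d=tracks["f_lwd"].to_numpy() - tracks["f_anc"].to_numpy(),
            shift_s=tracks["f_lws"].to_numpy() - tracks["f_anc"].to_numpy(),
            impacts=list(impacts), call_rate_threshold=cfg.call_rate,
            stat_cut=cfg.stat_cut, func_cut=cfg.func_cut, cap=cfg.cap)
        for v in cands:
            if v.status == "candidate":
                cand_rows.append({"region_id": r.id, "chrom": v.chrom,
                                  "pos": v.pos, "strategy": v.strategy,
                                  "impact": v.impact,
                                  "statistic": v.statistic_value})
    cand = pd.DataFrame(cand_rows)
    cand.to_csv(OUT / "candidates.tsv", sep="\t", index=False)
    print(f"{len(cand)} candidate variants across "
          f"{cand['region_id'].nunique() if len(cand) else 0} regions; "
          f"tables under {OUT}")


if __name__ == "__main__":
    main()
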