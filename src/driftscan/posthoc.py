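"""Downstream characterisation of candidate regions.

Covers gene assignment (with a flanking-gene rule for gene-empty regions),
QTL-overlap scoring and trait-by-region-category contingency residuals, the
analogous function-by-category association on a user-supplied gene-to-function
table, and candidate-variant prioritisation by a statistical and a functional
strategy using SnpEff-style ANN impact classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import Region

TRAIT_CATEGORIES = ("Both", "Both.Sire", "Dam")
IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
FUNCTIONAL_IMPACTS = ("HIGH", "MODERATE", "LOW")
# region categories expected for trait groups (dam-expected vs sire/both)
DAM_GROUP = ("LWD", "conv(LWD)", "div")
SIRE_GROUP = ("LWS", "conv(LWS)", "conv")

QTL_MAX_DISTANCE_BP = 2_000_000
FLANK_MAX_DISTANCE_BP = 1_000_000
SECOND_FLANK_GAP_BP = 50_000


@dataclass
class VariantCandidate:
    chrom: str
    pos: int
    status: str                  # invalid | valid | candidate
    impact: str                  # HIGH/MODERATE/LOW/MODIFIER/none
    strategy: str | None         # statistical | functional | None
    statistic_value: float


# ---------------------------------------------------------------------------
# gene annotation

def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Extract gene features from a GFF3/GTF file.

    Only feature type 'gene' is used; the gene name falls back to the gene ID
    when no name attribute is present.  Malformed lines are skipped and
    counted in ``DataFrame.attrs['n_skipped']``.
    """
    rows, skipped = [], 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                skipped += 1
                continue
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                skipped += 1
                continue
            attrs = _parse_attributes(parts[8])
            name = attrs.get("gene_name") or attrs.get("Name") \
                or attrs.get("gene_id") or attrs.get("ID") or "?"
            rows.append({"chrom": parts[0], "start": start, "end": end,
                         "gene": name})
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    out.attrs["n_skipped"] = skipped
    return out


def _parse_attributes(field: str) -> dict[str, str]:
    attrs = {}
    if "=" in field.split(";")[0]:          # GFF3 dialect
        for item in field.split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                attrs[k.strip()] = v.strip()
    else:                                   # GTF dialect
        for item in field.split(";"):
            item = item.strip()
            if not item:
                continue
            k, _, v = item.partition(" ")
            attrs[k] = v.strip().strip('"')
    return attrs


def assign_genes(region: Region, annotation: pd.DataFrame
                 ) -> tuple[list[str], bool]:
    """Genes overlapping the region; flanking genes when it is gene-empty.

    Overlap means any bp intersection (1-based inclusive).  For an empty
    region, on each side the closest gene is included if it lies within 1 Mb
    of the region, and the second closest if its gap to the first is below
    50 kb (at most four flanking genes in total).  Returns ``(genes,
    flanking_flag)``.
    """
    genes = annotation[annotation["chrom"].astype(str) == str(region.chrom)]
    overlap = genes[(genes["start"] <= region.end_bp)
                    & (genes["end"] >= region.start_bp)]
    if len(overlap):
        return list(overlap["gene"]), False

    picked: list[str] = []
    left = genes[genes["end"] < region.start_bp].sort_values(
        "end", ascending=False)
    right = genes[genes["start"] > region.end_bp].sort_values("start")
    for side, edge in ((left, "end"), (right, "start")):
        if not len(side):
            continue
        first = side.iloc[0]
        gap = (region.start_bp - first["end"] if edge == "end"
               else first["start"] - region.end_bp)
        if gap >= FLANK_MAX_DISTANCE_BP:
            continue
        picked.append(first["gene"])
        if len(side) > 1:
            second = side.iloc[1]
            gap2 = (first["start"] - second["end"] if edge == "end"
                    else second["start"] - first["end"])
            if gap2 < SECOND_FLANK_GAP_BP:
                picked.append(second["gene"])
    return picked, bool(picked)


# ---------------------------------------------------------------------------
# contingency residuals

def adjusted_residuals(table: pd.DataFrame) -> pd.DataFrame:
    """Adjusted standardised residuals of a contingency table.

    r_ij = (O_ij - E_ij) / sqrt(E_ij (1 - rowsum_i/N) (1 - colsum_j/N)) with
    E from row/column independence; the sign of r matches O - E.
    """
    O = table.to_numpy(dtype=float)
    N = O.sum()
    if N <= 0:
        raise ValueError("contingency table sums to zero")
    row = O.sum(axis=1, keepdims=True)
    col = O.sum(axis=0, keepdims=True)
    E = row @ col / N
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(E * (1 - row / N) * (1 - col / N))
        r = np.where(denom > 0, (O - E) / denom, 0.0)
    return pd.DataFrame(r, index=table.index, columns=table.columns)


def qtl_enrichment(regions: Sequence[Region], qtls: pd.DataFrame
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trait-category x region-category cumulated QTL scores and residuals.

    ``qtls`` needs columns chrom, start, end, trait_category (Both /
    Both.Sire / Dam) and weight (5 = trait directly in a selection index,
    1 = indirectly affected).  A QTL counts toward a region when the
    interval-to-interval gap is strictly below 2 Mb.  Returns
    ``(table, residuals)``.
    """
    if not len(regions) or not len(qtls):
        raise ValueError("need at least one region and one QTL")
    bad_w = set(qtls["weight"]) - {1, 5}
    if bad_w:
        raise ValueError(f"QTL weights must be 1 or 5, got {sorted(bad_w)}")
    cats = sorted({r.category or "unresolved" for r in regions})
    table = pd.DataFrame(0.0, index=list(TRAIT_CATEGORIES), columns=cats)
    for region in regions:
        sub = qtls[qtls["chrom"].astype(str) == str(region.chrom)]
        gap = np.maximum(sub["start"] - region.end_bp,
                         region.start_bp - sub["end"])
        near = sub[np.maximum(gap, 0) < QTL_MAX_DISTANCE_BP]
        for trait, grp in near.groupby("trait_category"):
            if trait not in TRAIT_CATEGORIES:
                raise ValueError(f"unknown trait category {trait!r}")
            table.loc[trait, region.category or "unresolved"] += \
                grp["weight"].sum()
    if table.to_numpy().sum() == 0:
        raise ValueError("no QTL within range of any region")
    return table, adjusted_residuals(table)


def function_association(gene_functions: pd.DataFrame,
                         region_genes: pd.DataFrame,
                         by: str = "genes") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Function x region-category association from a gene-to-function table.

    ``gene_functions`` has columns gene, function; ``region_genes`` has
    columns gene, region_id, category.  ``by='genes'`` counts genes per cell,
    ``by='regions'`` counts distinct regions.  Functions annotating no gene in
    any region are dropped.  Returns ``(table, residuals)``.
    """
    if by not in {"genes", "regions"}:
        raise ValueError("by must be 'genes' or 'regions'")
    merged = gene_functions.merge(region_genes, on="gene", how="inner")
    if merged.empty:
        raise ValueError("no annotated gene occurs in any region")
    if by == "genes":
        counts = (merged.groupby(["function", "category"])["gene"]
                  .nunique().unstack(fill_value=0))
    else:
        counts = (merged.groupby(["function", "category"])["region_id"]
                  .nunique().unstack(fill_value=0))
    counts = counts.loc[counts.sum(axis=1) > 0]
    return counts.astype(float), adjusted_residuals(counts.astype(float))


def trait_group_map() -> dict[str, str]:
    """Region-category grouping by the trait class expected to drive it."""
    mapping = {c: "Dam" for c in DAM_GROUP}
    mapping.update({c: "Both.Sire" for c in SIRE_GROUP})
    return mapping


# ---------------------------------------------------------------------------
# SnpEff ANN parsing and candidate prioritisation

_IMPACT_RANK = {imp: i for i, imp in enumerate(IMPACTS)}


def worst_impact(ann: str | None) -> str:
    """Worst SnpEff impact across the transcripts of an ANN field."""
    if not ann:
        return "none"
    impacts = []
    for entry in ann.split(","):
        fields = entry.split("|")
        if len(fields) > 2 and fields[2] in _IMPACT_RANK:
            impacts.append(fields[2])
    if not impacts:
        return "none"
    return min(impacts, key=_IMPACT_RANK.get)


def read_variant_impacts(path: str | Path) -> pd.DataFrame:
    """chrom/pos/impact table from a SnpEff-annotated VCF (ANN INFO field)."""
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(path))
    for var in vcf:
        rows.append({"chrom": var.CHROM, "pos": var.POS,
                     "impact": worst_impact(var.INFO.get("ANN"))})
    vcf.close()
    return pd.DataFrame(rows, columns=["chrom", "pos", "impact"])


RELEVANT_STAT = {"div": "flk", "LWD": "tlwd", "conv(LWD)": "tlwd",
                 "LWS": "tlws", "conv(LWS)": "tlws"}


def prioritize_variants(region: Region, tracks: pd.DataFrame,
                        call_rate: np.ndarray,
                        shift_d: np.ndarray, shift_s: np.ndarray,
                        impacts: Sequence[str] | None = None,
                        call_rate_threshold: float = 0.8,
                        stat_cut: float = 0.95, func_cut: float = 0.80,
                        cap: int = 3) -> list[VariantCandidate]:
    """Rank region variants into invalid / valid / candidate.

    ``tracks`` holds the region-restricted statistics (columns flk, tlwd_p,
    tlws_p, plus chrom/pos); the reference statistic follows the region
    category (FLK for div, the relevant temporal test otherwise; for plain
    conv the temporal test with the larger regional peak).  A variant is
    invalid when its call rate is below the threshold or its allele-frequency
    shift is inconsistent with the region's selection pattern (different sign
    or less than half the magnitude of the region's peak shift).  Statistical
    candidates are the valid variants at >= ``stat_cut`` of the regional
    maximum (at most ``cap``); functional candidates need >= ``func_cut`` of
    the maximum and a HIGH/MODERATE/LOW impact.
    """
    n = len(tracks)
    cat = region.category or "unresolved"

    def stat_column(name: str) -> np.ndarray:
        if name == "flk":
            return tracks["flk"].to_numpy(dtype=float)
        # temporal evidence enters through the p-value
        return -np.log10(np.maximum(tracks[f"{name}_p"].to_numpy(dtype=float),
                                    1e-300))

    if cat in RELEVANT_STAT:
        stat = stat_column(RELEVANT_STAT[cat])
        lines = ("LWD",) if "LWD" in cat else (
            ("LWS",) if "LWS" in cat else ("LWD", "LWS"))
        if cat == "div":
            lines = ("LWD", "LWS")
    else:  # conv and unresolved: temporal test with the larger peak
        tlwd, tlws = stat_column("tlwd"), stat_column("tlws")
        stat = tlwd if np.nanmax(tlwd, initial=0) >= np.nanmax(
            tlws, initial=0) else tlws
        lines = ("LWD", "LWS")

    shifts = {"LWD": np.asarray(shift_d, float),
              "LWS": np.asarray(shift_s, float)}
    consistent = np.ones(n, dtype=bool)
    for line in lines:
        sh = shifts[line]
        finite = np.isfinite(sh)
        peak = np.nanmax(np.abs(sh)) if finite.any() else 0.0
        if peak <= 0:
            continue
        peak_sign = np.sign(sh[np.nanargmax(np.abs(sh))])
        ok = finite & (np.sign(sh) == peak_sign) & (np.abs(sh) >= 0.5 * peak)
        consistent &= ok

    valid = (np.asarray(call_rate, float) >= call_rate_threshold) & consistent
    impacts = list(impacts) if impacts is not None else ["none"] * n

    out: list[VariantCandidate] = []
    stat_f = np.where(np.isfinite(stat), stat, -np.inf)
    vmax = stat_f[valid].max() if valid.any() else np.nan
    stat_idx = []
    if valid.any() and np.isfinite(vmax):
        cand = np.flatnonzero(valid & (stat_f >= stat_cut * vmax))
        stat_idx = list(cand[np.argsort(stat_f[cand])[::-1]][:cap])
    for i in range(n):
        status = "valid" if valid[i] else "invalid"
        strategy = None
        if i in stat_idx:
            status, strategy = "candidate", "statistical"
        elif (valid[i] and np.isfinite(vmax) and stat_f[i] >= func_cut * vmax
              and impacts[i] in FUNCTIONAL_IMPACTS):
            status, strategy = "candidate", "functional"
        out.append(VariantCandidate(
            chrom=str(tracks["chrom"].iat[i]), pos=int(tracks["pos"].iat[i]),
            status=status, impact=impacts[i], strategy=strategy,
            statistic_value=float(stat[i]) if np.isfinite(stat[i]) else np.nan))
    return out
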