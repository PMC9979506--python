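"""Candidate-region assembly and selection-scenario classification.

Segments produced by the three genome scans (hapFLK, time-LWD + local score,
time-LWS + local score) are merged into named candidate regions: segments of
the same test closer than 1 Mb are joined, then overlapping segments from
different tests are unioned.  Each region is then classified into one of six
selection scenarios (conv, conv(LWD), conv(LWS), div, LWD, LWS) from
region-restricted evidence: haplotype-cluster (or allele) frequency shifts of
each line away from the ancestral sample, whether both lines favour the same
target, and the peaks of the four test statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TEST_NAMES = ("hapFLK", "time-LWD+LS", "time-LWS+LS")
CATEGORIES = ("conv", "conv(LWD)", "conv(LWS)", "div", "LWD", "LWS")
WITHIN_TEST_GAP_BP = 1_000_000

# tau_shift separates a selected line's focal-SNP frequency shift from
# drift + sampling noise (~1.5 x the null standard deviation at Ne ~ 80,
# 25 generations, 13 sampled diploids); tau_hi quantifies "clearly more
# marked in one line" for the conv sub-categories and tau_lo "little"
# differentiation in hand-built evidence
DEFAULT_THRESHOLDS = {"tau_hi": 0.2, "tau_lo": 0.1, "tau_shift": 0.35}


@dataclass
class Region:
    chrom: str
    start_bp: int
    end_bp: int
    tests: set[str] = field(default_factory=set)
    category: str | None = None
    genes: list[str] = field(default_factory=list)

    @property
    def id(self) -> str:
        return name_region(self.chrom, self.start_bp)

    @property
    def length_kb(self) -> int:
        return round((self.end_bp - self.start_bp) / 1000)


@dataclass
class CategoryEvidence:
    """Region-restricted evidence feeding the scenario classifier.

    ``shift_d``/``shift_s`` are cluster (or allele) frequency changes from
    the ancestral sample to each line, in [0, 1]; ``same_target`` records
    whether the largest-gain cluster (or favoured allele) is identical in
    the two lines.  ``sig_d``/``sig_s`` flag a significant temporal signal
    (the region was called by that line's genome scan) and ``sug_d``/
    ``sug_s`` a suggestive one (an elevated local-score excursion inside the
    region); when left as None they are derived from the shifts, which makes
    hand-built evidence behave like the published qualitative typology.
    """

    shift_d: float
    shift_s: float
    same_target: bool
    hapflk_significant: bool
    sig_d: bool | None = None
    sig_s: bool | None = None
    sug_d: bool | None = None
    sug_s: bool | None = None
    flk_peak: float = np.nan
    hapflk_peak: float = np.nan
    tlwd_peak: float = np.nan
    tlws_peak: float = np.nan

    def __post_init__(self) -> None:
        if not (0 <= self.shift_d <= 1 and 0 <= self.shift_s <= 1):
            raise ValueError("shifts must lie in [0, 1]")


def name_region(chrom: str | int, start_bp: int) -> str:
    """Region ID 'SSC<chrom>:<Mb>' with Mb the integer part of the start."""
    if start_bp < 0:
        raise ValueError("start must be >= 0")
    return f"SSC{chrom}:{int(start_bp) // 1_000_000}"


def _merge_within_test(segments: Sequence[tuple[str, int, int]]
                       ) -> list[tuple[str, int, int]]:
    """Join same-test segments separated by strictly less than 1 Mb."""
    out: list[list] = []
    for chrom, start, end in sorted(segments):
        if out and out[-1][0] == chrom and start - out[-1][2] < WITHIN_TEST_GAP_BP:
            out[-1][2] = max(out[-1][2], end)
        else:
            out.append([chrom, start, end])
    return [tuple(seg) for seg in out]


def merge_regions(per_test: Mapping[str, Iterable[tuple[str, int, int]]]
                  ) -> list[Region]:
    """Combine per-test segment lists into uncategorised candidate regions.

    ``per_test`` maps a test name to (chrom, start_bp, end_bp) segments.
    Within a test, segments with a gap < 1 Mb are merged; across tests,
    merging requires >= 1 bp overlap.
    """
    pieces: list[tuple[str, int, int, str]] = []
    for test, segs in per_test.items():
        if test not in TEST_NAMES:
            raise ValueError(f"unknown test {test!r}; expected {TEST_NAMES}")
        for chrom, start, end in _merge_within_test(list(segs)):
            pieces.append((chrom, start, end, test))

    regions: list[Region] = []
    for chrom in sorted({p[0] for p in pieces}):
        chunk = sorted(p for p in pieces if p[0] == chrom)
        current: Region | None = None
        for _, start, end, test in chunk:
            if current is not None and start <= current.end_bp:
                current.end_bp = max(current.end_bp, end)
                current.tests.add(test)
            else:
                current = Region(chrom, start, end, {test})
                regions.append(current)
    return regions


def classify_region(evidence: CategoryEvidence,
                    thresholds: Mapping[str, float] | None = None) -> str:
    """Assign one of the six scenario categories (or 'unresolved').

    The rules operationalise the published test-pattern typology:
    line-specific selection shows a significant temporal signal in one line
    with not even a suggestive one in the other; divergent selection shows
    different targets in the two lines together with between-line
    differentiation (significant hapFLK, or suggestive temporal signals in
    both lines); convergent selection shows the same target with at least
    suggestive signals in both lines, refined to conv(LWD)/conv(LWS) when
    one line's frequency shift clearly dominates.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    tau_hi, tau_lo = thr["tau_hi"], thr["tau_lo"]
    tau_shift = thr["tau_shift"]
    ev = evidence

    hi_d, hi_s = ev.shift_d >= tau_shift, ev.shift_s >= tau_shift
    if hi_d and hi_s:
        if not ev.same_target:
            return "div"
        if ev.shift_d - ev.shift_s >= tau_hi:
            return "conv(LWD)"
        if ev.shift_s - ev.shift_d >= tau_hi:
            return "conv(LWS)"
        return "conv"
    if hi_d and ev.shift_s < tau_shift:
        return "LWD"
    if hi_s and ev.shift_d < tau_shift:
        return "LWS"

    # weak-shift fallback: lean on the test pattern
    sig_d = ev.sig_d if ev.sig_d is not None else ev.shift_d >= tau_hi
    sig_s = ev.sig_s if ev.sig_s is not None else ev.shift_s >= tau_hi
    sug_d = ev.sug_d if ev.sug_d is not None else ev.shift_d >= tau_lo
    sug_s = ev.sug_s if ev.sug_s is not None else ev.shift_s >= tau_lo
    sug_d, sug_s = sug_d or sig_d, sug_s or sig_s
    if ev.hapflk_significant and not ev.same_target:
        return "div"
    if sig_d and not sug_s:
        return "LWD"
    if sig_s and not sug_d:
        return "LWS"
    if ev.same_target and sug_d and sug_s:
        return "conv"
    return "unresolved"


def top_level_category(category: str) -> str:
    """Collapse conv(LWD)/conv(LWS) onto conv."""
    return "conv" if category.startswith("conv") else category


# ---------------------------------------------------------------------------
# region-restricted evidence

def _regional_lindley_max(p: np.ndarray, xi: float) -> float:
    from .localscore import lindley

    p = p[~np.isnan(p)]
    if p.size == 0:
        return 0.0
    return float(lindley(np.clip(p, 1e-300, 1.0), xi).max())


def build_evidence(region: Region, tracks, cluster_freqs=None,
                   pops: Sequence[str] | None = None,
                   xi: float = 2.0, h_suggestive: float = 1.0
                   ) -> CategoryEvidence:
    """Assemble CategoryEvidence from a region re-scan.

    ``tracks`` is the per-variant DataFrame of rescan_region (columns
    chrom, pos, flk, hapflk, tlwd_p, tlws_p, f_anc, f_lwd, f_lws).

    Shifts are the absolute allele-frequency changes of each line from the
    ancestral sample at the focal SNP — the variant with the largest
    combined change, i.e. the best proxy for the selected site;
    ``same_target`` holds when both lines moved that SNP in the same
    direction.  Suggestive temporal evidence is an elevated local-score
    excursion (max Lindley value >= ``h_suggestive``) of the line's
    p-values inside the region; significant means the region was called by
    that test in the genome scan.  When a cluster model is supplied its
    per-site top-gaining clusters at the focal SNP refine ``same_target``.
    """
    h_d = _regional_lindley_max(tracks["tlwd_p"].to_numpy(float), xi)
    h_s = _regional_lindley_max(tracks["tlws_p"].to_numpy(float), xi)

    dd = tracks["f_lwd"].to_numpy(float) - tracks["f_anc"].to_numpy(float)
    ds = tracks["f_lws"].to_numpy(float) - tracks["f_anc"].to_numpy(float)
    lp = (np.log10(np.maximum(tracks["tlwd_p"].to_numpy(float), 1e-300))
          + np.log10(np.maximum(tracks["tlws_p"].to_numpy(float), 1e-300)))
    ok = ~np.isnan(dd) & ~np.isnan(ds) & np.isfinite(lp)
    if not ok.any():
        raise ValueError(f"no co-called variants in region {region.id}")
    idx_ok = np.flatnonzero(ok)
    # focal SNP = strongest combined temporal evidence: picking it by raw
    # frequency shifts would bias toward sites where the unselected line
    # happened to drift far as well
    focal = idx_ok[np.argmin(lp[ok])]
    shift_d = float(min(abs(dd[focal]), 1.0))
    shift_s = float(min(abs(ds[focal]), 1.0))
    noise = 0.02
    same = (abs(dd[focal]) >= noise and abs(ds[focal]) >= noise
            and np.sign(dd[focal]) == np.sign(ds[focal]))

    def peak(col):
        v = tracks[col].to_numpy(float)
        v = v[np.isfinite(v)]
        return float(v.max()) if v.size else np.nan

    return CategoryEvidence(
        shift_d=shift_d, shift_s=shift_s, same_target=bool(same),
        hapflk_significant="hapFLK" in region.tests,
        sig_d="time-LWD+LS" in region.tests,
        sig_s="time-LWS+LS" in region.tests,
        sug_d=h_d >= h_suggestive, sug_s=h_s >= h_suggestive,
        flk_peak=peak("flk"), hapflk_peak=peak("hapflk"),
        tlwd_peak=-np.log10(max(np.nanmin(
            tracks["tlwd_p"].to_numpy(float)), 1e-300)),
        tlws_peak=-np.log10(max(np.nanmin(
            tracks["tlws_p"].to_numpy(float)), 1e-300)))


def rescan_region(region: Region, g_av, tree, ne_d: int, ne_s: int,
                  gens: int, K: int = 10, nfit: int = 2, seed: int = 0,
                  max_iter: int = 60):
    """Re-run the four tests on all available variants within a region.

    No MAF filter is applied; the cluster model is re-fitted on the region's
    variants including the ancestral population so that cluster-frequency
    shifts against it can be read off.  Returns ``(tracks, cluster_freqs,
    pops)`` where ``tracks`` is a per-variant DataFrame with columns flk,
    hapflk, tlwd_p/tlwd_s_hat, tlws_p/tlws_s_hat, and ``cluster_freqs`` is
    the (n_pop, L, K) array over ``pops`` = [ANC, LWD, LWS].
    """
    from . import flk as flk_mod
    from . import hapclust, wfhmm
    from .genio import allele_freqs

    inside = ((g_av.variants["chrom"] == region.chrom)
              & (g_av.variants["pos"] >= region.start_bp)
              & (g_av.variants["pos"] <= region.end_bp)).to_numpy()
    if not inside.any():
        raise ValueError(f"no variants in region {region.id}")
    sub = g_av.subset_variants(inside)
    freqs = allele_freqs(sub, ["ANC", "LWD", "LWS"])

    tracks = flk_mod.flk_test(freqs, tree)
    tracks.rename(columns={"p": "flk_p"}, inplace=True)
    fmat = freqs.freq
    for pop, col in (("ANC", "f_anc"), ("LWD", "f_lwd"), ("LWS", "f_lws")):
        tracks[col] = fmat[:, freqs.pop_index(pop)]
    tracks["hapflk"] = hapclust.hapflk_statistic(
        sub, tree, K=K, nfit=nfit, seed=seed, max_iter=max_iter,
        include=["ANC"])

    ia = freqs.pop_index("ANC")
    c_anc = freqs.alt_count[:, ia]
    n_anc = freqs.n_samples["ANC"]
    for line, ne, col in (("LWD", ne_d, "tlwd"), ("LWS", ne_s, "tlws")):
        il = freqs.pop_index(line)
        res = wfhmm.temporal_test(c_anc, n_anc, freqs.alt_count[:, il],
                                  freqs.n_samples[line], ne=ne, gens=gens,
                                  called1=freqs.called[:, ia],
                                  called2=freqs.called[:, il])
        tracks[f"{col}_p"] = res["p"].to_numpy()
        tracks[f"{col}_s_hat"] = res["s_hat"].to_numpy()

    pops = ["ANC", "LWD", "LWS"]
    model = hapclust.fit_cluster_model(sub.dosage, K, seed=seed,
                                       max_iter=max_iter)
    cluster_freqs = hapclust.cluster_frequencies(model, sub, pops)
    return tracks, cluster_freqs, pops


def regions_from_frame(df: pd.DataFrame) -> list[Region]:
    """Inverse of regions_to_frame (coordinates restored from Mb columns)."""
    out = []
    for _, row in df.iterrows():
        tests = set(str(row["tests"]).split(",")) if row.get("tests") else set()
        genes = ([g for g in str(row["genes"]).split(",") if g]
                 if "genes" in row and pd.notna(row["genes"]) else [])
        out.append(Region(str(row["chrom"]),
                          int(round(row["start_mb"] * 1e6)),
                          int(round(row["end_mb"] * 1e6)),
                          tests={t for t in tests if t},
                          category=row.get("category"), genes=genes))
    return out


def regions_to_frame(regions: Sequence[Region]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append({"id": r.id, "chrom": r.chrom,
                     "start_mb": r.start_bp / 1e6, "end_mb": r.end_bp / 1e6,
                     "length_kb": r.length_kb,
                     "tests": ",".join(sorted(r.tests)),
                     "category": r.category or "unresolved",
                     "n_genes": len(r.genes),
                     "genes": ",".join(r.genes)})
    return pd.DataFrame(rows)
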