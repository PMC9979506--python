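"""Forward Wright-Fisher simulator of a two-line breeding design.

The simulated world mirrors a livestock selection experiment: an ancestral
population is sampled once, evolves for a few generations, splits into a dam
(D) and a sire (S) line of different effective sizes, and each line is sampled
again after further generations of drift, recombination and (optionally)
genic selection at chosen loci.

Haplotypes are tracked explicitly so that downstream haplotype-cluster
statistics see realistic mosaic structure; no new mutations arise during the
simulated decades (negligible over ~25 generations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "SelectionScenario",
    "TruthTable",
    "HaplotypeSet",
    "simulate_design",
    "simulate_temporal_counts",
    "write_vcf",
    "write_sample_map",
    "write_truth",
]

POPULATIONS = ("ANC", "LWD", "LWS")


@dataclass
class SimConfig:
    """Parameters of the two-line design.

    Defaults follow the estimated effective sizes of the French Large White
    dam (80) and sire (74) lines, with ~25 generations between the 1977
    sample and the modern ones (10 pre-split + 15 post-split; the split is
    dated to about 20 generations before the modern samples, but the
    generation interval is not fixed, so both phases are configurable).
    """

    ne_anc: int = 100
    ne_d: int = 80
    ne_s: int = 74
    gens_pre_split: int = 10
    gens_post_split: int = 15
    n_chrom: int = 1
    chrom_length_bp: int = 2_000_000
    n_snps_per_chrom: int = 400
    recomb_rate: float = 1e-8
    sample_sizes: tuple[int, int, int] = (10, 13, 13)
    missing_rate: float = 0.0
    seed: int = 0
    # neutral generations before the first sample: the pool starts in
    # linkage equilibrium with exact per-site allele counts, and burn-in
    # drift/recombination builds realistic haplotype structure
    burnin_gens: int = 10
    # drop sites monomorphic across the union of the three samples,
    # emulating a called SNP panel
    ascertain: bool = True

    def __post_init__(self) -> None:
        for name in ("ne_anc", "ne_d", "ne_s", "n_chrom", "chrom_length_bp",
                     "n_snps_per_chrom"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        if self.gens_pre_split < 0 or self.gens_post_split < 0:
            raise ValueError("generation counts must be >= 0")
        if any(n <= 0 for n in self.sample_sizes):
            raise ValueError("sample sizes must be > 0")

    @property
    def total_gens(self) -> int:
        return self.gens_pre_split + self.gens_post_split


@dataclass
class SelectionScenario:
    """Per-locus selection regime.

    ``s_d``/``s_s`` act after the split in lines D and S, ``s_pre`` acts in
    the common population between the first sample and the split.  All are
    genic selective advantages of the alternate allele; negative values
    favour the reference allele.  ``label`` names the truth category:
    conv (same allele favoured in both lines), div (opposite alleles),
    line_d / line_s (one line only) or neutral.
    """

    chrom: str
    position_bp: int
    s_d: float = 0.0
    s_s: float = 0.0
    s_pre: float = 0.0
    label: str = "neutral"
    # starting frequency of the favoured allele; None draws from the neutral
    # SFS (sweeps from very rare standing variants are usually lost, so
    # detection experiments set a segregating start, default 0.2)
    f0: float | None = 0.2

    def __post_init__(self) -> None:
        for s in (self.s_d, self.s_s, self.s_pre):
            if s <= -1:
                raise ValueError("selective advantage must be > -1")
        if self.label not in {"conv", "div", "line_d", "line_s", "neutral"}:
            raise ValueError(f"unknown scenario label {self.label!r}")
        expected = infer_label(self.s_d, self.s_s)
        if self.label != "neutral" and expected != self.label:
            raise ValueError(
                f"label {self.label!r} inconsistent with (s_d={self.s_d}, "
                f"s_s={self.s_s}); expected {expected!r}")


def infer_label(s_d: float, s_s: float) -> str:
    """Map post-split selection coefficients to a scenario label."""
    if s_d == 0 and s_s == 0:
        return "neutral"
    if s_d != 0 and s_s == 0:
        return "line_d"
    if s_s != 0 and s_d == 0:
        return "line_s"
    return "conv" if s_d * s_s > 0 else "div"


@dataclass
class TruthTable:
    scenarios: list[SelectionScenario]
    # per selected locus: population -> frequency path, one value per
    # generation from the first sampling time (index 0) to the last
    trajectories: list[dict[str, np.ndarray]] = field(default_factory=list)
    # bp position of the SNP actually placed under selection (the requested
    # position snaps to a nearby segregating site)
    realized_bp: list[int] = field(default_factory=list)


@dataclass
class HaplotypeSet:
    """Phased haplotypes for the three samples over a shared variant map."""

    chrom: np.ndarray          # (n_var,) str
    pos: np.ndarray            # (n_var,) int, 1-based
    haplotypes: dict[str, np.ndarray]  # pop -> (2*n_diploid, n_var) uint8

    @property
    def n_variants(self) -> int:
        return self.pos.size

    def sample_names(self) -> list[str]:
        names = []
        for pop in POPULATIONS:
            n = self.haplotypes[pop].shape[0] // 2
            names += [f"{pop}_{i + 1:02d}" for i in range(n)]
        return names


def _draw_sfs_freqs(n: int, ne: int, rng: np.random.Generator,
                    fmin: float | None = None) -> np.ndarray:
    """Initial frequencies ~ 1/x truncated to [1/(2ne), 1 - 1/(2ne)].

    Inverse-CDF sampling: F(x) proportional to log(x/a) on [a, b].
    ``fmin`` optionally raises the lower truncation point (e.g. to emulate a
    MAF-filtered SNP panel).
    """
    a = max(1.0 / (2 * ne), fmin or 0.0)
    b = 1.0 - 1.0 / (2 * ne)
    u = rng.random(n)
    return a * (b / a) ** u


def _recombine(pair: np.ndarray, pos: np.ndarray, length_bp: int,
               recomb_rate: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a diploid parent (2, n_var) by crossover."""
    ncross = rng.poisson(recomb_rate * length_bp)
    start = rng.integers(2)
    if ncross == 0:
        return pair[start].copy()
    breaks = np.sort(rng.integers(1, length_bp + 1, size=ncross))
    cuts = np.searchsorted(pos, breaks, side="right")
    gamete = np.empty(pos.size, dtype=np.uint8)
    bounds = np.concatenate(([0], cuts, [pos.size]))
    which = start
    for k in range(len(bounds) - 1):
        gamete[bounds[k]:bounds[k + 1]] = pair[which, bounds[k]:bounds[k + 1]]
        which ^= 1
    return gamete


def _next_generation(pool: np.ndarray, ne_next: int, sel_idx: np.ndarray,
                     sel_s: np.ndarray, pos: np.ndarray, length_bp: int,
                     recomb_rate: float, rng: np.random.Generator) -> np.ndarray:
    """One Wright-Fisher generation with multiplicative genic selection.

    Parents are drawn proportional to (1+s)^dosage at each selected locus;
    under random union of gametes this reproduces the deterministic genic
    update f(1+s)/(1+fs) in expectation.
    """
    n_par = pool.shape[0] // 2
    if sel_idx.size:
        dosage = pool[0::2, sel_idx].astype(float) + pool[1::2, sel_idx]
        w = np.prod((1.0 + sel_s) ** dosage, axis=1)
        probs = w / w.sum()
    else:
        probs = np.full(n_par, 1.0 / n_par)
    parents = rng.choice(n_par, size=2 * ne_next, p=probs)
    out = np.empty((2 * ne_next, pool.shape[1]), dtype=np.uint8)
    for g, par in enumerate(parents):
        out[g] = _recombine(pool[2 * par:2 * par + 2], pos, length_bp,
                            recomb_rate, rng)
    return out


def simulate_design(config: SimConfig,
                    scenarios: Sequence[SelectionScenario] = (),
                    ) -> tuple[HaplotypeSet, TruthTable]:
    """Run the full two-line design and return haplotypes plus ground truth."""
    rng = np.random.default_rng(config.seed)
    chrom_names = [str(c + 1) for c in range(config.n_chrom)]
    for sc in scenarios:
        if sc.chrom not in chrom_names:
            raise ValueError(f"scenario chromosome {sc.chrom!r} is not on the "
                             f"simulated map (chromosomes {chrom_names})")
        if not 1 <= sc.position_bp <= config.chrom_length_bp:
            raise ValueError(f"scenario position {sc.position_bp} outside "
                             f"chromosome of length {config.chrom_length_bp}")

    all_chrom, all_pos = [], []
    haps = {pop: [] for pop in POPULATIONS}
    truth = TruthTable(scenarios=list(scenarios))

    n_anc, n_d, n_s = config.sample_sizes
    for chrom in chrom_names:
        pos = np.sort(rng.choice(
            np.arange(1, config.chrom_length_bp + 1),
            size=config.n_snps_per_chrom, replace=False))
        chrom_scen = [sc for sc in scenarios if sc.chrom == chrom]

        # linkage-equilibrium pool with exact per-site counts, then neutral
        # burn-in to build haplotype structure
        f0 = _draw_sfs_freqs(pos.size, config.ne_anc, rng)
        two_ne = 2 * config.ne_anc
        counts = np.clip(np.round(two_ne * f0).astype(int), 1, two_ne - 1)
        pool = np.zeros((two_ne, pos.size), dtype=np.uint8)
        for v in range(pos.size):
            pool[rng.permutation(two_ne)[:counts[v]], v] = 1
        for _ in range(config.burnin_gens):
            pool = _next_generation(pool, config.ne_anc, np.empty(0, int),
                                    np.empty(0), pos, config.chrom_length_bp,
                                    config.recomb_rate, rng)

        # the selected locus is an existing segregating site near the
        # requested position whose post-burn-in frequency is closest to the
        # scenario's f0 (keeps the linkage structure intact)
        cur_freq = pool.mean(axis=0)
        sel_sites = np.empty(len(chrom_scen), dtype=int)
        for j, sc in enumerate(chrom_scen):
            near = np.flatnonzero(np.abs(pos - sc.position_bp) <= 100_000)
            if near.size == 0 or sc.f0 is None:
                sel_sites[j] = int(np.argmin(np.abs(pos - sc.position_bp)))
            else:
                sel_sites[j] = int(near[np.argmin(
                    np.abs(cur_freq[near] - sc.f0))])
            truth.realized_bp.append(int(pos[sel_sites[j]]))

        traj = {pop: [] for pop in ("ANC", "LWD", "LWS")}

        def freqs_at(pool_):
            return pool_[:, sel_sites].mean(axis=0) if sel_sites.size else np.empty(0)

        # first sampling time: draw the ancestral sample, then evolve
        perm = rng.permutation(pool.shape[0])
        haps["ANC"].append(pool[perm[:2 * n_anc]].copy())

        s_pre = np.array([sc.s_pre for sc in chrom_scen])
        s_d = np.array([sc.s_d for sc in chrom_scen])
        s_s = np.array([sc.s_s for sc in chrom_scen])

        anc_path = [freqs_at(pool)]
        for _ in range(config.gens_pre_split):
            pool = _next_generation(pool, config.ne_anc, sel_sites, s_pre,
                                    pos, config.chrom_length_bp,
                                    config.recomb_rate, rng)
            anc_path.append(freqs_at(pool))

        if config.gens_post_split == 0:
            pool_d, pool_s = pool, pool
            d_path, s_path = [], []
        else:
            pool_d = _next_generation(pool, config.ne_d, sel_sites, s_d, pos,
                                      config.chrom_length_bp,
                                      config.recomb_rate, rng)
            pool_s = _next_generation(pool, config.ne_s, sel_sites, s_s, pos,
                                      config.chrom_length_bp,
                                      config.recomb_rate, rng)
            d_path, s_path = [freqs_at(pool_d)], [freqs_at(pool_s)]
            for _ in range(config.gens_post_split - 1):
                pool_d = _next_generation(pool_d, config.ne_d, sel_sites, s_d,
                                          pos, config.chrom_length_bp,
                                          config.recomb_rate, rng)
                pool_s = _next_generation(pool_s, config.ne_s, sel_sites, s_s,
                                          pos, config.chrom_length_bp,
                                          config.recomb_rate, rng)
                d_path.append(freqs_at(pool_d))
                s_path.append(freqs_at(pool_s))

        perm = rng.permutation(pool_d.shape[0])
        haps["LWD"].append(pool_d[perm[:2 * n_d]].copy())
        perm = rng.permutation(pool_s.shape[0])
        haps["LWS"].append(pool_s[perm[:2 * n_s]].copy())

        anc_arr = np.array(anc_path)  # (gens_pre+1, n_sel)
        d_arr = np.array(d_path).reshape(len(d_path), sel_sites.size)
        s_arr = np.array(s_path).reshape(len(s_path), sel_sites.size)
        for j, sc in enumerate(chrom_scen):
            truth.trajectories.append({
                "ANC": anc_arr[:, j].copy(),
                "LWD": np.concatenate([anc_arr[:, j], d_arr[:, j]]),
                "LWS": np.concatenate([anc_arr[:, j], s_arr[:, j]]),
            })

        all_chrom.append(np.full(pos.size, chrom, dtype=object))
        all_pos.append(pos)

    hapset = HaplotypeSet(
        chrom=np.concatenate(all_chrom),
        pos=np.concatenate(all_pos),
        haplotypes={pop: np.hstack(haps[pop]) for pop in POPULATIONS},
    )
    if config.ascertain:
        union = np.vstack([hapset.haplotypes[p] for p in POPULATIONS])
        seg = (union.sum(axis=0) > 0) & (union.sum(axis=0) < union.shape[0])
        hapset = HaplotypeSet(
            chrom=hapset.chrom[seg], pos=hapset.pos[seg],
            haplotypes={p: h[:, seg] for p, h in hapset.haplotypes.items()})
    return hapset, truth


def deterministic_trajectory(f0: float, s: float, gens: int) -> np.ndarray:
    """Deterministic genic-selection recursion (no drift)."""
    f = np.empty(gens + 1)
    f[0] = f0
    for t in range(gens):
        f[t + 1] = _genic_update(np.array([f[t]]), s)[0]
    return f


def _genic_update(f: np.ndarray, s: float) -> np.ndarray:
    """Expected post-selection frequency of the counted allele.

    Positive s favours the counted allele; negative s gives the *other*
    allele the advantage |s|, which makes the map exactly equivariant under
    allele relabelling (f -> 1-f, s -> -s).
    """
    if s >= 0:
        return f * (1 + s) / (1 + f * s)
    q = 1.0 - f
    return 1.0 - q * (1 - s) / (1 - q * s)


def simulate_temporal_counts(ne: int, s: float, f0, gens: int,
                             sample_sizes: tuple[int, int], n_loci: int,
                             seed: int = 0,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Allele counts at two sampling times under a hidden WF trajectory.

    Returns ``(c1, c2)``: alternate-allele counts in samples of
    ``sample_sizes`` diploids taken before and after ``gens`` generations of
    drift (binomial 2*ne resampling) and genic selection ``s``.  ``f0`` may
    be a scalar or an array of per-locus initial frequencies.
    """
    if ne <= 0:
        raise ValueError("ne must be > 0")
    if gens == 0 and s != 0:
        raise ValueError("gens = 0 with s != 0 is contradictory")
    if s <= -1:
        raise ValueError("selective advantage must be > -1")
    f0 = np.broadcast_to(np.asarray(f0, dtype=float), (n_loci,)).copy()
    if np.any((f0 <= 0) | (f0 >= 1)):
        raise ValueError("f0 must be strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    n1, n2 = sample_sizes
    c1 = rng.binomial(2 * n1, f0)
    f = f0
    for _ in range(gens):
        f = rng.binomial(2 * ne, _genic_update(f, s)) / (2 * ne)
    c2 = rng.binomial(2 * n2, f)
    return c1, c2


# ---------------------------------------------------------------------------
# output writers

def write_vcf(hapset: HaplotypeSet, path: str | Path,
              missing_rate: float = 0.0, seed: int = 0) -> None:
    """Write a minimal GT-only VCF v4.2 for the union of the three samples.

    Genotypes are phased haplotype pairs; a fraction ``missing_rate`` of
    calls is masked to ``./.`` at random.
    """
    rng = np.random.default_rng(seed)
    names = hapset.sample_names()
    mats = [hapset.haplotypes[pop] for pop in POPULATIONS]
    H = np.vstack(mats)  # (2*total_samples, n_var)
    n_samp = H.shape[0] // 2
    miss = (rng.random((hapset.n_variants, n_samp)) < missing_rate
            if missing_rate > 0 else None)

    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(hapset.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for v in range(hapset.n_variants):
            gts = []
            for i in range(n_samp):
                if miss is not None and miss[v, i]:
                    gts.append("./.")
                else:
                    gts.append(f"{H[2 * i, v]}|{H[2 * i + 1, v]}")
            fh.write(f"{hapset.chrom[v]}\t{hapset.pos[v]}\t.\tA\tG\t.\t.\t.\t"
                     f"GT\t" + "\t".join(gts) + "\n")


def write_sample_map(hapset: HaplotypeSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tpopulation\n")
        for name in hapset.sample_names():
            fh.write(f"{name}\t{name.split('_')[0]}\n")


def write_truth(truth: TruthTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("chrom\tpos\ts_d\ts_s\ts_pre\tlabel\n")
        for sc in truth.scenarios:
            fh.write(f"{sc.chrom}\t{sc.position_bp}\t{sc.s_d}\t{sc.s_s}\t"
                     f"{sc.s_pre}\t{sc.label}\n")
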