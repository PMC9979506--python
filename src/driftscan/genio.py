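"""Genotype I/O and basic diversity statistics.

VCF files are read through cyvcf2 into a dense dosage matrix; all downstream
statistics (per-population allele frequencies, MAF filters, polymorphism and
private-allele summaries, IBS/MDS, windowed missingness) operate on that
matrix.  Coordinates are 1-based inclusive throughout (VCF convention);
BED-style output is converted at the writers only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes for labelled population samples.

    ``dosage`` holds per-variant alternate-allele counts in {0, 1, 2} with
    ``-1`` marking a missing call (``./.`` in the VCF).
    """

    variants: pd.DataFrame          # columns chrom, pos, ref, alt
    dosage: np.ndarray              # (n_var, n_samples) int8
    samples: list[str]
    populations: dict[str, str]     # sample -> population label

    def __post_init__(self) -> None:
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted on chromosome {chrom}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def pop_labels(self) -> list[str]:
        return list(dict.fromkeys(self.populations[s] for s in self.samples))

    def pop_indices(self, pop: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples)
               if self.populations[s] == pop]
        if not idx:
            raise ValueError(f"no samples in population {pop!r}")
        return np.array(idx)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.variants.loc[mask].reset_index(drop=True),
                              self.dosage[mask], list(self.samples),
                              dict(self.populations))


@dataclass
class FreqTable:
    """Per-variant, per-population allele counts and frequencies."""

    variants: pd.DataFrame
    pops: list[str]
    alt_count: np.ndarray     # (n_var, n_pop) called alternate alleles
    called: np.ndarray        # (n_var, n_pop) called alleles (2 x calls)
    n_samples: dict[str, int]

    @property
    def freq(self) -> np.ndarray:
        """Alternate-allele frequency; NaN where no allele was called."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.called > 0, self.alt_count / self.called,
                            np.nan)

    @property
    def call_rate(self) -> np.ndarray:
        n = np.array([2 * self.n_samples[p] for p in self.pops], dtype=float)
        return self.called / n

    def pop_index(self, pop: str) -> int:
        return self.pops.index(pop)


def read_sample_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_vcf(path: str | Path, sample_map: Mapping[str, str] | str | Path,
             mode: str = "HQ") -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix.

    ``mode="HQ"`` keeps biallelic SNPs only; ``mode="AV"`` additionally keeps
    biallelic indels (multiallelic records are dropped in both modes).
    """
    from cyvcf2 import VCF

    if mode not in {"HQ", "AV"}:
        raise ValueError("mode must be 'HQ' or 'AV'")
    if not isinstance(sample_map, Mapping):
        sample_map = read_sample_map(sample_map)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing_in_header = set(sample_map) - set(samples)
    if missing_in_header:
        raise ValueError(f"samples not in VCF header: {sorted(missing_in_header)}")

    rows, dosages = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        is_snp = len(var.REF) == 1 and len(var.ALT[0]) == 1 \
            and var.REF in "ACGT" and var.ALT[0] in "ACGT"
        if mode == "HQ" and not is_snp:
            continue
        g = np.asarray(var.genotypes)[:, :2]
        d = np.where((g < 0).any(axis=1), MISSING, g.sum(axis=1)).astype(np.int8)
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        dosages.append(d)
    vcf.close()

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = (np.vstack(dosages) if dosages
              else np.empty((0, len(samples)), dtype=np.int8))
    keep = [i for i, s in enumerate(samples) if s in sample_map]
    return GenotypeMatrix(variants, dosage[:, keep],
                          [samples[i] for i in keep],
                          {samples[i]: sample_map[samples[i]] for i in keep})


def from_haplotypes(hapset, missing_rate: float = 0.0,
                    seed: int = 0) -> GenotypeMatrix:
    """Build a GenotypeMatrix directly from simulator output (no I/O)."""
    rng = np.random.default_rng(seed)
    names = hapset.sample_names()
    H = np.vstack([hapset.haplotypes[p] for p in ("ANC", "LWD", "LWS")])
    dosage = (H[0::2] + H[1::2]).T.astype(np.int8)  # (n_var, n_samples)
    if missing_rate > 0:
        miss = rng.random(dosage.shape) < missing_rate
        dosage = np.where(miss, MISSING, dosage).astype(np.int8)
    variants = pd.DataFrame({"chrom": hapset.chrom, "pos": hapset.pos,
                             "ref": "A", "alt": "G"})
    pops = {n: n.split("_")[0] for n in names}
    return GenotypeMatrix(variants, dosage, names, pops)


def allele_freqs(g: GenotypeMatrix, pops: Iterable[str] | None = None
                 ) -> FreqTable:
    """Per-population alternate-allele frequencies; missing calls excluded."""
    pops = list(pops) if pops is not None else g.pop_labels
    n_var = g.n_variants
    alt = np.zeros((n_var, len(pops)), dtype=np.int64)
    called = np.zeros((n_var, len(pops)), dtype=np.int64)
    n_samples = {}
    for j, pop in enumerate(pops):
        idx = g.pop_indices(pop)
        n_samples[pop] = idx.size
        d = g.dosage[:, idx]
        ok = d != MISSING
        alt[:, j] = np.where(ok, d, 0).sum(axis=1)
        called[:, j] = 2 * ok.sum(axis=1)
    return FreqTable(g.variants, pops, alt, called, n_samples)


def maf_filter(f: FreqTable, pops: Iterable[str], threshold: float = 0.10
               ) -> np.ndarray:
    """Boolean mask of variants with pooled MAF strictly above ``threshold``.

    Pooling is on allele counts over the named populations (well defined with
    unequal or incomplete samples), not a mean of frequencies.
    """
    pops = list(pops)
    if not pops:
        raise ValueError("empty population subset")
    if not 0 <= threshold <= 0.5:
        raise ValueError("threshold must be in [0, 0.5]")
    cols = [f.pop_index(p) for p in pops]
    alt = f.alt_count[:, cols].sum(axis=1)
    called = f.called[:, cols].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, alt / called, np.nan)
    maf = np.minimum(p, 1 - p)
    return (maf > threshold) & ~np.isnan(maf)


def diversity_summary(g: GenotypeMatrix) -> pd.DataFrame:
    """% polymorphic and % private-minor-allele variants per population.

    A variant is polymorphic in a population when both alleles are observed
    there; the globally less frequent allele is private to a population when
    it is observed in that population only.
    """
    pops = g.pop_labels
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    f = allele_freqs(g, pops)
    alt, called = f.alt_count, f.called
    ref = called - alt

    total_alt, total_called = alt.sum(axis=1), called.sum(axis=1)
    # global minor allele; ties resolved toward the alternate allele
    minor_is_alt = total_alt * 2 <= total_called
    minor = np.where(minor_is_alt[:, None], alt, ref)
    minor_observed = minor > 0

    rows = []
    for j, pop in enumerate(pops):
        poly = (alt[:, j] > 0) & (ref[:, j] > 0)
        private = minor_observed[:, j] & ~np.delete(
            minor_observed, j, axis=1).any(axis=1)
        # a "private" allele absent everywhere is meaningless
        private &= minor_observed.any(axis=1)
        rows.append({"population": pop,
                     "pct_polymorphic": 100.0 * poly.mean() if len(poly) else 0.0,
                     "pct_private": 100.0 * private.mean() if len(private) else 0.0})
    return pd.DataFrame(rows)


def ibs_distance(g: GenotypeMatrix, min_sites: int = 100
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise IBS distance (1 - shared-allele proportion over co-called sites).

    Returns ``(dist, reliable)`` where ``reliable`` flags pairs with at least
    ``min_sites`` co-called sites.
    """
    d = g.dosage.astype(float)
    d[g.dosage == MISSING] = np.nan
    n = d.shape[1]
    dist = np.zeros((n, n))
    reliable = np.ones((n, n), dtype=bool)
    for i in range(n):
        diff = np.abs(d[:, i:i + 1] - d[:, i:])
        co = ~np.isnan(diff)
        counts = co.sum(axis=0)
        with np.errstate(invalid="ignore"):
            row = np.nansum(diff, axis=0) / (2 * counts)
        dist[i, i:] = np.where(counts > 0, row, np.nan)
        dist[i:, i] = dist[i, i:]
        reliable[i, i:] = reliable[i:, i] = counts >= min_sites
    np.fill_diagonal(dist, 0.0)
    return dist, reliable


def classical_mds(dist: np.ndarray, k: int) -> np.ndarray:
    """Torgerson MDS: double-centre the squared distances, eigendecompose."""
    n = dist.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-12
    rank = int(pos.sum())
    if k > rank:
        import warnings
        warnings.warn(f"requested {k} MDS dimensions but rank is {rank}; "
                      "truncating")
        k = rank
    return vecs[:, :k] * np.sqrt(vals[:k])


def ibs_mds(g: GenotypeMatrix, k: int = 2) -> pd.DataFrame:
    """Classical MDS embedding of the IBS distance matrix."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if (g.dosage == MISSING).all(axis=0).any():
        raise ValueError("a sample has 100% missing genotypes")
    dist, _ = ibs_distance(g)
    coords = classical_mds(dist, k)
    out = pd.DataFrame(coords, columns=[f"C{i + 1}" for i in range(coords.shape[1])])
    out.insert(0, "sample", g.samples)
    out.insert(1, "population", [g.populations[s] for s in g.samples])
    return out


def windowed_missingness(g: GenotypeMatrix, window_bp: int = 2000
                         ) -> pd.DataFrame:
    """Missing-call fraction in non-overlapping windows along each chromosome.

    Windows containing no variant are reported with NaN.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    rows = []
    miss = (g.dosage == MISSING)
    for chrom, grp in g.variants.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        idx = grp.index.to_numpy()
        n_win = int(pos.max() // window_bp) + 1
        win = (pos - 1) // window_bp
        for w in range(n_win):
            sel = idx[win == w]
            frac = miss[sel].mean() if sel.size else np.nan
            rows.append({"chrom": chrom, "start": w * window_bp + 1,
                         "end": (w + 1) * window_bp,
                         "n_variants": sel.size, "missing_frac": frac})
    return pd.DataFrame(rows)
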