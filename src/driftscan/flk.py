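"""Tree-based single-SNP differentiation test (FLK).

Neutral evolution of allele frequencies is modelled by a rooted population
tree whose branch lengths are drift units (~ t / 2Ne).  The tree is estimated
genome-wide from pairwise Reynolds distances by neighbour joining, rooted on
an outgroup population which is then removed.  The kinship matrix F collects
the drift shared by each pair of tested populations from the root; per-SNP
deviations from the tree are chi-square distributed under neutrality.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genio import FreqTable


@dataclass
class PopulationTree:
    populations: list[str]        # tested populations, outgroup removed
    kinship: np.ndarray           # (n, n) symmetric PSD drift matrix F
    branch_report: str            # human-readable topology + lengths

    def __post_init__(self) -> None:
        F = self.kinship
        if not np.allclose(F, F.T):
            raise ValueError("kinship matrix must be symmetric")
        if np.any(np.diag(F) + 1e-12 < np.max(np.abs(F - np.diag(np.diag(F))),
                                              axis=0, initial=0)):
            warnings.warn("kinship diagonal smaller than off-diagonal entries")


def reynolds_distance(f: FreqTable, pop_i: str, pop_j: str,
                      mask: np.ndarray | None = None) -> float:
    """Ratio-of-sums Reynolds drift distance between two populations.

    Per-locus numerator (p_i - p_j)^2 and denominator
    (1 - p_i p_j - q_i q_j) / 2, summed over loci before taking the ratio.
    Under pure drift from a common ancestor E[(p_i - p_j)^2] =
    (F_i + F_j) p0 q0 and E[1 - p_i p_j - q_i q_j] = 2 p0 q0, so the ratio
    estimates the total drift F_i + F_j separating the populations and NJ
    branch lengths come out in per-population drift units (~ t / 2Ne).
    Sample-size (heterozygosity) corrections of the full Reynolds estimator
    are omitted.
    """
    p = f.freq
    i, j = f.pop_index(pop_i), f.pop_index(pop_j)
    pi, pj = p[:, i], p[:, j]
    ok = ~np.isnan(pi) & ~np.isnan(pj)
    if mask is not None:
        ok &= mask
    pi, pj = pi[ok], pj[ok]
    num = ((pi - pj) ** 2).sum()
    den = 0.5 * (1.0 - pi * pj - (1 - pi) * (1 - pj)).sum()
    if den <= 0:
        raise ValueError("degenerate Reynolds denominator (no polymorphism)")
    return float(num / den)


def _nj_tree(dist: np.ndarray, labels: list[str]):
    from skbio import DistanceMatrix
    from skbio.tree import nj

    return nj(DistanceMatrix(dist, ids=labels))


def estimate_tree(f: FreqTable, tested: list[str], outgroup: str,
                  mask: np.ndarray | None = None) -> PopulationTree:
    """Estimate the population tree and kinship matrix F.

    Pairwise Reynolds distances -> neighbour joining -> root where the
    outgroup attaches -> drop the outgroup -> F from shared branch lengths.
    Negative NJ branch lengths are truncated to zero.
    """
    pops = list(tested) + [outgroup]
    if len(pops) < 3:
        raise ValueError("need >= 2 tested populations plus an outgroup")
    n = len(pops)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = reynolds_distance(f, pops[i], pops[j],
                                                        mask)
    tree = _nj_tree(dist, pops)

    og_tip = tree.find(outgroup)
    root = og_tip.parent
    tree = tree.root_at(root) if root.parent is not None else tree
    og_tip = tree.find(outgroup)

    truncated = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            truncated = True
    if truncated:
        warnings.warn("negative NJ branch lengths truncated to 0")

    # drift shared from the root: sum of common ancestral branch lengths
    root = tree.root()
    paths = {}
    for name in tested:
        tip = tree.find(name)
        edges = []
        node = tip
        while node is not root:
            edges.append(node)
            node = node.parent
        paths[name] = edges
    F = np.zeros((len(tested), len(tested)))
    for i, a in enumerate(tested):
        for j, b in enumerate(tested):
            shared = set(map(id, paths[a])) & set(map(id, paths[b]))
            F[i, j] = sum(e.length or 0.0 for e in paths[a]
                          if id(e) in shared)

    report = tree.ascii_art() + "\nF =\n" + np.array_str(F, precision=5)
    return PopulationTree(list(tested), F, report)


def kinship_inverse(F: np.ndarray) -> np.ndarray:
    """Inverse of F, ridge-regularised when a branch length collapsed to 0."""
    F = np.asarray(F, dtype=float)
    try:
        return np.linalg.inv(F)
    except np.linalg.LinAlgError:
        ridge = 1e-6 * max(np.mean(np.diag(F)), 1e-6)
        return np.linalg.inv(F + ridge * np.eye(F.shape[0]))


def tree_from_kinship(populations: list[str], F: np.ndarray) -> PopulationTree:
    """Wrap a known kinship matrix (used in simulations and tests)."""
    return PopulationTree(list(populations), np.asarray(F, dtype=float),
                          "kinship supplied directly")


def flk_test(f: FreqTable, tree: PopulationTree) -> pd.DataFrame:
    """FLK statistic and chi-square p-value for every variant.

    p0_hat = (1' F^-1 p) / (1' F^-1 1);
    FLK = (p - p0_hat 1)' [p0_hat (1 - p0_hat) F]^-1 (p - p0_hat 1),
    compared to chi-square with (#populations - 1) degrees of freedom.
    Variants with undefined frequencies or p0_hat in {0, 1} get NaN.
    """
    cols = [f.pop_index(p) for p in tree.populations]
    p = f.freq[:, cols]
    F = tree.kinship
    Finv = kinship_inverse(F)
    a = Finv.sum(axis=1)
    denom = a.sum()
    if denom <= 0:
        raise ValueError("kinship matrix not positive definite")

    p0 = p @ a / denom
    resid = p - p0[:, None]
    quad = np.einsum("vi,ij,vj->v", resid, Finv, resid)
    with np.errstate(invalid="ignore", divide="ignore"):
        flk = quad / (p0 * (1 - p0))
    bad = np.isnan(p).any(axis=1) | (p0 <= 0) | (p0 >= 1)
    flk = np.where(bad, np.nan, flk)
    pval = stats.chi2.sf(flk, df=len(cols) - 1)
    out = f.variants[["chrom", "pos"]].copy()
    out["flk"] = flk
    out["p"] = np.where(bad, np.nan, pval)
    out["p0_hat"] = np.where(bad, np.nan, p0)
    return out
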