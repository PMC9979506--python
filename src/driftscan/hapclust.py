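"""Haplotype-cluster HMM and the hapFLK statistic.

Unphased genotypes are modelled by a fastPHASE-style hidden Markov model:
each of the two haplotypes of an individual follows a Markov chain over K
latent clusters, with site-specific cluster allele frequencies theta[l, k],
site-specific cluster weights alpha[l, k] and a single genome-wide jump
intensity rho (per marker interval).  The diploid chain runs over ordered
cluster pairs; the forward-backward recursions exploit the product structure
so all operations stay K x K.

hapFLK extends the single-SNP FLK test to local haplotype-cluster
frequencies: at every site the FLK quadratic form is summed over clusters and
averaged over independently seeded EM fits.  P-values come from a scaled
chi-square fitted robustly to the genome-wide empirical distribution, and
significance is assessed by Storey q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .genio import MISSING, GenotypeMatrix
from . import flk as flk_mod
from .flk import PopulationTree

THETA_FLOOR = 1e-4
ALPHA_FLOOR = 1e-8


@dataclass
class ClusterModel:
    K: int
    theta: np.ndarray          # (L, K) cluster allele frequencies
    alpha: np.ndarray          # (L, K) cluster weights, rows sum to 1
    rho: float                 # per-interval jump probability
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    usage: np.ndarray | None = None   # (N, L, K) posterior slot marginals


def _emission_stack(theta_l: np.ndarray) -> np.ndarray:
    """(4, K, K) emission matrices for genotypes 0/1/2/missing."""
    p = theta_l
    q = 1.0 - p
    E = np.empty((4, p.size, p.size))
    E[0] = np.outer(q, q)
    E[1] = np.outer(p, q) + np.outer(q, p)
    E[2] = np.outer(p, p)
    E[3] = 1.0
    return E


def _forward(gcode: np.ndarray, theta: np.ndarray, alpha: np.ndarray,
             rho: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward pass.  Returns (F, c, loglik).

    gcode: (N, L) genotype codes with 3 = missing; F: (L, N, K, K).
    """
    N, L = gcode.shape
    K = theta.shape[1]
    F = np.empty((L, N, K, K))
    c = np.empty((L, N))
    E = _emission_stack(theta[0])[gcode[:, 0]]
    f = np.outer(alpha[0], alpha[0])[None] * E
    c[0] = f.sum(axis=(1, 2))
    F[0] = f / c[0][:, None, None]
    eye = np.eye(K)
    for l in range(1, L):
        T = (1.0 - rho) * eye + rho * np.tile(alpha[l], (K, 1))
        pred = np.matmul(T.T, np.matmul(F[l - 1], T))
        E = _emission_stack(theta[l])[gcode[:, l]]
        f = pred * E
        c[l] = f.sum(axis=(1, 2))
        F[l] = f / c[l][:, None, None]
    loglik = float(np.log(c).sum())
    return F, c, loglik


def _em_iteration(gcode: np.ndarray, theta: np.ndarray, alpha: np.ndarray,
                  rho: float, update_rho: bool
                  ) -> tuple[np.ndarray, np.ndarray, float, float, np.ndarray]:
    """One EM step.  Returns (theta', alpha', rho', loglik, usage)."""
    N, L = gcode.shape
    K = theta.shape[1]
    F, c, loglik = _forward(gcode, theta, alpha, rho)
    eye = np.eye(K)

    theta_num = np.zeros((L, K))
    theta_den = np.zeros((L, K))
    alpha_new = np.zeros((L, K))
    usage = np.empty((N, L, K))
    jumps = 0.0

    B = np.ones((N, K, K))
    for l in range(L - 1, -1, -1):
        E = _emission_stack(theta[l])[gcode[:, l]]
        gamma = F[l] * B                      # (N, K, K), sums to 1 per n
        usage[:, l] = gamma.sum(axis=2)

        # allele attribution for the theta update (slot A; slot B symmetric)
        p = theta[l]
        with np.errstate(invalid="ignore", divide="ignore"):
            het_den = np.outer(p, 1 - p) + np.outer(1 - p, p)
            W1 = np.where(het_den > 0, np.outer(p, 1 - p) / het_den, 0.5)
        Wstack = np.stack([np.zeros((K, K)), W1, np.ones((K, K)),
                           np.zeros((K, K))])
        W = Wstack[gcode[:, l]]               # (N, K, K)
        observed = (gcode[:, l] != 3).astype(float)
        theta_num[l] = 2.0 * (gamma * W).sum(axis=2).T @ observed
        theta_den[l] = 2.0 * gamma.sum(axis=2).T @ observed

        if l > 0:
            T = (1.0 - rho) * eye + rho * np.tile(alpha[l], (K, 1))
            W_b = E * B                       # (N, K, K)
            G = np.matmul(np.matmul(F[l - 1], T), W_b.transpose(0, 2, 1))
            colsum = G.sum(axis=1) / c[l][:, None]          # (N, K)
            jump_in = 2.0 * rho * alpha[l][None, :] * colsum
            alpha_new[l] = jump_in.sum(axis=0)
            jumps += jump_in.sum()
            # propagate backward
            B = np.matmul(T, np.matmul(W_b, T.T)) / c[l][:, None, None]
        else:
            alpha_new[0] = 2.0 * usage[:, 0].sum(axis=0)

    with np.errstate(invalid="ignore"):
        theta_new = np.where(theta_den > 0, theta_num / theta_den, theta)
    theta_new = np.clip(theta_new, THETA_FLOOR, 1 - THETA_FLOOR)
    alpha_new += ALPHA_FLOOR
    alpha_new /= alpha_new.sum(axis=1, keepdims=True)
    rho_new = jumps / (2.0 * N * max(L - 1, 1)) if update_rho and L > 1 else rho
    rho_new = float(np.clip(rho_new, 1e-6, 0.999))
    return theta_new, alpha_new, rho_new, loglik, usage


def fit_cluster_model(dosage: np.ndarray, K: int, seed: int = 0,
                      rho_init: float = 0.05, max_iter: int = 100,
                      tol: float = 1e-6, update_rho: bool = True
                      ) -> ClusterModel:
    """Fit the cluster HMM to an (n_variants, n_individuals) dosage matrix.

    Missing genotypes (-1) contribute no emission information.  EM stops when
    the relative log-likelihood change drops below ``tol`` or after
    ``max_iter`` iterations; the log-likelihood trace is monotone.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    dosage = np.asarray(dosage)
    gcode = dosage.T.copy()                  # (N, L)
    gcode[gcode == MISSING] = 3
    gcode = gcode.astype(np.int8)
    N, L = gcode.shape
    rng = np.random.default_rng(seed)

    with np.errstate(invalid="ignore"):
        obs = gcode != 3
        freq = np.where(obs.sum(axis=0) > 0,
                        np.where(obs, gcode, 0).sum(axis=0) / (2 * obs.sum(axis=0)),
                        0.5)
    theta = np.clip(freq[:, None] + rng.normal(0, 0.15, size=(L, K)),
                    0.02, 0.98)
    alpha = np.full((L, K), 1.0 / K)
    rho = rho_init if K > 1 else 1e-6

    trace: list[float] = []
    usage = None
    prev = -np.inf
    for _ in range(max_iter):
        theta, alpha, rho, loglik, usage = _em_iteration(
            gcode, theta, alpha, rho, update_rho and K > 1)
        if not np.isfinite(loglik):
            raise FloatingPointError("non-finite likelihood in cluster EM; "
                                     f"rho={rho}, K={K}")
        trace.append(loglik)
        if prev > -np.inf and abs(loglik - prev) < tol * abs(prev):
            break
        prev = loglik
    # trace[i] is the likelihood under the parameters *before* update i; one
    # final forward pass scores the returned parameters
    _, _, final_ll = _forward(gcode, theta, alpha, rho)
    trace.append(final_ll)
    return ClusterModel(K, theta, alpha, rho, final_ll, trace, usage)


def cluster_frequencies(model: ClusterModel, g: GenotypeMatrix,
                        populations: list[str]) -> np.ndarray:
    """Posterior-weighted cluster frequencies: (n_pop, L, K), rows sum to 1."""
    if model.usage is None:
        raise ValueError("model carries no posterior usage")
    out = np.empty((len(populations), model.theta.shape[0], model.K))
    for j, pop in enumerate(populations):
        idx = g.pop_indices(pop)
        out[j] = model.usage[idx].mean(axis=0)
    return out


def cluster_tracks(model: ClusterModel, g: GenotypeMatrix,
                   populations: list[str]) -> pd.DataFrame:
    """Long-format cluster-frequency track for stacked-band plotting."""
    freqs = cluster_frequencies(model, g, populations)
    rows = []
    for j, pop in enumerate(populations):
        for l in range(freqs.shape[1]):
            for k in range(model.K):
                rows.append((pop, g.variants["chrom"].iat[l],
                             int(g.variants["pos"].iat[l]), k, freqs[j, l, k]))
    return pd.DataFrame(rows, columns=["population", "chrom", "pos",
                                       "cluster", "freq"])


def _hapflk_quadform(freqs: np.ndarray, Finv: np.ndarray) -> np.ndarray:
    """Multi-cluster FLK quadratic form per site.

    freqs: (n_pop, L, K) cluster frequencies.  Clusters whose estimated
    ancestral frequency hits 0 or 1 contribute nothing at that site.
    """
    a = Finv.sum(axis=1)
    asum = a.sum()
    p0 = np.einsum("i,ilk->lk", a, freqs) / asum          # (L, K)
    resid = freqs - p0[None]                              # (n_pop, L, K)
    quad = np.einsum("ilk,ij,jlk->lk", resid, Finv, resid)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = quad / (p0 * (1 - p0))
    ok = (p0 > 0) & (p0 < 1)
    return np.where(ok, terms, 0.0).sum(axis=1)


def hapflk_statistic(g: GenotypeMatrix, tree: PopulationTree, K: int = 10,
                     nfit: int = 10, seed: int = 0, max_iter: int = 100,
                     tol: float = 1e-6, include: list[str] | None = None
                     ) -> np.ndarray:
    """hapFLK statistic per variant, averaged over ``nfit`` EM fits.

    The cluster model is fitted per chromosome on the individuals of the
    tested populations (plus ``include`` populations, if any, which join the
    fit but not the statistic).
    """
    pops = tree.populations
    fit_pops = pops + [p for p in (include or []) if p not in pops]
    idx = np.concatenate([g.pop_indices(p) for p in fit_pops])
    Finv = flk_mod.kinship_inverse(tree.kinship)

    sub_samples = [g.samples[i] for i in idx]
    sub_pops = {s: g.populations[s] for s in sub_samples}
    stat = np.zeros(g.n_variants)
    for chrom, grp in g.variants.groupby("chrom", sort=False):
        rows = grp.index.to_numpy()
        dose = g.dosage[rows][:, idx]
        sub = GenotypeMatrix(grp.reset_index(drop=True), dose, sub_samples,
                             sub_pops)
        acc = np.zeros(rows.size)
        for i in range(nfit):
            model = fit_cluster_model(dose, K, seed=seed * 1009 + i,
                                      max_iter=max_iter, tol=tol)
            freqs = cluster_frequencies(model, sub, pops)
            acc += _hapflk_quadform(freqs, Finv)
        stat[rows] = acc / nfit
    return stat


def fit_scaled_chi2(values: np.ndarray) -> tuple[float, float]:
    """Robust (scale, df) of a scaled chi-square matched to median and Q3.

    Quantile matching is robust to the selected upper tail that motivates the
    scan in the first place.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 10:
        raise ValueError("too few finite statistics to fit the null")
    med, q75 = np.quantile(v, [0.5, 0.75])
    target = q75 / med

    def ratio(df):
        with np.errstate(divide="ignore"):
            return stats.chi2.ppf(0.75, df) / stats.chi2.ppf(0.5, df) - target

    lo, hi = 1e-2, 1e4
    if ratio(lo) < 0 or ratio(hi) > 0:   # outside achievable range
        df = 1.0
    else:
        df = brentq(ratio, lo, hi)
    scale = med / stats.chi2.ppf(0.5, df)
    return float(scale), float(df)


def hapflk_test(g: GenotypeMatrix, tree: PopulationTree, K: int = 10,
                nfit: int = 10, seed: int = 0, max_iter: int = 100,
                tol: float = 1e-6) -> pd.DataFrame:
    """hapFLK scan: statistic, scaled-chi-square p-value and Storey q-value."""
    if nfit < 1:
        raise ValueError("nfit must be >= 1")
    stat = hapflk_statistic(g, tree, K, nfit, seed, max_iter, tol)
    scale, df = fit_scaled_chi2(stat)
    p = stats.chi2.sf(stat / scale, df)
    out = g.variants[["chrom", "pos"]].copy()
    out["hapflk"] = stat
    out["p"] = p
    out["q"] = qvalues(p)
    return out


def qvalues(p: np.ndarray, lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values with the smoothed-lambda pi0 estimator.

    For fewer than 100 p-values pi0 is set to 1 (Benjamini-Hochberg
    behaviour), which also covers the degenerate single-p case.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    ok = ~np.isnan(p)
    pv = p[ok]
    n = pv.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    # the estimator needs a populated right tail: lambdas at or beyond the
    # largest p carry no information and drive pi0 to 0
    lambdas = lambdas[lambdas < max(pv.max() - 0.05, 0.0)]
    if n < 100 or lambdas.size < 5:
        pi0 = 1.0
    else:
        pi0s = np.array([(pv > lam).mean() / (1 - lam) for lam in lambdas])
        from scipy.interpolate import UnivariateSpline
        spl = UnivariateSpline(lambdas, pi0s, k=3)
        pi0 = float(np.clip(spl(lambdas[-1]), 0.05, 1.0))
    order = np.argsort(pv)
    q = np.empty(n)
    ranked = pi0 * pv[order] * n / (np.arange(n) + 1)
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.full(p.shape, np.nan)
    out[ok] = np.minimum(q, 1.0)
    return out
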