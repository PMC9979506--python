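"""Local-score segmentation of per-SNP p-values (Lindley process).

Each SNP contributes a score X_i = -log10(p_i) - xi; the Lindley process
h_i = max(0, h_{i-1} + X_i) accumulates runs of unusually small p-values.
Per-chromosome significance thresholds are calibrated by Monte Carlo to a
target chromosome-wide false-positive rate under independent uniform
p-values (or by circular shifts of observed p-values for an
autocorrelation-robust null).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

DEFAULT_XI = 2.0


@dataclass
class Segment:
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    peak: float


def scores(p: np.ndarray, xi: float = DEFAULT_XI) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p = 0 clamped to smallest positive float")
        p = np.maximum(p, np.finfo(float).tiny)
    return -np.log10(p) - xi


def lindley(p: np.ndarray, xi: float = DEFAULT_XI) -> np.ndarray:
    """Lindley (local-score) process over position-ordered p-values."""
    x = scores(p, xi)
    h = np.empty(x.size)
    acc = 0.0
    for i in range(x.size):
        acc = max(0.0, acc + x[i])
        h[i] = acc
    return h


def _max_lindley_null(n_snps: int, xi: float, n_reps: int,
                      rng: np.random.Generator,
                      observed_p: np.ndarray | None = None) -> np.ndarray:
    """Max of the Lindley process on null chromosomes (vectorised over reps)."""
    if observed_p is None:
        x = -np.log10(rng.random((n_reps, n_snps))) - xi
    else:
        base = scores(observed_p, xi)
        shifts = rng.integers(base.size, size=n_reps)
        x = np.stack([np.roll(base, k) for k in shifts])
        n_snps = base.size
    h = np.zeros(n_reps)
    best = np.zeros(n_reps)
    for i in range(n_snps):
        h = np.maximum(0.0, h + x[:, i])
        best = np.maximum(best, h)
    return best


def calibrate_threshold(n_snps: int, xi: float = DEFAULT_XI,
                        fpr_target: float = 0.01, n_reps: int = 1000,
                        seed: int = 0,
                        observed_p: np.ndarray | None = None) -> float:
    """Monte-Carlo threshold achieving a chromosome-wide FPR of ``fpr_target``.

    Draws ``n_reps`` null chromosomes of ``n_snps`` independent uniform
    p-values (or circular shifts of ``observed_p``) and returns the
    (1 - fpr_target) quantile of the maximum Lindley value.
    """
    if not 0 < fpr_target < 1:
        raise ValueError("fpr_target must be in (0, 1)")
    if n_reps < 10 / fpr_target:
        warnings.warn("n_reps is small for the requested FPR; the threshold "
                      "quantile will be noisy")
    rng = np.random.default_rng(seed)
    best = _max_lindley_null(n_snps, xi, n_reps, rng, observed_p)
    return float(np.quantile(best, 1.0 - fpr_target))


def call_segments(h: np.ndarray, threshold: float,
                  positions: np.ndarray) -> list[Segment]:
    """Maximal excursions of h above the threshold with genomic coordinates.

    Each above-threshold run is extended back to the SNP following the last
    zero of h; runs sharing that zero belong to the same excursion and are
    merged.
    """
    h = np.asarray(h, dtype=float)
    positions = np.asarray(positions)
    above = h > threshold
    if not above.any():
        return []
    # anchor of index i = last index j <= i with h[j] == 0 (or -1)
    zero_idx = np.where(h == 0, np.arange(h.size), -1)
    anchors = np.maximum.accumulate(zero_idx)
    segs: dict[int, list[int]] = {}
    for i in np.flatnonzero(above):
        segs.setdefault(int(anchors[i]), []).append(i)
    out = []
    for anchor, idxs in sorted(segs.items()):
        start = anchor + 1 if anchor >= 0 else 0
        end = max(idxs)
        start = min(start, min(idxs))
        out.append(Segment(start, end, int(positions[start]),
                           int(positions[end]), float(h[start:end + 1].max())))
    return out


def scan_chromosome(p: np.ndarray, positions: np.ndarray,
                    xi: float = DEFAULT_XI, fpr_target: float = 0.01,
                    n_reps: int = 1000, seed: int = 0,
                    threshold: float | None = None) -> list[Segment]:
    """Calibrate (unless given) and apply the local-score segment caller."""
    if threshold is None:
        threshold = calibrate_threshold(len(p), xi, fpr_target, n_reps, seed)
    h = lindley(p, xi)
    return call_segments(h, threshold, positions)
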