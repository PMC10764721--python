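"""Histogram-based Otsu threshold solver with a brute-force oracle.

Otsu's criterion picks the histogram cut maximising the between-class
variance sigma_b^2 = w0 * w1 * (mu0 - mu1)^2, equivalently minimising the
within-class variance. Both the purple-pink transform channel and the
luminance baseline are thresholded with the same solver.

Two choices the classical 256-grey-level formulation leaves open for
continuous data are made here and recorded in results:

* the histogram spans [0, max(values)] rather than [0, 1] — the transform
  channel concentrates its tissue mass near zero (realistic stains top out
  around 0.2), and a fixed [0, 1] domain would collapse it into a handful
  of bins;
* when several cuts tie on sigma_b^2, the midpoint of the contiguous
  maximising range of bin edges is returned (Otsu's original averaging
  suggestion; deterministic and symmetric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transform import IntensityMap

__all__ = [
    "Histogram",
    "ThresholdResult",
    "build_histogram",
    "otsu_threshold",
    "brute_force_threshold",
]

#: Lower bound on the histogram domain width, for all-zero inputs.
_EPS_DOMAIN = 1e-12
#: Relative tolerance grouping near-equal sigma_b^2 maxima into one tie range.
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class Histogram:
    """Equal-width binned counts of a single-channel raster."""

    bin_edges: np.ndarray  # n + 1 ascending floats
    counts: np.ndarray  # n non-negative integers

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        counts = np.asarray(self.counts, dtype=np.int64)
        if edges.ndim != 1 or counts.ndim != 1 or edges.size != counts.size + 1:
            raise ValueError("need n+1 edges for n counts")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if counts.min(initial=0) < 0:
            raise ValueError("counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("histogram must contain at least one observation")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class ThresholdResult:
    """An Otsu cut in data units.

    ``degenerate`` is set when no bin boundary splits the mass into two
    non-empty classes (a constant image); the threshold then falls back to
    the lowest bin edge and callers should emit an empty mask rather than an
    arbitrary split.
    """

    threshold: float
    between_class_variance: float
    degenerate: bool = False


def build_histogram(map_or_values, n_bins: int = 256) -> Histogram:
    """Bin an intensity map into ``n_bins`` equal-width bins over [0, max].

    The right-most bin is closed so the maximum value is counted. For an
    all-zero input the domain degenerates to [0, 1e-12].
    """
    if isinstance(map_or_values, IntensityMap):
        values = map_or_values.values
    else:
        values = np.asarray(map_or_values, dtype=np.float64)
    values = values.ravel()
    if values.size == 0:
        raise ValueError("cannot build a histogram from an empty map")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2; got {n_bins}")
    hi = max(float(values.max()), _EPS_DOMAIN)
    counts, edges = np.histogram(values, bins=int(n_bins), range=(0.0, hi))
    return Histogram(bin_edges=edges, counts=counts)


def _tie_midpoint(edges_at_boundaries: np.ndarray, sigma: np.ndarray, valid: np.ndarray) -> tuple[float, float]:
    """Midpoint of the contiguous maximising run containing the argmax."""
    sigma_max = sigma[valid].max()
    tol = abs(sigma_max) * _TIE_RTOL
    maximising = valid & (sigma >= sigma_max - tol)
    k = int(np.argmax(np.where(maximising, sigma, -np.inf)))
    lo = k
    while lo - 1 >= 0 and maximising[lo - 1]:
        lo -= 1
    hi = k
    while hi + 1 < maximising.size and maximising[hi + 1]:
        hi += 1
    threshold = 0.5 * (edges_at_boundaries[lo] + edges_at_boundaries[hi])
    return float(threshold), float(sigma_max)


def otsu_threshold(hist: Histogram) -> ThresholdResult:
    """Cut maximising the between-class variance over all bin boundaries.

    Class statistics use bin centres. Boundaries leaving either class empty
    are skipped; ties are resolved by the midpoint rule documented above.
    """
    counts = hist.counts.astype(np.float64)
    total = counts.sum()
    p = counts / total
    centers = hist.centers
    # boundary k sits after bin k, i.e. at bin_edges[k + 1], k = 0 .. n-2
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    m = np.cumsum(p * centers)
    mu_total = m[-1]
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return ThresholdResult(
            threshold=float(hist.bin_edges[0]),
            between_class_variance=0.0,
            degenerate=True,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(valid, m[:-1] / w0, 0.0)
        mu1 = np.where(valid, (mu_total - m[:-1]) / w1, 0.0)
    sigma = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    threshold, sigma_max = _tie_midpoint(hist.bin_edges[1:-1], sigma, valid)
    return ThresholdResult(threshold=threshold, between_class_variance=sigma_max, degenerate=False)


def brute_force_threshold(values, n_bins: int = 256) -> ThresholdResult:
    """Exhaustive Otsu oracle evaluated directly from the raw values.

    Quantises values to the same equal-width bin centres as
    :func:`build_histogram`, then for every candidate boundary computes the
    class weights and means by direct masking — no cumulative-sum shortcuts —
    and maximises sigma_b^2. Intended for tests; O(n_bins * n_values).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if np.unique(values).size < 2:
        raise ValueError("brute_force_threshold needs at least 2 distinct values")
    hi = max(float(values.max()), _EPS_DOMAIN)
    edges = np.histogram_bin_edges(values, bins=int(n_bins), range=(0.0, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    # same assignment rule as np.histogram: right-most bin closed
    idx = np.minimum(np.searchsorted(edges, values, side="right") - 1, int(n_bins) - 1)
    idx = np.maximum(idx, 0)
    quantised = centers[idx]
    n = values.size
    best: list[tuple[int, float]] = []
    sigma_max = -np.inf
    for k in range(int(n_bins) - 1):  # boundary after bin k
        left = idx <= k
        n0 = int(left.sum())
        if n0 == 0 or n0 == n:
            continue
        mu0 = quantised[left].mean()
        mu1 = quantised[~left].mean()
        w0 = n0 / n
        sigma = w0 * (1.0 - w0) * (mu0 - mu1) ** 2
        best.append((k, sigma))
        sigma_max = max(sigma_max, sigma)
    if not best:
        return ThresholdResult(float(edges[0]), 0.0, degenerate=True)
    tol = abs(sigma_max) * _TIE_RTOL
    maximising_ks = [k for k, s in best if s >= sigma_max - tol]
    # contiguous run containing the global argmax
    k_star = max(best, key=lambda ks: ks[1])[0]
    run = {k_star}
    k = k_star
    while k - 1 in maximising_ks:
        k -= 1
        run.add(k)
    k = k_star
    while k + 1 in maximising_ks:
        k += 1
        run.add(k)
    lo, hi_k = min(run), max(run)
    threshold = 0.5 * (edges[lo + 1] + edges[hi_k + 1])
    return ThresholdResult(float(threshold), float(sigma_max), degenerate=False)
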