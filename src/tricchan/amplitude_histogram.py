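"""All-points amplitude histograms and Gaussian-mixture level resolution.

Every sample of a single-channel recording is binned (default width
0.03 pA, one bin edge anchored exactly at 0 pA) and the histogram is
decomposed into a sum of k Gaussian components by nonlinear least squares.
The component means are the current levels of the closed state and the
multimeric open states (O1..O3 for one trimer, O1..O6 when a patch holds
two); converting level means to conductances only needs the holding
potential and the reversal potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit.models import GaussianModel

from .channel_sim import Trace

__all__ = [
    "AmplitudeHistogram",
    "MixtureFit",
    "build_histogram",
    "fit_mixture",
    "levels_to_conductances",
]

DEFAULT_BIN_WIDTH = 0.03  # pA


@dataclass
class AmplitudeHistogram:
    """Uniform-width all-points amplitude histogram (right-open bins)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_samples: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        widths = np.diff(self.bin_edges)
        if len(widths) != len(self.counts):
            raise ValueError("bin_edges must have len(counts)+1 entries")
        if np.any(widths <= 0) or not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("bin edges must be strictly increasing and uniform")
        if np.any(self.counts < 0) or self.counts.sum() != self.n_samples:
            raise ValueError("counts must be non-negative and sum to n_samples")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class MixtureFit:
    """Sum-of-Gaussians decomposition of an amplitude histogram.

    ``components`` are ``(mean_pA, sd_pA, area)`` tuples sorted by mean
    (ties broken by ascending sd); ``area`` is the integral of each
    component in counts*pA.  ``degenerate`` flags components whose area fell
    below 0.1% of the total (k larger than the number of resolvable peaks).
    """

    components: list
    k: int
    rss: float
    converged: bool
    degenerate: list
    shared_sd: bool = False

    @property
    def means(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def areas(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])


def build_histogram(trace, bin_width: float = DEFAULT_BIN_WIDTH) -> AmplitudeHistogram:
    """Bin every sample of a trace (or raw array) into right-open bins.

    Bins are anchored so that one edge falls exactly at an integer multiple
    of ``bin_width`` including 0 pA; a sample equal to an edge goes into the
    bin to its right.
    """
    samples = trace.samples if isinstance(trace, Trace) else np.asarray(trace, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot histogram an empty trace")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    idx = np.floor(samples / bin_width).astype(np.int64)
    lo, hi = int(idx.min()), int(idx.max())
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    edges = np.arange(lo, hi + 2, dtype=float) * bin_width
    return AmplitudeHistogram(bin_edges=edges, counts=counts, n_samples=samples.size)


def _initial_means(hist: AmplitudeHistogram, k: int) -> np.ndarray:
    """Pick k peak locations from the 5-bin-smoothed histogram."""
    smooth = np.convolve(hist.counts.astype(float), np.ones(5) / 5.0, mode="same")
    centers = hist.centers
    interior = (smooth[1:-1] >= smooth[:-2]) & (smooth[1:-1] > smooth[2:])
    peak_idx = np.flatnonzero(interior) + 1
    if len(peak_idx) == 0:
        peak_idx = np.array([int(np.argmax(smooth))])
    # strongest k peaks, then left-to-right
    order = peak_idx[np.argsort(smooth[peak_idx])[::-1][:k]]
    means = np.sort(centers[order])
    if len(means) < k:  # fewer detected peaks than requested: spread the rest
        extra = np.linspace(centers[0], centers[-1], k - len(means) + 2)[1:-1]
        means = np.sort(np.concatenate([means, extra]))[:k]
    return means


def fit_mixture(
    hist: AmplitudeHistogram,
    k: int,
    init_means=None,
    shared_sd: bool = False,
    poisson_weights: bool = False,
) -> MixtureFit:
    """Least-squares fit of a sum of k Gaussians to histogram counts.

    By default raw counts are fit unweighted with independent component
    widths; ``poisson_weights`` weights residuals by 1/sqrt(count) and
    ``shared_sd`` ties all component sds together (both choices are recorded
    on the returned fit).  When ``init_means`` is omitted, starting means
    come from the k highest local maxima of a lightly smoothed histogram.
    The fit is deterministic for fixed inputs; non-convergence is reported
    through ``converged``, never raised.
    """
    if k < 1 or k > 8:
        raise ValueError("k must be in 1..8")
    x = hist.centers
    y = hist.counts.astype(float)
    means0 = np.sort(np.asarray(init_means, dtype=float)) if init_means is not None else _initial_means(hist, k)
    if len(means0) != k:
        raise ValueError("init_means length must equal k")
    sep = np.min(np.diff(means0)) if k > 1 else (x[-1] - x[0])
    sigma0 = max(2.0 * hist.bin_width, 0.2 * sep)

    model = None
    params = None
    for i in range(k):
        g = GaussianModel(prefix=f"g{i}_")
        model = g if model is None else model + g
        p = g.make_params()
        near = np.argmin(np.abs(x - means0[i]))
        height0 = max(y[near], 1.0)
        p[f"g{i}_center"].set(value=means0[i])
        p[f"g{i}_sigma"].set(value=sigma0, min=hist.bin_width / 10.0)
        p[f"g{i}_amplitude"].set(value=height0 * sigma0 * np.sqrt(2 * np.pi), min=0.0)
        params = p if params is None else params.update(p) or params
    if shared_sd:
        for i in range(1, k):
            params[f"g{i}_sigma"].set(expr="g0_sigma")

    weights = 1.0 / np.sqrt(np.maximum(y, 1.0)) if poisson_weights else None
    result = model.fit(y, params, x=x, weights=weights)

    comps = sorted(
        (
            (
                float(result.params[f"g{i}_center"].value),
                float(result.params[f"g{i}_sigma"].value),
                float(result.params[f"g{i}_amplitude"].value),
            )
            for i in range(k)
        ),
        key=lambda c: (c[0], c[1]),
    )
    total_area = sum(c[2] for c in comps)
    degenerate = [i for i, c in enumerate(comps) if total_area > 0 and c[2] < 1e-3 * total_area]
    rss = float(np.sum((result.best_fit - y) ** 2))
    return MixtureFit(
        components=comps,
        k=k,
        rss=rss,
        converged=bool(result.success),
        degenerate=degenerate,
        shared_sd=shared_sd,
    )


def levels_to_conductances(fit: MixtureFit, V: float, e_rev: float) -> np.ndarray:
    """Convert fitted level means to per-level conductances (pS).

    gamma_m = 1000 * (mu_m - mu_0) / (V - E_rev), where mu_0 is the
    component nearest 0 pA (the closed level).  Returns conductances of the
    remaining components in ascending-mean order.
    """
    if V == e_rev:
        raise ValueError("zero driving force: V equals the reversal potential")
    if len(fit.components) < 2:
        raise ValueError("need at least two components (closed + one open)")
    means = fit.means
    closed = int(np.argmin(np.abs(means)))
    mu0 = means[closed]
    open_means = np.delete(means, closed)
    return 1000.0 * (open_means - mu0) / (V - e_rev)
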