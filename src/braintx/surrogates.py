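"""Variogram-matched surrogate maps and empirical spatial p-values.

Surrogates preserve the spatial autocorrelation of an empirical region map
while destroying its specific regional pattern: values are permuted,
re-smoothed with distance-decaying kernels over k nearest neighbours, the
smoothing level is chosen by matching the empirical variogram, and (by
default) the result is rank-remapped onto the original value multiset.
Statistics computed against an ensemble of such maps yield spatial p-values
that are calibrated under spatial autocorrelation, unlike naive parametric
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .atlas import RegionMap

DEFAULT_N_BINS = 25
#: candidate neighbourhood sizes for the smoothing step ("all" = n - 1).
#: A dense grid measurably improves null calibration over a sparse one: the
#: closer the best achievable variogram match, the closer surrogate-based
#: rejection rates sit to the nominal alpha.
DEFAULT_K_GRID = (2, 3, 4, 5, 6, 8, 10, 12, 15, 20, 25, 30, 40, 50, "all")
#: percentile of pairwise distances used when matching variograms during
#: surrogate generation.  Short-range structure dominates spatial inference,
#: but fitting only the shortest quartile leaves long-range smoothness
#: unconstrained and measurably biases null rejection rates; the shortest
#: 40% balances both (rejection at nominal alpha for regression and forest
#: nulls on this geometry).
DEFAULT_FIT_PERCENTILE = 40.0


@dataclass(frozen=True)
class Variogram:
    """Binned semivariance estimate of a region map."""

    bin_centers: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        for name in ("bin_centers", "semivariance", "pair_counts"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.semivariance < 0):
            raise ValueError("semivariance must be non-negative")


@dataclass
class SurrogateEnsemble:
    """A set of variogram-matched surrogate draws for one source map."""

    source_id: str
    source_values: np.ndarray
    surrogates: np.ndarray  # (n_surrogates, n_regions)
    seed: int
    k_chosen: np.ndarray  # (n_surrogates,)
    sse: np.ndarray  # (n_surrogates,) variogram-fit SSE
    resample: bool = True

    def __post_init__(self) -> None:
        self.source_values = np.asarray(self.source_values, dtype=float)
        self.surrogates = np.asarray(self.surrogates, dtype=float)
        if self.surrogates.ndim != 2 or self.surrogates.shape[1] != len(
            self.source_values
        ):
            raise ValueError("surrogates must be (n_surrogates, n_regions)")

    @property
    def n_surrogates(self) -> int:
        return self.surrogates.shape[0]


# ---------------------------------------------------------------------------
# variogram estimation
# ---------------------------------------------------------------------------

def _pair_bins(distmat: np.ndarray, n_bins: int, max_percentile: float = 100.0):
    """Equal-count distance bins over the upper-triangle pairs.

    ``max_percentile`` < 100 restricts the bins to the shortest pairs.
    Returns (iu, ju, order, starts, counts, centers): pair indices, the
    ordering of pairs by distance, and reduceat segment starts per bin.
    """
    n = distmat.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    d = distmat[iu, ju]
    if max_percentile < 100.0:
        keep = d <= np.percentile(d, max_percentile)
        iu, ju, d = iu[keep], ju[keep], d[keep]
    n_pairs = iu.size
    if n_bins > n_pairs:
        raise ValueError(f"n_bins={n_bins} exceeds number of pairs {n_pairs}")
    order = np.argsort(d, kind="stable")
    edges = np.linspace(0, n_pairs, n_bins + 1).astype(int)
    starts = edges[:-1]
    counts = np.diff(edges)
    centers = np.add.reduceat(d[order], starts) / counts
    return iu, ju, order, starts, counts, centers


def compute_variogram(
    region_map: RegionMap | np.ndarray,
    distances: np.ndarray | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> Variogram:
    """Binned semivariance gamma(h) = sum over pairs in bin of
    (x_i - x_j)^2 / (2 N_h), with equal-count distance bins."""
    if isinstance(region_map, RegionMap):
        values = region_map.values
        if distances is None:
            distances = region_map.atlas.distance_matrix
    else:
        values = np.asarray(region_map, dtype=float)
        if distances is None:
            raise ValueError("distances required when passing a bare array")
    if values.size < 2:
        raise ValueError("need at least 2 regions")
    iu, ju, order, starts, counts, centers = _pair_bins(np.asarray(distances), n_bins)
    sq = (values[iu] - values[ju]) ** 2
    gamma = np.add.reduceat(sq[order], starts) / (2.0 * counts)
    return Variogram(centers, gamma, counts)


# ---------------------------------------------------------------------------
# surrogate generation
# ---------------------------------------------------------------------------

def _smoothing_weights(distmat: np.ndarray, k: int) -> np.ndarray:
    """Row-normalized exponential kernel over each region's k nearest
    neighbours (self excluded): w_ij = exp(-d_ij / d_ik)."""
    n = distmat.shape[0]
    W = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(distmat[i], kind="stable")
        nbrs = order[order != i][:k]
        dk = distmat[i, nbrs[-1]]
        if dk <= 0:
            w = np.ones(len(nbrs))
        else:
            w = np.exp(-distmat[i, nbrs] / dk)
        W[i, nbrs] = w / w.sum()
    return W


def generate_surrogates(
    region_map: RegionMap,
    n: int,
    seed: int = 0,
    distances: np.ndarray | None = None,
    n_bins: int = DEFAULT_N_BINS,
    k_grid: Sequence = DEFAULT_K_GRID,
    resample: bool = True,
    source_id: str = "",
    fit_percentile: float = DEFAULT_FIT_PERCENTILE,
) -> SurrogateEnsemble:
    """Generate ``n`` variogram-matched surrogates of ``region_map``.

    Per surrogate: permute the map, smooth with each candidate neighbourhood
    size k, least-squares match the smoothed variogram to the empirical one
    (gamma_emp ~ beta * gamma_smooth + alpha), keep the best k, and emit
    ``sqrt(|beta|) * smoothed + sqrt(|alpha|) * gaussian``.  In resample mode
    (default) surrogate values are rank-remapped onto the source multiset.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    values = region_map.values
    nreg = values.size
    if nreg < 10:
        raise ValueError("need at least 10 regions for surrogate generation")
    if np.unique(values).size < 2:
        raise ValueError("constant input map has no spatial structure to match")
    D = region_map.atlas.distance_matrix if distances is None else np.asarray(distances)

    ks = [nreg - 1 if k == "all" else int(k) for k in k_grid]
    ks = sorted({k for k in ks if 1 <= k <= nreg - 1})

    # variogram matching uses Gaussian-kernel-smoothed estimates at uniform
    # lags over the shortest `fit_percentile`% of pair distances: single-draw
    # binned estimates are too noisy to anchor the least-squares fit
    iu, ju = np.triu_indices(nreg, k=1)
    dpair = D[iu, ju]
    keep = dpair <= np.percentile(dpair, fit_percentile)
    iu, ju, dpair = iu[keep], ju[keep], dpair[keep]
    lags = np.linspace(dpair.min(), dpair.max(), n_bins)
    bw = 3.0 * (lags[1] - lags[0])
    K = np.exp(-0.5 * ((lags[:, None] - dpair[None, :]) / bw) ** 2)
    k_norm = K.sum(axis=1)

    def _smoothed_variogram(rows: np.ndarray) -> np.ndarray:
        diff2 = 0.5 * (rows[:, iu] - rows[:, ju]) ** 2
        return diff2 @ K.T / k_norm

    gamma_emp = _smoothed_variogram(values[None, :])[0]
    weights = [_smoothing_weights(D, k) for k in ks]

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(values, (n, nreg)).copy(), axis=1)

    n_k = len(ks)
    all_sse = np.empty((n_k, n))
    all_alpha = np.empty((n_k, n))
    all_beta = np.empty((n_k, n))
    smoothed_stack = np.empty((n_k, n, nreg))
    for m, W in enumerate(weights):
        S = perms @ W.T  # (n, nreg)
        smoothed_stack[m] = S
        gam = _smoothed_variogram(S)
        # per-row simple regression gamma_emp ~ beta*gam + alpha
        gbar = gam.mean(axis=1)
        ebar = gamma_emp.mean()
        sxx = ((gam - gbar[:, None]) ** 2).sum(axis=1)
        sxy = ((gam - gbar[:, None]) * (gamma_emp - ebar)).sum(axis=1)
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        alpha = ebar - beta * gbar
        resid = gamma_emp[None, :] - (beta[:, None] * gam + alpha[:, None])
        all_sse[m] = (resid**2).sum(axis=1)
        all_alpha[m] = alpha
        all_beta[m] = beta

    best = np.argmin(all_sse, axis=0)
    rows = np.arange(n)
    beta = all_beta[best, rows]
    alpha = all_alpha[best, rows]
    sse = all_sse[best, rows]
    smoothed = smoothed_stack[best, rows]

    noise = rng.standard_normal((n, nreg))
    surr = np.sqrt(np.abs(beta))[:, None] * smoothed + np.sqrt(np.abs(alpha))[
        :, None
    ] * noise

    if resample:
        sorted_vals = np.sort(values)
        ranks = np.argsort(np.argsort(surr, axis=1, kind="stable"), axis=1)
        surr = sorted_vals[ranks]

    return SurrogateEnsemble(
        source_id=source_id or region_map.name,
        source_values=values.copy(),
        surrogates=surr,
        seed=seed,
        k_chosen=np.array(ks)[best],
        sse=sse,
        resample=resample,
    )


# ---------------------------------------------------------------------------
# empirical p-values
# ---------------------------------------------------------------------------

def empirical_pvalue(
    observed: float, nulls: Sequence[float], sided: str = "two"
) -> float:
    """Add-one permutation-style p-value against a null sample.

    two-sided: (1 + #{|null| >= |obs|}) / (1 + N); one-sided ("greater"):
    (1 + #{null >= obs}) / (1 + N).
    """
    observed = float(observed)
    if not np.isfinite(observed):
        raise ValueError("observed statistic must be finite")
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size < 1:
        raise ValueError("need at least one null value")
    if sided == "two":
        count = int(np.sum(np.abs(nulls) >= abs(observed)))
    elif sided in ("one", "greater"):
        count = int(np.sum(nulls >= observed))
    elif sided == "less":
        count = int(np.sum(nulls <= observed))
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return (1 + count) / (1 + nulls.size)
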