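"""Weighted Histogram Analysis Method: rebuild the unbiased free-energy
profile W(ξ) from the per-window biased histograms, plus the direct
Boltzmann-inversion PMF and window-overlap diagnostics.

The self-consistent equations solved here are the standard ones: with
per-bin counts n_i(b), totals N_i and bias factors c_i(b) = exp(−V_i(ξ_b)/kBT),

    ρ(b)          = Σ_i n_i(b) / Σ_i N_i exp(f_i/kBT) c_i(b)
    exp(−f_i/kBT) = Σ_b ρ(b) c_i(b) Δξ

iterated from f_i = 0 until no bin free energy W(b) = −kBT ln ρ(b) changes
by more than the tolerance between consecutive iterations.  Windows are
weighted by their actual sample counts N_i.  All energies kcal/mol.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, kbt
from .synthetic import WindowSamples, WindowSpec

__all__ = [
    "HistogramSet",
    "FreeEnergyProfile",
    "WhamError",
    "WhamNonConvergence",
    "build_histograms",
    "wham_solve",
    "pmf_from_distribution",
    "overlap_matrix",
    "low_overlap_pairs",
]

logger = logging.getLogger(__name__)


class WhamError(ValueError):
    """Invalid histogram/window input."""


class WhamNonConvergence(RuntimeError):
    """Iteration budget exhausted before reaching the tolerance."""

    def __init__(self, n_iter: int, residual: float, tol: float):
        self.n_iter = n_iter
        self.residual = residual
        self.tol = tol
        super().__init__(
            f"WHAM did not converge in {n_iter} iterations: "
            f"max |ΔW| = {residual:.3e} > tol = {tol:.3e} kcal/mol")


@dataclass
class HistogramSet:
    """Per-window counts on a shared reaction-coordinate grid.

    ``counts`` has shape (n_windows, n_bins); float entries are allowed so
    that exact expected counts N_i·p_i(b) can be used as idealized input.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    totals: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        self.totals = np.asarray(self.totals, dtype=float)
        if not np.all(np.diff(self.bin_edges) > 0):
            raise WhamError("bin edges must be strictly increasing")
        if self.counts.shape != (len(self.totals), len(self.bin_edges) - 1):
            raise WhamError("counts shape does not match edges/totals")
        if np.any(self.counts < 0):
            raise WhamError("negative counts")
        if not np.allclose(self.counts.sum(axis=1), self.totals):
            raise WhamError("per-window counts do not sum to the totals")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]


@dataclass
class FreeEnergyProfile:
    """Binned free-energy profile W(ξ), minimum over defined bins at zero.

    ``F`` is NaN outside ``defined_mask`` (bins with no aggregate density).
    ``window_offsets`` are the converged WHAM constants f_i (kcal/mol) when
    the profile came from :func:`wham_solve`.
    """

    xi_grid: np.ndarray
    F: np.ndarray
    defined_mask: np.ndarray
    window_offsets: np.ndarray | None = None
    n_iter: int = 0
    residual: float = 0.0

    def __post_init__(self):
        self.xi_grid = np.asarray(self.xi_grid, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)


def build_histograms(samples: list[WindowSamples], n_bins: int = 1000,
                     range: tuple[float, float] | None = None) -> HistogramSet:
    """Histogram every window's ξ series on one shared grid.

    The default grid spans [min sample − ε, max sample + ε].  With an
    explicit ``range``, a sample falling outside raises, naming the window.
    """
    if not samples:
        raise WhamError("no windows given")
    if n_bins < 1:
        raise WhamError("n_bins must be >= 1")
    eps = 1e-9
    if range is None:
        lo = min(float(s.xi.min()) for s in samples) - eps
        hi = max(float(s.xi.max()) for s in samples) + eps
    else:
        lo, hi = map(float, range)
        for s in samples:
            if s.xi.min() < lo or s.xi.max() > hi:
                raise WhamError(
                    f"window {s.spec.index}: samples outside histogram "
                    f"range [{lo}, {hi}]")
    edges = np.linspace(lo, hi, n_bins + 1)
    counts = np.vstack([np.histogram(s.xi, bins=edges)[0] for s in samples])
    totals = np.array([s.xi.size for s in samples], dtype=float)
    temperature = samples[0].temperature
    return HistogramSet(bin_edges=edges, counts=counts.astype(float),
                        totals=totals, temperature=temperature)


def wham_solve(hist: HistogramSet, windows: list[WindowSpec],
               tol: float = 1e-6, max_iter: int = 200_000) -> FreeEnergyProfile:
    """Self-consistent WHAM solution of ``hist`` under ``windows`` biases.

    Convergence is declared when the largest absolute change of any defined
    bin's free energy between consecutive iterations is ≤ ``tol`` (kcal/mol).
    Empty aggregate bins are masked out of the profile, never an error.

    Raises
    ------
    WhamNonConvergence
        If ``max_iter`` iterations do not reach ``tol``.
    """
    if len(windows) != hist.n_windows:
        raise WhamError(
            f"{len(windows)} window specs for {hist.n_windows} histograms")
    kt = kbt(hist.temperature)
    centers = hist.bin_centers
    width = hist.bin_width
    # Log bias weights -V_i(xi_b)/kBT, shape (n_windows, n_bins).  The whole
    # iteration runs in log space: per-window offsets span many kBT, so the
    # plain exponential form overflows.
    log_bias = np.vstack(
        [-0.5 * w.k * (centers - w.xi) ** 2 for w in windows]) / kt

    agg = hist.counts.sum(axis=0)
    defined = agg > 0
    log_agg = np.where(defined, np.log(agg, where=defined,
                                       out=np.zeros_like(agg)), -np.inf)
    log_n = np.log(hist.totals)
    g = np.zeros(len(windows))  # f_i / kBT

    w_old = None
    n_iter = 0
    residual = np.inf
    for n_iter in range(1, max_iter + 1):
        log_denom = logsumexp(log_bias + (log_n + g)[:, None], axis=0)
        log_rho = log_agg - log_denom
        g = -(logsumexp(log_bias + log_rho[None, :], axis=1) + np.log(width))
        g -= g[0]  # fix the additive gauge: f_1 = 0
        w = -kt * log_rho[defined]
        if w_old is not None:
            residual = float(np.max(np.abs(w - w_old)))
            if residual <= tol:
                break
        w_old = w
    else:
        raise WhamNonConvergence(max_iter, residual, tol)

    logger.info("WHAM converged in %d iterations (max |ΔW| = %.3e kcal/mol)",
                n_iter, residual)
    f = np.full(len(centers), np.nan)
    f[defined] = w - w.min()
    offsets = kt * g
    return FreeEnergyProfile(xi_grid=centers, F=f, defined_mask=defined,
                             window_offsets=offsets, n_iter=n_iter,
                             residual=residual)


def pmf_from_distribution(xi_grid: np.ndarray, g: np.ndarray,
                          temperature: float = DEFAULT_TEMPERATURE) -> FreeEnergyProfile:
    """Direct Boltzmann inversion W(ξ) = −kBT ln g(ξ), minimum shifted to 0.

    ``g`` is a (non-negative) density over the grid; zero-density bins are
    undefined in the output.
    """
    xi_grid = np.asarray(xi_grid, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise WhamError("distribution has negative entries")
    if not np.any(g > 0):
        raise WhamError("distribution is identically zero")
    defined = g > 0
    w = np.full(g.shape, np.nan)
    with np.errstate(divide="ignore"):
        w[defined] = -kbt(temperature) * np.log(g[defined])
    w[defined] -= w[defined].min()
    return FreeEnergyProfile(xi_grid=xi_grid, F=w, defined_mask=defined)


def overlap_matrix(hist: HistogramSet) -> np.ndarray:
    """Pairwise overlap coefficients OVL(i,j) = Σ_b min(p_i(b), p_j(b))."""
    if hist.n_windows < 2:
        raise WhamError("overlap needs at least two windows")
    p = hist.counts / hist.totals[:, None]
    n = hist.n_windows
    ovl = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ovl[i, j] = ovl[j, i] = float(np.minimum(p[i], p[j]).sum())
        ovl[i, i] = float(np.minimum(p[i], p[i]).sum())
    return ovl


def low_overlap_pairs(ovl: np.ndarray, windows: list[WindowSpec],
                      threshold: float = 0.05) -> list[tuple[int, int, float]]:
    """Adjacent-window pairs (sorted by restraint center) whose overlap
    coefficient falls below ``threshold``; each entry is
    (window index i, window index j, OVL)."""
    order = sorted(range(len(windows)), key=lambda i: windows[i].xi)
    flagged = []
    for u, v in zip(order[:-1], order[1:]):
        if ovl[u, v] < threshold:
            flagged.append((windows[u].index, windows[v].index, float(ovl[u, v])))
    return flagged
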