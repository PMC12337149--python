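"""Markov state model on a 1-D coordinate and stationary-reweighted free energy.

Many short trajectories sample a slow coordinate (here the bottleneck
distance) without individually reaching equilibrium.  Discretizing the
coordinate into bins, counting transitions at a lag time, and estimating a
(reversible) transition matrix yields a stationary distribution π that
reweights the pooled data into equilibrium populations; the free-energy
landscape follows as ΔG_i = −k_B T ln π_i, shifted so the global minimum
is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eig
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "MarkovModel",
    "FreeEnergyLandscape",
    "discretize",
    "count_matrix",
    "transition_matrix",
    "stationary_distribution",
    "implied_timescales",
    "reweighted_fel",
    "choose_lag",
    "MarkovStateModel",
]

KB_KCAL = 0.0019872041  # kcal/(mol K)


@dataclass
class MarkovModel:
    bin_edges: np.ndarray
    lag_frames: int
    lag_ns: float
    count_matrix: np.ndarray  # on the active set
    transition_matrix: np.ndarray
    stationary: np.ndarray
    active_set: np.ndarray  # bin indices retained (largest connected set)


@dataclass
class FreeEnergyLandscape:
    bin_centers: np.ndarray  # Å, active set
    delta_g_kt: np.ndarray  # kT, min = 0 (inf for empty bins)
    delta_g_kcal: np.ndarray  # kcal/mol
    temperature: float
    stationary: np.ndarray = field(default=None)


def discretize(values, bin_edges=None, n_bins: int = 40):
    """Map a scalar series to bin indices; out-of-range frames go to the
    nearest edge bin.  ``bin_edges`` must be strictly increasing; when absent
    ``n_bins`` equal-width bins span the observed range."""
    values = np.asarray(getattr(values, "distances", values), dtype=float)
    if bin_edges is None:
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        bin_edges = np.linspace(values.min(), values.max(), n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or len(bin_edges) < 3:
        raise ValueError("need at least 2 bins (3 edges)")
    if not np.all(np.diff(bin_edges) > 0):
        raise ValueError("bin_edges must be strictly increasing")
    states = np.digitize(values, bin_edges) - 1
    return np.clip(states, 0, len(bin_edges) - 2)


def count_matrix(state_sequences, lag: int, n_states: int | None = None):
    """Sliding-window transition counts at ``lag`` frames.

    ``state_sequences`` is one sequence or a list of sequences; counts never
    cross trajectory boundaries.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    seqs = state_sequences
    if np.ndim(seqs[0]) == 0:
        seqs = [seqs]
    seqs = [np.asarray(s, dtype=int) for s in seqs]
    usable = [s for s in seqs if len(s) > lag]
    if not usable:
        raise ValueError(f"all sequences are shorter than lag+1 = {lag + 1}")
    if n_states is None:
        n_states = int(max(s.max() for s in seqs)) + 1
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    for s in usable:
        np.add.at(counts, (s[:-lag], s[lag:]), 1)
    return counts


def largest_connected_set(counts) -> np.ndarray:
    """Indices of the largest strongly connected set of the count graph."""
    adjacency = csr_matrix((counts > 0).astype(np.int8))
    n_comp, labels = connected_components(adjacency, connection="strong")
    sizes = np.bincount(labels)
    # tie-break: component with the most counts
    best, best_counts = 0, -1
    for c in np.flatnonzero(sizes == sizes.max()):
        members = np.flatnonzero(labels == c)
        total = counts[np.ix_(members, members)].sum()
        if total > best_counts:
            best, best_counts = c, total
    return np.flatnonzero(labels == best)


def transition_matrix(
    counts, reversible: bool = True, pseudocount: float = 0.0
):
    """Row-stochastic transition matrix on the largest connected set.

    Reversible estimation symmetrizes the counts, (C + Cᵀ)/2, before row
    normalization, which enforces detailed balance by construction — adequate
    for a 1-D coordinate sampled at equilibrium.  Returns
    ``(T, active_set, restricted_counts)``.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    active = largest_connected_set(counts)
    if len(active) == 0:
        raise ValueError("empty connected set: no transitions observed")
    sub = counts[np.ix_(active, active)] + pseudocount
    if reversible:
        sub_eff = 0.5 * (sub + sub.T)
    else:
        sub_eff = sub
    rows = sub_eff.sum(axis=1)
    if np.any(rows == 0):
        raise ValueError("zero-count row inside the connected set")
    T = sub_eff / rows[:, None]
    return T, active, counts[np.ix_(active, active)].astype(np.int64)


def stationary_distribution(T) -> np.ndarray:
    """Left Perron eigenvector of a row-stochastic matrix, normalized to 1."""
    T = np.asarray(T, dtype=float)
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("transition matrix rows must sum to 1")
    comp_n, labels = connected_components(
        csr_matrix((T > 0).astype(np.int8)), connection="strong"
    )
    if comp_n > 1:
        blocks = [list(np.flatnonzero(labels == c)) for c in range(comp_n)]
        raise ValueError(
            f"transition matrix is reducible; disconnected blocks: {blocks}"
        )
    vals, vecs = eig(T, left=True, right=False)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    pi = pi / pi.sum()
    return pi


def implied_timescales(T, lag: float = 1.0) -> np.ndarray:
    """Relaxation timescales t_i = −lag / ln λ_i for eigenvalues below 1.

    Eigenvalues are sorted by decreasing real part; the stationary eigenvalue
    λ₁ = 1 is excluded.  λ → 1 maps to +inf; non-positive eigenvalues (no
    real timescale at this lag) map to NaN.  Complex parts beyond tolerance
    trigger a warning and the real part is used.
    """
    vals = np.linalg.eigvals(np.asarray(T, dtype=float))
    if np.any(np.abs(vals.imag) > 1e-8):
        warnings.warn(
            "complex transition-matrix eigenvalues; using real parts",
            stacklevel=2,
        )
    lam = np.sort(vals.real)[::-1][1:]  # drop the stationary eigenvalue
    out = np.full(lam.shape, np.nan)
    out[lam >= 1.0] = np.inf
    pos = (lam > 0) & (lam < 1.0)
    out[pos] = -lag / np.log(lam[pos])
    return out


def reweighted_fel(
    pi, bin_centers, temperature: float = 300.0
) -> FreeEnergyLandscape:
    """Free-energy landscape ΔG_i = −k_B T ln π_i, minimum shifted to zero.

    Zero-probability bins get +inf and are excluded from the minimum.
    Energies are reported both in kT and in kcal/mol at ``temperature``.
    """
    pi = np.asarray(pi, dtype=float)
    centers = np.asarray(bin_centers, dtype=float)
    with np.errstate(divide="ignore"):
        g = -np.log(pi)
    g = g - g[np.isfinite(g)].min()
    return FreeEnergyLandscape(
        bin_centers=centers,
        delta_g_kt=g,
        delta_g_kcal=g * KB_KCAL * temperature,
        temperature=float(temperature),
        stationary=pi,
    )


def choose_lag(state_sequences, lags=None, rel_tol: float = 0.10):
    """Smallest lag whose slowest implied timescale is lag-stable.

    Scans candidate lags and returns the first whose t₂ changes by less than
    ``rel_tol`` (relative) when the lag doubles — a plateau criterion for
    Markovianity.  Falls back to the last candidate when no plateau is found.
    """
    if lags is None:
        lags = [1, 2, 4, 8, 16, 32]
    lags = sorted(set(int(l) for l in lags))

    def t2(lag):
        counts = count_matrix(state_sequences, lag)
        T, _, _ = transition_matrix(counts, reversible=True)
        ts = implied_timescales(T, lag=lag)
        return ts[0] if len(ts) else np.nan

    for lag in lags:
        t_here, t_double = t2(lag), t2(2 * lag)
        if (
            np.isfinite(t_here)
            and np.isfinite(t_double)
            and abs(t_double - t_here) <= rel_tol * t_here
        ):
            return lag
    return lags[-1]


class MarkovStateModel:
    """Convenience estimator bundling discretization, counting and the FEL.

    Parameters mirror the module functions: ``n_bins`` equal-width bins over
    the pooled observed range, ``lag`` in frames (or "auto" for the implied-
    timescale plateau heuristic), reversible estimation by count
    symmetrization, temperature for the kcal/mol scale.
    """

    def __init__(
        self,
        n_bins: int = 40,
        lag="auto",
        reversible: bool = True,
        pseudocount: float = 0.0,
        temperature: float = 300.0,
    ):
        self.n_bins = n_bins
        self.lag = lag
        self.reversible = reversible
        self.pseudocount = pseudocount
        self.temperature = temperature

    def fit(self, series_list, timestep_ns: float = 1.0):
        """Estimate the MSM from one or more scalar series (Å)."""
        arrays = [
            np.asarray(getattr(s, "distances", s), dtype=float)
            for s in (series_list if isinstance(series_list, (list, tuple)) else [series_list])
        ]
        pooled = np.concatenate(arrays)
        edges = np.linspace(pooled.min(), pooled.max(), self.n_bins + 1)
        seqs = [discretize(a, bin_edges=edges) for a in arrays]
        lag = (
            choose_lag(seqs)
            if isinstance(self.lag, str) and self.lag == "auto"
            else int(self.lag)
        )
        counts = count_matrix(seqs, lag, n_states=self.n_bins)
        T, active, sub_counts = transition_matrix(
            counts, reversible=self.reversible, pseudocount=self.pseudocount
        )
        pi = stationary_distribution(T)
        self.model_ = MarkovModel(
            bin_edges=edges,
            lag_frames=lag,
            lag_ns=lag * timestep_ns,
            count_matrix=sub_counts,
            transition_matrix=T,
            stationary=pi,
            active_set=active,
        )
        centers = 0.5 * (edges[:-1] + edges[1:])
        self.fel_ = reweighted_fel(
            pi, centers[active], temperature=self.temperature
        )
        self.timescales_ = implied_timescales(T, lag=lag * timestep_ns)
        return self
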