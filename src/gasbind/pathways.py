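"""Tunnel representation, event→pathway assignment, and symmetry testing.

Tunnels are ordered chains of spheres from the buried site to the protein
surface, as produced by tunnel-detection tools (CAVER-style PDB sphere
records, cluster id in the residue-number field, radius in the B-factor
field).  Each (un)binding event is assigned to the tunnel whose sphere chain
best matches the event's surface-crossing trace; pathway probabilities carry
bootstrap standard errors, and binding/unbinding symmetry (expected at
equilibrium from detailed balance) is tested with a two-sample chi-square
test with small-count pooling and a Monte-Carlo fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UNASSIGNED",
    "Tunnel",
    "PathwayDistribution",
    "SymmetryTestResult",
    "load_tunnels",
    "write_tunnels",
    "assign_event",
    "assign_events",
    "merge_assignments",
    "pathway_distribution",
    "chi_square_compare",
]

UNASSIGNED = "unassigned"


@dataclass
class Tunnel:
    """An ordered chain of spheres (centers Å, radii Å) from site to surface."""

    id: str
    centers: np.ndarray
    radii: np.ndarray

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if len(self.centers) < 2:
            raise ValueError(f"tunnel {self.id}: needs at least 2 spheres")
        if len(self.centers) != len(self.radii):
            raise ValueError(f"tunnel {self.id}: centers/radii length mismatch")
        if np.any(self.radii <= 0):
            raise ValueError(f"tunnel {self.id}: radii must be positive")


def _tunnel_sort_key(tid: str):
    digits = "".join(c for c in tid if c.isdigit())
    return (tid[: len(tid) - len(digits)], int(digits) if digits else -1)


def load_tunnels(path, site_anchor=None) -> list:
    """Parse a CAVER-style sphere file into tunnels ordered site-first.

    One ATOM/HETATM record per sphere; the residue-number field carries the
    tunnel cluster id and the B-factor field the sphere radius.  When
    ``site_anchor`` (Å) is given, each tunnel's spheres are sorted by
    distance from it so the chain runs site → surface.
    """
    clusters: dict[int, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                cluster = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                radius = float(line[60:66])
            except (ValueError, IndexError) as err:
                raise ValueError(
                    f"{path}: malformed sphere record at line {lineno}"
                ) from err
            clusters.setdefault(cluster, []).append((x, y, z, radius))
    if not clusters:
        raise ValueError(f"{path}: no tunnel sphere records found")
    tunnels = []
    for cluster in sorted(clusters):
        arr = np.array(clusters[cluster])
        centers, radii = arr[:, :3], arr[:, 3]
        if site_anchor is not None:
            order = np.argsort(
                np.linalg.norm(centers - np.asarray(site_anchor, float), axis=1),
                kind="stable",
            )
            centers, radii = centers[order], radii[order]
        tunnels.append(Tunnel(id=f"T{cluster}", centers=centers, radii=radii))
    return tunnels


def write_tunnels(tunnels, path):
    """Write tunnels in the same sphere-record dialect read by load_tunnels."""
    serial = 0
    with open(path, "w") as fh:
        for tunnel in tunnels:
            cluster = int("".join(c for c in tunnel.id if c.isdigit()))
            for center, radius in zip(tunnel.centers, tunnel.radii):
                serial += 1
                fh.write(
                    f"ATOM  {serial:5d}  H   FIL T{cluster:4d}    "
                    f"{center[0]:8.3f}{center[1]:8.3f}{center[2]:8.3f}"
                    f"{1.0:6.2f}{radius:6.3f}\n"
                )


def _trace_score(trace: np.ndarray, tunnel: Tunnel) -> float:
    """Mean surface-excess distance of trace points to the tunnel spheres.

    Per point: distance to the nearest sphere center minus that sphere's
    radius, floored at zero; a point inside any nearest sphere scores 0.
    """
    d = np.linalg.norm(
        trace[:, None, :] - tunnel.centers[None, :, :], axis=-1
    )
    nearest = np.argmin(d, axis=1)
    excess = d[np.arange(len(trace)), nearest] - tunnel.radii[nearest]
    return float(np.clip(excess, 0.0, None).mean())


def assign_event(trace, tunnels, max_assign_dist: float = 3.0) -> str:
    """Tunnel id best matching a crossing trace, or "unassigned".

    The winning tunnel minimizes the mean surface-excess distance of the
    trace to its sphere chain; if even the best score exceeds
    ``max_assign_dist`` (Å) the event is left unassigned for human review.
    Ties are broken by tunnel id order.
    """
    trace = np.atleast_2d(np.asarray(trace, dtype=float))
    if trace.size == 0:
        raise ValueError("empty crossing trace")
    if not tunnels:
        raise ValueError("empty tunnel list")
    ordered = sorted(tunnels, key=lambda t: _tunnel_sort_key(t.id))
    scores = [_trace_score(trace, t) for t in ordered]
    best = int(np.argmin(scores))  # first minimum: id-order tie-break
    if scores[best] <= max_assign_dist:
        return ordered[best].id
    return UNASSIGNED


def assign_events(events, tunnels, max_assign_dist: float = 3.0):
    """Assign every event with a usable crossing trace; sets ``event.pathway``.

    Events without a trace, or whose trace never crosses the surface, are
    labeled "unassigned".
    """
    from .labeling import surface_crossing_point

    assignments = []
    for event in events:
        if event.crossing_trace is None or len(event.crossing_trace) == 0:
            event.pathway = UNASSIGNED
        else:
            crossing_ok = True
            if event.crossing_outside is not None:
                crossing_ok = surface_crossing_point(event) is not None
            event.pathway = (
                assign_event(event.crossing_trace, tunnels, max_assign_dist)
                if crossing_ok
                else UNASSIGNED
            )
        assignments.append(event.pathway)
    return assignments


def merge_assignments(assignments, merge_map):
    """Apply a user-supplied tunnel merge map (e.g. {"T2": "T1"})."""
    return [merge_map.get(a, a) for a in assignments]


@dataclass
class PathwayDistribution:
    """Event counts and probabilities per tunnel id (plus "unassigned")."""

    categories: list
    counts: np.ndarray
    probabilities: np.ndarray
    standard_errors: np.ndarray
    n_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway": self.categories,
                "count": self.counts,
                "probability": self.probabilities,
                "bootstrap_se": self.standard_errors,
            }
        )

    def as_dict(self) -> dict:
        return dict(zip(self.categories, self.counts))


def pathway_distribution(
    assignments,
    n_boot: int = 1000,
    seed: int | None = None,
    categories=None,
) -> PathwayDistribution:
    """Pathway probabilities with bootstrap standard errors.

    ``categories`` fixes the category order (tunnel ids plus "unassigned");
    by default the ids observed in the assignments, id-sorted, with
    "unassigned" last.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("no assignments")
    if categories is None:
        ids = sorted(
            {a for a in assignments if a != UNASSIGNED}, key=_tunnel_sort_key
        )
        categories = ids + ([UNASSIGNED] if UNASSIGNED in assignments else [])
    categories = list(categories)
    index = {c: i for i, c in enumerate(categories)}
    codes = np.array([index[a] for a in assignments])
    n = len(codes)
    k = len(categories)
    counts = np.bincount(codes, minlength=k)
    probs = counts / n

    rng = np.random.default_rng(seed)
    resamples = rng.integers(0, n, size=(n_boot, n))
    boot = np.stack(
        [np.bincount(codes[row], minlength=k) / n for row in resamples]
    )
    ses = boot.std(axis=0, ddof=1)
    return PathwayDistribution(
        categories=categories,
        counts=counts,
        probabilities=probs,
        standard_errors=ses,
        n_events=n,
    )


@dataclass
class SymmetryTestResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float
    pooled_categories: list = field(default_factory=list)
    method: str = "asymptotic"


def _chi2_statistic(table: np.ndarray) -> float:
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (table - expected) ** 2 / expected
    return float(np.nansum(terms))


def chi_square_compare(
    counts_a,
    counts_b,
    min_expected: float = 5.0,
    mc_replicates: int = 100_000,
    seed: int | None = None,
) -> SymmetryTestResult:
    """Two-sample chi-square homogeneity test with pooling and MC fallback.

    ``counts_a`` and ``counts_b`` are mappings category → count over the same
    category set (e.g. binding vs unbinding counts per tunnel).  Categories
    whose expected count under homogeneity falls below ``min_expected`` are
    pooled into "other"; if an expected count below the threshold remains
    after pooling, the p-value is computed by seeded Monte-Carlo resampling
    from the pooled null instead of the asymptotic χ² distribution.
    """
    if set(counts_a) != set(counts_b):
        raise ValueError("count vectors must share the same category set")
    cats = sorted(counts_a, key=_tunnel_sort_key)
    a = np.array([counts_a[c] for c in cats], dtype=float)
    b = np.array([counts_b[c] for c in cats], dtype=float)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both samples need a positive total count")

    # drop categories empty in both samples, then pool small-expected ones
    keep = (a + b) > 0
    cats = [c for c, k in zip(cats, keep) if k]
    a, b = a[keep], b[keep]

    def expected(table):
        return np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()

    table = np.vstack([a, b])
    exp = expected(table)
    small = exp.min(axis=0) < min_expected
    pooled_categories = list(cats)
    # pool the small-expected categories together, but never collapse the
    # table below 2 categories; if everything is small, fall through to MC
    if small.sum() > 1 and (~small).any():
        pooled_categories = [c for c, s in zip(cats, small) if not s] + ["other"]
        merged_a = np.concatenate([a[~small], [a[small].sum()]])
        merged_b = np.concatenate([b[~small], [b[small].sum()]])
        table = np.vstack([merged_a, merged_b])
        exp = expected(table)

    k = table.shape[1]
    if k < 2:
        return SymmetryTestResult(
            statistic=0.0,
            degrees_of_freedom=0,
            p_value=1.0,
            pooled_categories=pooled_categories,
            method="degenerate",
        )
    stat = _chi2_statistic(table)
    dof = k - 1

    if exp.min() >= min_expected:
        p = float(stats.chi2.sf(stat, dof)) if stat > 0 else 1.0
        method = "asymptotic"
    else:
        rng = np.random.default_rng(seed)
        n_a, n_b = int(table[0].sum()), int(table[1].sum())
        total = n_a + n_b
        null_p = table.sum(axis=0) / total
        draws_a = rng.multinomial(n_a, null_p, size=mc_replicates).astype(float)
        draws_b = rng.multinomial(n_b, null_p, size=mc_replicates).astype(float)
        cols = draws_a + draws_b
        exp_a = n_a * cols / total
        exp_b = n_b * cols / total
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = (draws_a - exp_a) ** 2 / exp_a + (draws_b - exp_b) ** 2 / exp_b
        null_stats = np.nansum(terms, axis=1)
        exceed = int(np.sum(null_stats >= stat - 1e-12))
        p = (1 + exceed) / (mc_replicates + 1)
        method = "monte_carlo"
    return SymmetryTestResult(
        statistic=stat,
        degrees_of_freedom=dof,
        p_value=float(p),
        pooled_categories=pooled_categories,
        method=method,
    )
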