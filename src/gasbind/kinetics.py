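"""Association/dissociation rate constants from (un)binding event statistics.

The association rate constant follows from the mean first-passage time (FPT)
of the binding events and the ligand concentration in the simulation box,

    k_on = 1 / (<FPT> * C),

and the dissociation rate constant from the mean residence time,

    k_off = 1 / <residence>.

Uncertainties come from a seeded bootstrap over events; the experimental
reference rate is derived from Michaelis–Menten constants as k_cat / K_m.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.constants import Avogadro

__all__ = [
    "KineticsEstimate",
    "ExperimentalReference",
    "ligand_concentration",
    "estimate_kon",
    "estimate_koff",
    "experimental_kon",
    "bootstrap_se",
    "bootstrap_interval",
    "kon_interval",
]

NS_TO_S = 1e-9
NM3_TO_L = 1e-24


@dataclass
class KineticsEstimate:
    """A rate constant with its bootstrap standard error.

    ``rate`` is in 1/(M s) for k_on and 1/s for k_off; ``mean_passage`` is
    the mean FPT or residence time in ns; ``concentration`` (mol/L) is set
    for k_on only.
    """

    kind: str  # "k_on" | "k_off"
    rate: float
    standard_error: float
    n_events: int
    mean_passage: float
    concentration: float | None = None

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class ExperimentalReference:
    K_m: float  # mol/L
    k_cat: float  # 1/s
    derived_k_on: float  # 1/(M s)


def ligand_concentration(n_ligands: int, box_volume: float) -> float:
    """Molar concentration of ``n_ligands`` copies in a box of ``box_volume`` nm³."""
    if n_ligands < 1:
        raise ValueError("n_ligands must be >= 1")
    if box_volume <= 0:
        raise ValueError("box_volume must be positive")
    return n_ligands / (Avogadro * box_volume * NM3_TO_L)


def bootstrap_se(values, statistic, n_boot: int = 1000, seed: int | None = None):
    """Bootstrap standard error of ``statistic`` over an event sample."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    replicates = np.array([statistic(values[row]) for row in idx])
    return float(replicates.std(ddof=1)), replicates


def bootstrap_interval(
    values,
    statistic,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
):
    """Percentile bootstrap confidence interval for ``statistic``."""
    _, replicates = bootstrap_se(values, statistic, n_boot=n_boot, seed=seed)
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(replicates, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def kon_interval(
    fpts,
    concentration: float,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
):
    """Percentile bootstrap interval for k_on over binding events."""
    fpts = np.asarray(fpts, dtype=float)
    return bootstrap_interval(
        fpts,
        lambda s: 1.0 / (s.mean() * NS_TO_S * concentration),
        n_boot=n_boot,
        seed=seed,
        level=level,
    )


def estimate_kon(
    fpts, concentration: float, n_boot: int = 1000, seed: int | None = None
) -> KineticsEstimate:
    """k_on = 1 / (<FPT> * C) with a bootstrap SE over binding events.

    ``fpts`` in ns, ``concentration`` in mol/L; the rate is returned in
    M⁻¹ s⁻¹.
    """
    fpts = np.asarray(fpts, dtype=float)
    if fpts.size == 0:
        raise ValueError("no events: cannot estimate k_on from an empty sample")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    mean_fpt = float(fpts.mean())
    rate = 1.0 / (mean_fpt * NS_TO_S * concentration)

    def stat(sample):
        return 1.0 / (sample.mean() * NS_TO_S * concentration)

    se = 0.0
    if fpts.size > 1:
        se, _ = bootstrap_se(fpts, stat, n_boot=n_boot, seed=seed)
    return KineticsEstimate(
        kind="k_on",
        rate=rate,
        standard_error=se,
        n_events=int(fpts.size),
        mean_passage=mean_fpt,
        concentration=float(concentration),
    )


def estimate_koff(
    residence_times, n_boot: int = 1000, seed: int | None = None
) -> KineticsEstimate:
    """k_off = 1 / <residence time> with a bootstrap SE over unbinding events."""
    residences = np.asarray(residence_times, dtype=float)
    if residences.size == 0:
        raise ValueError("no events: cannot estimate k_off from an empty sample")
    mean_res = float(residences.mean())
    rate = 1.0 / (mean_res * NS_TO_S)

    def stat(sample):
        return 1.0 / (sample.mean() * NS_TO_S)

    se = 0.0
    if residences.size > 1:
        se, _ = bootstrap_se(residences, stat, n_boot=n_boot, seed=seed)
    return KineticsEstimate(
        kind="k_off",
        rate=rate,
        standard_error=se,
        n_events=int(residences.size),
        mean_passage=mean_res,
    )


def experimental_kon(K_m: float, k_cat: float, formula=None) -> ExperimentalReference:
    """Reference association rate from Michaelis–Menten constants.

    By default k_on ≈ k_cat / K_m, the diffusion-limited reading of the
    Michaelis constant; ``formula`` may supply an alternative callable
    (K_m, k_cat) -> k_on.
    """
    if K_m <= 0 or k_cat <= 0:
        raise ValueError("K_m and k_cat must be positive")
    rate = (k_cat / K_m) if formula is None else float(formula(K_m, k_cat))
    return ExperimentalReference(K_m=K_m, k_cat=k_cat, derived_k_on=rate)
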