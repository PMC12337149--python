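"""Synthetic Brownian-dynamics generator with recorded ground truth.

The toy system emulates the statistical structure of unbiased-MD gas-ligand
(un)binding data: many identical ligand copies diffusing in a periodic box, a
spherical protein exclusion volume pierced by a small number of cylindrical
channels that lead to a buried binding site, and a bimodal two-state distance
coordinate with Markovian switching (a stand-in for a gating-bottleneck
distance).  Every binding/unbinding transit is recorded together with the
channel used, so downstream event extraction, kinetics and pathway assignment
can be checked against exact ground truth.

Internal units are nm and ns; the analysis-facing helpers convert to Å, the
unit used throughout the labeling/pathway layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ToySystem",
    "GroundTruthEvent",
    "SyntheticTrajectory",
    "TwoStateSeries",
    "simulate_ligand_diffusion",
    "generate_two_state_series",
    "label_toy_trajectory",
    "ground_truth_passage_times",
    "write_trajectory",
    "load_ground_truth",
]

NM_TO_ANG = 10.0


@dataclass(frozen=True)
class ToySystem:
    """Geometry and dynamics parameters of the toy (un)binding system.

    Parameters
    ----------
    box_edge : float
        Edge of the cubic periodic box (nm).
    protein_center : ndarray shape (3,)
        Center of the spherical protein exclusion volume (nm).
    protein_radius : float
        Radius of the exclusion sphere (nm); must be < box_edge / 2.
    channels : list of (axis, radius)
        Each channel is a cylinder of the given radius (nm) around a ray from
        the protein center along the unit vector ``axis``.
    site_radius : float
        Radius of the buried binding-site sphere at the protein center (nm).
    diffusion_coeff : float
        Ligand diffusion coefficient (nm^2/ns).  The default 4.5 is the
        magnitude of H2 diffusion in water at room temperature.
    timestep : float
        Integration step (ns).
    """

    box_edge: float = 6.0
    protein_center: np.ndarray = field(
        default_factory=lambda: np.array([3.0, 3.0, 3.0])
    )
    protein_radius: float = 1.3
    channels: tuple = (
        (np.array([1.0, 0.0, 0.0]), 0.5),
        (np.array([-1.0, 0.0, 0.0]), 0.5),
    )
    site_radius: float = 0.45
    diffusion_coeff: float = 4.5
    timestep: float = 0.004

    def __post_init__(self):
        object.__setattr__(
            self, "protein_center", np.asarray(self.protein_center, dtype=float)
        )
        chans = []
        for axis, radius in self.channels:
            axis = np.asarray(axis, dtype=float)
            norm = np.linalg.norm(axis)
            if norm == 0:
                raise ValueError("channel axis must be a nonzero vector")
            if not np.isclose(norm, 1.0):
                axis = axis / norm
            if radius <= 0:
                raise ValueError("channel radius must be positive")
            chans.append((axis, float(radius)))
        object.__setattr__(self, "channels", tuple(chans))
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")
        if not (0 < self.protein_radius < self.box_edge / 2):
            raise ValueError("protein_radius must be in (0, box_edge/2)")
        if not (0 < self.site_radius < self.protein_radius):
            raise ValueError("site_radius must be in (0, protein_radius)")
        for _, radius in self.channels:
            if radius >= self.protein_radius:
                raise ValueError("channel radius must be < protein_radius")
        if self.diffusion_coeff <= 0:
            raise ValueError("diffusion_coeff must be positive")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")

    # -- geometry helpers -------------------------------------------------

    def displacement(self, positions: np.ndarray) -> np.ndarray:
        """Minimum-image displacement from the protein center (nm)."""
        d = np.atleast_2d(positions) - self.protein_center
        d -= self.box_edge * np.round(d / self.box_edge)
        return d

    def radial(self, positions: np.ndarray) -> np.ndarray:
        return np.linalg.norm(self.displacement(positions), axis=-1)

    def _ray_distances(self, disp: np.ndarray) -> np.ndarray:
        """Distance from each displacement to each channel axis ray, (n, k)."""
        axes = np.array([a for a, _ in self.channels])  # (k, 3)
        axial = disp @ axes.T  # (n, k)
        r2 = np.sum(disp**2, axis=-1)[:, None]
        perp = np.sqrt(np.clip(r2 - axial**2, 0.0, None))
        # behind the ray origin the nearest ray point is the origin itself
        return np.where(axial > 0, perp, np.sqrt(r2))

    def in_channel(self, positions: np.ndarray) -> np.ndarray:
        """Boolean (n, k): point lies inside channel cylinder k.

        A point belongs to a channel when its distance to the channel axis ray
        is below the channel radius and its radial coordinate lies between the
        site radius and ``protein_radius + channel_radius`` — the channel mouth
        extends one radius beyond the protein surface so that crossing traces
        are detectable outside the sphere.
        """
        disp = self.displacement(positions)
        r = np.linalg.norm(disp, axis=-1)
        if not self.channels:
            return np.zeros((len(disp), 0), dtype=bool)
        ray = self._ray_distances(disp)
        radii = np.array([c for _, c in self.channels])
        return (ray < radii) & (r[:, None] >= self.site_radius) & (
            r[:, None] <= self.protein_radius + radii
        )

    def channel_at(self, position: np.ndarray) -> int:
        """Channel index containing a point; nearest axis if none contains it.

        Ties are broken by the lowest channel index.
        """
        pos = np.atleast_2d(position)
        member = self.in_channel(pos)[0]
        if member.any():
            return int(np.argmax(member))
        return int(np.argmin(self._ray_distances(self.displacement(pos))[0]))

    def tunnels(self, spacing: float | None = None):
        """Channel geometry as tunnel sphere chains (Å), ordered site→surface."""
        from .pathways import Tunnel

        tunnels = []
        for i, (axis, radius) in enumerate(self.channels):
            spc = radius if spacing is None else spacing
            rr = np.arange(
                self.site_radius, self.protein_radius + radius + 0.5 * spc, spc
            )
            centers = (self.protein_center + rr[:, None] * axis) * NM_TO_ANG
            radii = np.full(len(rr), radius * NM_TO_ANG)
            tunnels.append(Tunnel(id=f"T{i + 1}", centers=centers, radii=radii))
        return tunnels


@dataclass(frozen=True)
class GroundTruthEvent:
    ligand: int
    kind: str  # "binding" | "unbinding"
    frame: int
    channel: int


@dataclass
class SyntheticTrajectory:
    """Positions (frame × ligand × 3, nm, wrapped) plus recorded ground truth."""

    system: ToySystem
    positions: np.ndarray
    ground_truth_events: list
    rng_seed: int

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_ligands(self) -> int:
        return self.positions.shape[1]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.system.timestep


def simulate_ligand_diffusion(
    system: ToySystem, n_ligands: int, n_frames: int, seed: int
) -> SyntheticTrajectory:
    """Overdamped Brownian dynamics of independent ligands in the toy system.

    Each step proposes an isotropic Gaussian displacement with per-axis
    variance ``2 D dt``; proposals whose endpoint lies inside the protein
    exclusion sphere are rejected (the ligand stays in place) unless the
    endpoint is inside a channel cylinder or the binding-site sphere.  With a
    symmetric proposal this Metropolis rule preserves the uniform equilibrium
    density on the allowed volume, so binding and unbinding fluxes through
    each channel balance in equilibrium.

    A ligand arriving in the site sphere after having visited bulk records a
    binding event; the channel is the one containing the ligand at its last
    inward crossing of the protein-radius shell.  A bound ligand crossing back
    out to bulk records an unbinding event with the channel of exit.
    """
    if n_ligands < 1:
        raise ValueError("n_ligands must be >= 1")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")

    rng = np.random.default_rng(seed)
    L = system.box_edge
    sigma = np.sqrt(2.0 * system.diffusion_coeff * system.timestep)

    # initial positions: uniform in bulk (outside the protein sphere)
    pos = rng.uniform(0.0, L, size=(n_ligands, 3))
    bad = system.radial(pos) < system.protein_radius
    while bad.any():
        pos[bad] = rng.uniform(0.0, L, size=(int(bad.sum()), 3))
        bad = system.radial(pos) < system.protein_radius

    positions = np.empty((n_frames, n_ligands, 3))
    positions[0] = pos
    r_prev = system.radial(pos)
    bound = np.zeros(n_ligands, dtype=bool)
    last_channel = np.full(n_ligands, -1, dtype=int)
    events: list[GroundTruthEvent] = []

    R = system.protein_radius
    site = system.site_radius

    for t in range(1, n_frames):
        prop = pos + rng.normal(0.0, sigma, size=(n_ligands, 3))
        prop %= L
        r_new = system.radial(prop)
        allowed = (r_new >= R) | (r_new <= site) | system.in_channel(prop).any(
            axis=1
        )
        pos = np.where(allowed[:, None], prop, pos)
        r = np.where(allowed, r_new, r_prev)
        positions[t] = pos

        crossed_in = np.flatnonzero((r_prev >= R) & (r < R))
        for i in crossed_in:
            last_channel[i] = system.channel_at(pos[i])
        newly_bound = np.flatnonzero(~bound & (r <= site))
        for i in newly_bound:
            events.append(GroundTruthEvent(int(i), "binding", t, int(last_channel[i])))
            bound[i] = True
        escaped = np.flatnonzero(bound & (r >= R))
        for i in escaped:
            events.append(
                GroundTruthEvent(int(i), "unbinding", t, system.channel_at(pos[i]))
            )
            bound[i] = False
        r_prev = r

    return SyntheticTrajectory(
        system=system,
        positions=positions,
        ground_truth_events=events,
        rng_seed=int(seed),
    )


def ground_truth_passage_times(traj: SyntheticTrajectory):
    """(first-passage times, residence times) in ns from the recorded events.

    The first binding of each ligand is measured from frame 0; subsequent
    bindings from the completing frame of the preceding unbinding.  Residence
    time runs from binding to unbinding.
    """
    dt = traj.system.timestep
    fpts, residences = [], []
    ref = {}  # ligand -> reference frame for the next FPT
    bind_frame = {}
    for ev in traj.ground_truth_events:
        if ev.kind == "binding":
            fpts.append((ev.frame - ref.get(ev.ligand, 0)) * dt)
            bind_frame[ev.ligand] = ev.frame
        else:
            residences.append((ev.frame - bind_frame[ev.ligand]) * dt)
            ref[ev.ligand] = ev.frame
    return np.array(fpts), np.array(residences)


def label_toy_trajectory(traj: SyntheticTrajectory):
    """Geometric bound/intermediate/unbound labels for every ligand copy.

    Bound when the radial coordinate is within the site sphere; unbound when
    it is at or beyond the protein radius (bulk); intermediate inside a
    channel.  These are exactly the simulator's own ground-truth definitions,
    so hysteresis event extraction with ``min_dwell=1`` must reproduce the
    recorded events one-to-one.

    Returns a list of :class:`gasbind.labeling.StateSeries` with positions
    (Å, unwrapped relative to the protein center) and an outside-surface flag
    per frame, so crossing traces and pathway assignment can run downstream.
    """
    from .labeling import BOUND, INTERMEDIATE, UNBOUND, StateSeries

    system = traj.system
    times = traj.times_ns
    out = []
    for i in range(traj.n_ligands):
        disp = system.displacement(traj.positions[:, i, :])
        r = np.linalg.norm(disp, axis=-1)
        labels = np.full(traj.n_frames, INTERMEDIATE, dtype=np.int8)
        labels[r >= system.protein_radius] = UNBOUND
        labels[r <= system.site_radius] = BOUND
        out.append(
            StateSeries(
                ligand_id=i,
                labels=labels,
                frame_times=times,
                positions=(system.protein_center + disp) * NM_TO_ANG,
                outside=r >= system.protein_radius,
            )
        )
    return out


@dataclass
class TwoStateSeries:
    """A scalar coordinate switching between two Gaussian emission states."""

    values: np.ndarray  # Å
    hidden_states: np.ndarray  # 0 / 1 per frame
    transition_probs: tuple  # (p01, p10) per-frame switching probabilities
    emissions: tuple  # ((mean0, sd0), (mean1, sd1)) in Å

    @property
    def stationary(self) -> tuple:
        p01, p10 = self.transition_probs
        return (p10 / (p01 + p10), p01 / (p01 + p10))


def generate_two_state_series(
    transition_probs, emissions, n_frames: int, seed: int
) -> TwoStateSeries:
    """Markov-switching bimodal series, a stand-in for a gating distance.

    The hidden chain starts from its stationary distribution; the observed
    value at each frame is drawn from the Gaussian emission of the hidden
    state.  The long-run occupancy of state 0 is p10 / (p01 + p10).
    """
    p01, p10 = transition_probs
    if not (0 < p01 < 1 and 0 < p10 < 1):
        raise ValueError("transition probabilities must lie in (0, 1)")
    (m0, s0), (m1, s1) = emissions
    if s0 <= 0 or s1 <= 0:
        raise ValueError("emission standard deviations must be positive")
    if abs(m0 - m1) < 2.0 * (s0 + s1):
        warnings.warn(
            "emission modes closer than 2 combined sd; states may not be "
            "separable in the observed density",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    pi0 = p10 / (p01 + p10)
    states = np.empty(n_frames, dtype=np.int8)
    u = rng.random(n_frames)
    states[0] = 0 if u[0] < pi0 else 1
    for t in range(1, n_frames):
        if states[t - 1] == 0:
            states[t] = 1 if u[t] < p01 else 0
        else:
            states[t] = 0 if u[t] < p10 else 1
    means = np.array([m0, m1])
    sds = np.array([s0, s1])
    values = rng.normal(means[states], sds[states])
    return TwoStateSeries(
        values=values,
        hidden_states=states,
        transition_probs=(p01, p10),
        emissions=((m0, s0), (m1, s1)),
    )


# -- standard-format output -----------------------------------------------


def write_trajectory(
    traj: SyntheticTrajectory,
    topology_path,
    trajectory_path,
    ground_truth_path=None,
    n_surface_beads: int = 64,
):
    """Write the toy trajectory as a PDB topology plus an XTC/DCD file.

    The topology holds one pseudo-atom per ligand copy (resname LIG) plus a
    static pseudo-protein: Ni and Fe beads flanking the protein center and a
    shell of beads on the exclusion sphere (resname PRO), so the real-data
    readers and selections are exercised by the fixture.  Ground truth is
    serialized to a JSON sidecar.
    """
    import MDAnalysis as mda

    system = traj.system
    n_lig = traj.n_ligands
    # deterministic Fibonacci shell of surface beads
    k = np.arange(n_surface_beads)
    phi = np.arccos(1.0 - 2.0 * (k + 0.5) / n_surface_beads)
    theta = np.pi * (1.0 + 5**0.5) * k
    shell = system.protein_center + system.protein_radius * np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)],
        axis=1,
    )
    anchor_offset = np.array([0.1, 0.0, 0.0])
    protein_xyz = np.vstack(
        [system.protein_center - anchor_offset, system.protein_center + anchor_offset, shell]
    )
    n_prot = len(protein_xyz)

    u = mda.Universe.empty(
        n_atoms=n_prot + n_lig,
        n_residues=n_prot + n_lig,
        atom_resindex=np.arange(n_prot + n_lig),
        trajectory=True,
    )
    names = ["NI", "FE"] + [f"S{j}" for j in range(n_surface_beads)] + [
        "LIG" for _ in range(n_lig)
    ]
    u.add_TopologyAttr("name", names)
    u.add_TopologyAttr(
        "resname", ["PRO"] * n_prot + ["LIG"] * n_lig
    )
    u.add_TopologyAttr("resid", list(range(1, n_prot + n_lig + 1)))
    u.dimensions = [system.box_edge * NM_TO_ANG] * 3 + [90.0, 90.0, 90.0]

    frames = np.empty((traj.n_frames, n_prot + n_lig, 3), dtype=np.float32)
    frames[:, :n_prot, :] = protein_xyz * NM_TO_ANG
    frames[:, n_prot:, :] = traj.positions * NM_TO_ANG
    u.load_new(frames, dt=system.timestep * 1000.0)  # ps
    u.trajectory.ts.dimensions = u.dimensions

    with mda.Writer(str(topology_path), n_atoms=u.atoms.n_atoms) as w:
        w.write(u.atoms)
    with mda.Writer(str(trajectory_path), n_atoms=u.atoms.n_atoms) as w:
        for ts in u.trajectory:
            ts.dimensions = [system.box_edge * NM_TO_ANG] * 3 + [90.0, 90.0, 90.0]
            w.write(u.atoms)

    if ground_truth_path is not None:
        record = {
            "rng_seed": traj.rng_seed,
            "timestep_ns": system.timestep,
            "n_frames": traj.n_frames,
            "n_ligands": n_lig,
            "box_edge_nm": system.box_edge,
            "events": [
                {
                    "ligand": ev.ligand,
                    "kind": ev.kind,
                    "frame": ev.frame,
                    "channel": ev.channel,
                }
                for ev in traj.ground_truth_events
            ],
        }
        with open(ground_truth_path, "w") as fh:
            json.dump(record, fh, indent=1)


def load_ground_truth(path):
    with open(path) as fh:
        record = json.load(fh)
    record["events"] = [
        GroundTruthEvent(e["ligand"], e["kind"], e["frame"], e["channel"])
        for e in record["events"]
    ]
    return record
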