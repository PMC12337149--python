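"""Per-frame bound/intermediate/unbound labeling and event extraction.

A ligand copy is *bound* when its center of mass is within ``bound_cutoff``
of the catalytic-site center of mass and within ``interface_cutoff`` of the
midpoint of the two anchor atoms (for a [NiFe] hydrogenase, the Ni and Fe);
it is *unbound* when fully solvated, i.e. when its minimum atom–atom distance
to the protein exceeds ``contact_cutoff``; everything else is *intermediate*.
All distances use the minimum-image convention and are reported in Å.

Events are extracted with a hysteresis rule: a binding event completes at the
first frame of a run of at least ``min_dwell`` consecutive bound frames that
follows the most recent qualifying unbound run, and symmetrically for
unbinding.  The first-passage time of a replica's first binding is measured
from frame 0; later first-passage times from the completing frame of the
preceding unbinding; the residence time runs from binding completion to
unbinding completion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "UNBOUND",
    "INTERMEDIATE",
    "BOUND",
    "SiteDefinition",
    "StateSeries",
    "Event",
    "label_frames",
    "extract_events",
    "surface_crossing_point",
    "events_to_passage_times",
    "events_to_dataframe",
    "write_events_csv",
    "read_events_csv",
]

UNBOUND, INTERMEDIATE, BOUND = 0, 1, 2
_LABEL_NAMES = {UNBOUND: "unbound", INTERMEDIATE: "intermediate", BOUND: "bound"}


@dataclass
class SiteDefinition:
    """Geometric definition of the buried binding site.

    ``site_atoms`` selects the catalytic center (its center of mass is the
    site reference point); ``anchor_pair`` selects the two metal atoms whose
    midpoint defines the "near the interface" criterion.  Cutoffs in Å.
    """

    site_atoms: str
    anchor_pair: tuple
    bound_cutoff: float = 5.0
    interface_cutoff: float = 3.0

    def __post_init__(self):
        if self.bound_cutoff <= 0 or self.interface_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class StateSeries:
    """Per-ligand label series plus optional geometry for crossing traces."""

    ligand_id: int
    labels: np.ndarray  # int8 codes per frame
    frame_times: np.ndarray  # ns
    positions: np.ndarray | None = None  # ligand COM per frame (Å)
    outside: np.ndarray | None = None  # per frame: outside protein surface?
    replica_id: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.labels) != len(self.frame_times):
            raise ValueError("labels and frame_times must have equal length")
        if len(self.frame_times) > 1 and not np.all(
            np.diff(self.frame_times) > 0
        ):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def label_names(self):
        return np.array([_LABEL_NAMES[int(c)] for c in self.labels])


@dataclass
class Event:
    """One binding or unbinding transit.

    ``passage_time`` is the first-passage time for a binding event and the
    residence time for an unbinding event (ns).  ``crossing_trace`` holds the
    ligand COM positions (Å) in a window around the protein-surface crossing;
    ``crossing_outside`` flags which trace points are outside the surface.
    """

    kind: str  # "binding" | "unbinding"
    ligand_id: int
    replica_id: int
    start_frame: int
    end_frame: int
    passage_time: float
    crossing_trace: np.ndarray | None = None
    crossing_outside: np.ndarray | None = None
    pathway: str | None = field(default=None)

    def __post_init__(self):
        if self.kind not in ("binding", "unbinding"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")
        if self.passage_time <= 0:
            raise ValueError("passage_time must be positive")


def _ligand_groups(universe, ligand_selection):
    sel = universe.select_atoms(ligand_selection)
    if sel.n_atoms == 0:
        raise ValueError(f"ligand selection {ligand_selection!r} is empty")
    return [res.atoms for res in sel.residues]


def label_frames(
    universe,
    site: SiteDefinition,
    ligand_selection: str = "resname LIG",
    protein_selection: str = "protein",
    contact_cutoff: float = 4.0,
) -> list:
    """Label every ligand copy in every frame of an MDAnalysis Universe.

    Each residue matched by ``ligand_selection`` is one ligand copy.  Returns
    one :class:`StateSeries` per copy, carrying the ligand COM per frame and
    the outside-surface flag (minimum protein contact > ``contact_cutoff``)
    needed for crossing traces.
    """
    from MDAnalysis.lib.distances import distance_array

    site_group = universe.select_atoms(site.site_atoms)
    if site_group.n_atoms == 0:
        raise ValueError(f"site selection {site.site_atoms!r} is empty")
    anchors = [universe.select_atoms(s) for s in site.anchor_pair]
    for s, grp in zip(site.anchor_pair, anchors):
        if grp.n_atoms == 0:
            raise ValueError(f"anchor selection {s!r} is empty")
    protein = universe.select_atoms(protein_selection)
    if protein.n_atoms == 0:
        raise ValueError(f"protein selection {protein_selection!r} is empty")
    ligands = _ligand_groups(universe, ligand_selection)

    n_frames = len(universe.trajectory)
    n_lig = len(ligands)
    labels = np.empty((n_lig, n_frames), dtype=np.int8)
    coms = np.empty((n_lig, n_frames, 3))
    outside = np.empty((n_lig, n_frames), dtype=bool)
    times = np.empty(n_frames)

    for f, ts in enumerate(universe.trajectory):
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            raise ValueError(f"missing box vectors at frame {f}")
        box = ts.dimensions
        times[f] = ts.time / 1000.0  # ps -> ns
        site_com = site_group.center_of_mass()
        midpoint = 0.5 * (
            anchors[0].center_of_mass() + anchors[1].center_of_mass()
        )
        refs = np.vstack([site_com, midpoint])
        for i, lig in enumerate(ligands):
            com = lig.center_of_mass()
            coms[i, f] = com
            d_site, d_mid = distance_array(
                com[None, :], refs, box=box
            ).ravel()
            min_contact = distance_array(
                lig.positions, protein.positions, box=box
            ).min()
            outside[i, f] = min_contact > contact_cutoff
            if d_site <= site.bound_cutoff and d_mid <= site.interface_cutoff:
                labels[i, f] = BOUND
            elif min_contact > contact_cutoff:
                labels[i, f] = UNBOUND
            else:
                labels[i, f] = INTERMEDIATE

    if n_frames > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(n_frames, dtype=float)
    return [
        StateSeries(
            ligand_id=i,
            labels=labels[i],
            frame_times=times,
            positions=coms[i],
            outside=outside[i],
        )
        for i in range(n_lig)
    ]


def _runs(labels):
    """(value, start, length) for each maximal constant run."""
    labels = np.asarray(labels)
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def _trace(series: StateSeries, crossing_frame, before, after):
    if series.positions is None or crossing_frame is None:
        return None, None
    lo = max(0, crossing_frame - before)
    hi = min(len(series.labels), crossing_frame + after + 1)
    trace = np.array(series.positions[lo:hi])
    out = (
        np.array(series.outside[lo:hi]) if series.outside is not None else None
    )
    return trace, out


def extract_events(
    series: StateSeries, min_dwell: int = 1, trace_window: int = 3
) -> list:
    """Hysteresis extraction of alternating binding/unbinding events.

    ``min_dwell`` is the minimum run length (frames) for a bound or unbound
    stretch to commit a transition; raising it suppresses recrossing noise.
    A ligand that starts bound contributes no event until it first completes
    a qualifying unbound run.  Crossing traces straddle the surface crossing
    (the last outside frame before the bound run for binding, the first frame
    of the unbound run for unbinding) keeping the crossing frame on the bulk
    side and ``trace_window`` frames on the inside — the in-channel side of
    the transit is what identifies the tunnel used.
    """
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    labels = series.labels
    times = series.frame_times
    events: list[Event] = []
    committed = None  # last committed macro-state
    ref_frame = 0  # FPT reference: start, or last unbinding completion
    bind_frame = None
    for value, start, length in _runs(labels):
        if value == INTERMEDIATE or length < min_dwell:
            continue
        if value == committed:
            continue
        if value == BOUND:
            if committed is None:
                # started bound: no FPT reference, skip to first unbound run
                continue
            crossing = None
            if series.outside is not None:
                bulk = np.flatnonzero(series.outside[:start])
                crossing = int(bulk[-1]) if len(bulk) else None
            # the crossing frame (last bulk point) plus the inward transit:
            # the in-channel side of the crossing is what identifies the tunnel
            trace, out = _trace(series, crossing, 0, trace_window)
            events.append(
                Event(
                    kind="binding",
                    ligand_id=series.ligand_id,
                    replica_id=series.replica_id,
                    start_frame=ref_frame,
                    end_frame=start,
                    passage_time=float(times[start] - times[ref_frame]),
                    crossing_trace=trace,
                    crossing_outside=out,
                )
            )
            bind_frame = start
            committed = BOUND
        else:  # UNBOUND
            if committed == BOUND and bind_frame is not None:
                # inside frames leading to the exit plus the first bulk point
                trace, out = _trace(series, start, trace_window, 0)
                events.append(
                    Event(
                        kind="unbinding",
                        ligand_id=series.ligand_id,
                        replica_id=series.replica_id,
                        start_frame=bind_frame,
                        end_frame=start,
                        passage_time=float(times[start] - times[bind_frame]),
                        crossing_trace=trace,
                        crossing_outside=out,
                    )
                )
                # the next FPT is measured from this unbinding completion;
                # the very first FPT stays referenced to frame 0
                ref_frame = start
            committed = UNBOUND
    return events


def surface_crossing_point(event: Event, surface_def=None):
    """The surface-crossing point of an event's trace, or None if no crossing.

    For an unbinding event this is the first trace point outside the protein
    surface; for a binding event, the last outside point that still precedes
    an inside point (the entry).  ``surface_def`` is an optional callable
    mapping a point (Å) to True when it lies outside the surface; when absent
    the outside flags stored with the event are used.  A trace that never
    crosses the surface is flagged with a logged warning and None is
    returned, which excludes the event from pathway assignment.
    """
    if event.crossing_trace is None or len(event.crossing_trace) == 0:
        raise ValueError("event has no crossing trace")
    trace = np.asarray(event.crossing_trace)
    if surface_def is not None:
        outside = np.array([bool(surface_def(p)) for p in trace])
    elif event.crossing_outside is not None:
        outside = np.asarray(event.crossing_outside, dtype=bool)
    else:
        raise ValueError("no surface definition or stored outside flags")
    if outside.all() or (~outside).all():
        logger.warning(
            "%s event of ligand %d: trace never crosses the surface",
            event.kind,
            event.ligand_id,
        )
        return None
    if event.kind == "unbinding":
        return trace[int(np.flatnonzero(outside)[0])]
    inside_idx = np.flatnonzero(~outside)
    candidates = np.flatnonzero(outside[: inside_idx[-1]])
    if len(candidates) == 0:
        logger.warning(
            "binding event of ligand %d: no outside point before entry",
            event.ligand_id,
        )
        return None
    return trace[int(candidates[-1])]


def events_to_passage_times(events):
    """Split events into first-passage times and residence times (ns)."""
    fpts = np.array([e.passage_time for e in events if e.kind == "binding"])
    residences = np.array(
        [e.passage_time for e in events if e.kind == "unbinding"]
    )
    return fpts, residences


def events_to_dataframe(events) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "kind": e.kind,
                "ligand_id": e.ligand_id,
                "replica_id": e.replica_id,
                "start_frame": e.start_frame,
                "end_frame": e.end_frame,
                "passage_time_ns": e.passage_time,
                "pathway": e.pathway if e.pathway is not None else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "kind",
            "ligand_id",
            "replica_id",
            "start_frame",
            "end_frame",
            "passage_time_ns",
            "pathway",
        ],
    )


def write_events_csv(events, path):
    events_to_dataframe(events).to_csv(path, index=False)


def read_events_csv(path):
    df = pd.read_csv(path, keep_default_na=False)
    events = []
    for _, row in df.iterrows():
        events.append(
            Event(
                kind=row["kind"],
                ligand_id=int(row["ligand_id"]),
                replica_id=int(row["replica_id"]),
                start_frame=int(row["start_frame"]),
                end_frame=int(row["end_frame"]),
                passage_time=float(row["passage_time_ns"]),
                pathway=(row["pathway"] or None),
            )
        )
    return events
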