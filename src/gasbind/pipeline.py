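"""End-to-end orchestration of the synthetic (un)binding study.

Runs the full chain — Brownian-dynamics simulation, state labeling, event
extraction, k_on/k_off estimation, tunnel assignment with the
binding/unbinding symmetry test, and the two-state gating coordinate with
its density, classification and MSM-reweighted free-energy landscape — from
one :class:`~gasbind.config.RunConfig` and one integer seed, writing CSV and
JSON artifacts plus a provenance record when an output directory is given.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bottleneck import classify_states, distance_density
from .config import RunConfig, config_hash
from .kinetics import estimate_koff, estimate_kon, ligand_concentration
from .labeling import events_to_passage_times, extract_events, write_events_csv
from .msm import MarkovStateModel
from .pathways import (
    assign_events,
    chi_square_compare,
    merge_assignments,
    pathway_distribution,
)
from .synthetic import (
    generate_two_state_series,
    ground_truth_passage_times,
    label_toy_trajectory,
    simulate_ligand_diffusion,
)

logger = logging.getLogger(__name__)

# fixed offsets decorrelate the per-stage RNG streams from one base seed
_SEED_SIM, _SEED_BOOT, _SEED_CHAIN, _SEED_MC = 0, 101, 211, 307


@dataclass
class StudyResult:
    trajectory: object
    events: list
    concentration: float
    kon: object
    koff: object
    binding_distribution: object
    unbinding_distribution: object
    symmetry: object
    two_state: object
    density: object
    gate_summary: object
    msm: object


def run_synthetic_study(
    config: RunConfig, seed: int, outdir=None, write_trajectory_files=False
) -> StudyResult:
    """Run every pipeline stage on the toy system defined by ``config``."""
    t0 = time.time()
    base = int(seed) % (2**31 - 1)
    system = config.toy_system()
    traj = simulate_ligand_diffusion(
        system, config.n_ligands, config.n_frames, seed=base + _SEED_SIM
    )
    series = label_toy_trajectory(traj)
    events = [
        ev for s in series for ev in extract_events(s, min_dwell=config.min_dwell)
    ]
    logger.info(
        "simulated %d ligands × %d frames: %d events (%.1f s)",
        config.n_ligands,
        config.n_frames,
        len(events),
        time.time() - t0,
    )

    fpts, residences = events_to_passage_times(events)
    concentration = ligand_concentration(config.n_ligands, config.box_edge**3)
    kon = (
        estimate_kon(
            fpts, concentration, n_boot=config.n_boot, seed=base + _SEED_BOOT
        )
        if len(fpts)
        else None
    )
    koff = (
        estimate_koff(
            residences, n_boot=config.n_boot, seed=base + _SEED_BOOT + 1
        )
        if len(residences)
        else None
    )

    tunnels = system.tunnels()
    assign_events(events, tunnels, max_assign_dist=config.max_assign_dist)
    if config.merge_map:
        for ev in events:
            ev.pathway = merge_assignments([ev.pathway], config.merge_map)[0]
    tunnel_ids = [t.id for t in tunnels]
    binding = [e.pathway for e in events if e.kind == "binding"]
    unbinding = [e.pathway for e in events if e.kind == "unbinding"]
    categories = tunnel_ids + ["unassigned"]
    binding_dist = (
        pathway_distribution(
            binding, n_boot=config.n_boot, seed=base + _SEED_BOOT + 2,
            categories=categories,
        )
        if binding
        else None
    )
    unbinding_dist = (
        pathway_distribution(
            unbinding, n_boot=config.n_boot, seed=base + _SEED_BOOT + 3,
            categories=categories,
        )
        if unbinding
        else None
    )
    symmetry = None
    if binding_dist is not None and unbinding_dist is not None:
        symmetry = chi_square_compare(
            binding_dist.as_dict(),
            unbinding_dist.as_dict(),
            min_expected=config.min_expected,
            mc_replicates=config.mc_replicates,
            seed=base + _SEED_MC,
        )

    (m_open, m_closed) = config.two_state_means
    (s_open, s_closed) = config.two_state_sds
    # state 0 = open (larger distance), state 1 = closed
    two_state = generate_two_state_series(
        (config.two_state_p01, config.two_state_p10),
        ((m_open, s_open), (m_closed, s_closed)),
        config.two_state_frames,
        seed=base + _SEED_CHAIN,
    )
    density = distance_density(two_state.values, bin_width=config.bin_width)
    gate_summary = classify_states(density, two_state.values)
    msm = MarkovStateModel(
        n_bins=config.n_bins,
        lag=config.msm_lag,
        temperature=config.temperature,
    ).fit([two_state.values], timestep_ns=config.timestep)

    result = StudyResult(
        trajectory=traj,
        events=events,
        concentration=concentration,
        kon=kon,
        koff=koff,
        binding_distribution=binding_dist,
        unbinding_distribution=unbinding_dist,
        symmetry=symmetry,
        two_state=two_state,
        density=density,
        gate_summary=gate_summary,
        msm=msm,
    )
    if outdir is not None:
        write_artifacts(
            result, config, seed, Path(outdir), write_trajectory_files
        )
    return result


def write_artifacts(result, config, seed, outdir: Path, trajectory_files=False):
    outdir.mkdir(parents=True, exist_ok=True)
    write_events_csv(result.events, outdir / "events.csv")

    report = {}
    for name, est in (("k_on", result.kon), ("k_off", result.koff)):
        if est is not None:
            report[name] = {
                "rate": est.rate,
                "standard_error": est.standard_error,
                "n_events": est.n_events,
                "mean_passage_ns": est.mean_passage,
            }
    report["concentration_M"] = result.concentration
    (outdir / "kinetics.json").write_text(json.dumps(report, indent=1))

    frames = []
    for kind, dist in (
        ("binding", result.binding_distribution),
        ("unbinding", result.unbinding_distribution),
    ):
        if dist is not None:
            df = dist.to_frame()
            df.insert(0, "kind", kind)
            frames.append(df)
    if frames:
        pd.concat(frames).to_csv(outdir / "pathway_distribution.csv", index=False)
    if result.symmetry is not None:
        (outdir / "symmetry_test.json").write_text(
            json.dumps(
                {
                    "chi_square": result.symmetry.statistic,
                    "degrees_of_freedom": result.symmetry.degrees_of_freedom,
                    "p_value": result.symmetry.p_value,
                    "pooled_categories": result.symmetry.pooled_categories,
                    "method": result.symmetry.method,
                },
                indent=1,
            )
        )

    pd.DataFrame(
        {
            "center_A": result.density.centers,
            "density": result.density.density,
            "smoothed": result.density.smoothed,
        }
    ).to_csv(outdir / "bottleneck_density.csv", index=False)
    gs = result.gate_summary
    (outdir / "bottleneck_states.json").write_text(
        json.dumps(
            {
                "mode_open_A": gs.mode_open,
                "mode_closed_A": gs.mode_closed,
                "threshold_A": gs.threshold,
                "open_fraction": gs.open_fraction,
                "bimodal": gs.bimodal,
            },
            indent=1,
        )
    )

    model = result.msm.model_
    np.savetxt(outdir / "msm_count_matrix.csv", model.count_matrix, delimiter=",", fmt="%d")
    np.savetxt(
        outdir / "msm_transition_matrix.csv", model.transition_matrix, delimiter=","
    )
    fel = result.msm.fel_
    pd.DataFrame(
        {
            "center_A": fel.bin_centers,
            "stationary": fel.stationary,
            "delta_g_kT": fel.delta_g_kt,
            "delta_g_kcal_mol": fel.delta_g_kcal,
        }
    ).to_csv(outdir / "fel.csv", index=False)

    if trajectory_files:
        from .synthetic import write_trajectory
        from .pathways import write_tunnels

        write_trajectory(
            result.trajectory,
            outdir / "topology.pdb",
            outdir / "trajectory.xtc",
            outdir / "ground_truth.json",
        )
        write_tunnels(config.toy_system().tunnels(), outdir / "tunnels.pdb")

    (outdir / "provenance.json").write_text(
        json.dumps(
            {
                "gasbind_version": __version__,
                "config_hash": config_hash(config),
                "config": config.to_dict(),
                "seed": int(seed),
                "n_events": len(result.events),
            },
            indent=1,
        )
    )


def ground_truth_summary(result: StudyResult) -> dict:
    """Ground-truth event counts and passage times recorded by the simulator."""
    traj = result.trajectory
    fpts, residences = ground_truth_passage_times(traj)
    channels = {}
    for ev in traj.ground_truth_events:
        key = (ev.kind, f"T{ev.channel + 1}")
        channels[key] = channels.get(key, 0) + 1
    return {
        "n_binding": int(len(fpts)),
        "n_unbinding": int(len(residences)),
        "mean_fpt_ns": float(fpts.mean()) if len(fpts) else None,
        "mean_residence_ns": float(residences.mean()) if len(residences) else None,
        "channel_counts": {f"{k}:{t}": v for (k, t), v in channels.items()},
    }
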