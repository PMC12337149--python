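"""Run configuration: a YAML file mirrored by the CLI, with validation.

A single configuration drives all pipeline stages.  Defaults reproduce the
built-in synthetic toy study, so ``gasbind all`` runs end-to-end without any
external data; real-data runs point the ``inputs`` section at a topology,
trajectories and a tunnel sphere file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "config_hash"]


_POSITIVE = [
    ("bound_cutoff",),
    ("interface_cutoff",),
    ("contact_cutoff",),
    ("max_assign_dist",),
    ("box_edge",),
    ("protein_radius",),
    ("site_radius",),
    ("channel_radius",),
    ("diffusion_coeff",),
    ("timestep",),
    ("temperature",),
]


@dataclass
class RunConfig:
    # synthetic study
    box_edge: float = 6.0
    protein_radius: float = 1.3
    site_radius: float = 0.45
    channel_radius: float = 0.5
    n_channels: int = 2
    diffusion_coeff: float = 4.5
    timestep: float = 0.004
    n_ligands: int = 30
    n_frames: int = 10000
    # labeling
    bound_cutoff: float = 5.0
    interface_cutoff: float = 3.0
    contact_cutoff: float = 4.0
    min_dwell: int = 1
    site_atoms: str = "name NI FE"
    anchor_pair: tuple = ("name NI", "name FE")
    ligand_selection: str = "resname LIG"
    protein_selection: str = "resname PRO"
    # pathways
    max_assign_dist: float = 3.0
    min_expected: float = 5.0
    mc_replicates: int = 100000
    merge_map: dict = field(default_factory=dict)
    # kinetics
    n_boot: int = 1000
    # bottleneck / MSM surrogate coordinate
    two_state_p01: float = 0.01
    two_state_p10: float = 0.03
    two_state_means: tuple = (7.5, 4.5)  # open, closed (Å)
    two_state_sds: tuple = (0.5, 0.3)
    two_state_frames: int = 100000
    bottleneck_pair: tuple = ("resid 74", "resid 122")
    bin_width: float = 0.2
    n_bins: int = 40
    msm_lag: object = "auto"
    temperature: float = 300.0
    # orchestration
    seed: int = 1
    topology: str | None = None
    trajectories: list = field(default_factory=list)
    tunnel_file: str | None = None

    def validate(self):
        for (key,) in _POSITIVE:
            if getattr(self, key) <= 0:
                raise ValueError(f"config parameter {key!r} must be positive")
        for key in ("n_ligands", "n_channels", "min_dwell", "n_boot"):
            if getattr(self, key) < 1:
                raise ValueError(f"config parameter {key!r} must be >= 1")
        if self.n_frames < 2:
            raise ValueError("config parameter 'n_frames' must be >= 2")
        if not (0 < self.two_state_p01 < 1 and 0 < self.two_state_p10 < 1):
            raise ValueError(
                "config parameters 'two_state_p01'/'two_state_p10' must be in (0, 1)"
            )
        if self.site_radius >= self.protein_radius:
            raise ValueError("config parameter 'site_radius' must be < protein_radius")
        for key in ("topology", "tunnel_file"):
            path = getattr(self, key)
            if path is not None and not __import__("os").path.exists(path):
                raise ValueError(f"config parameter {key!r}: path {path} not found")
        return self

    def toy_system(self):
        from .synthetic import ToySystem

        angles = 2 * np.pi * np.arange(self.n_channels) / self.n_channels
        axes = np.stack(
            [np.cos(angles), np.sin(angles), np.zeros_like(angles)], axis=1
        )
        return ToySystem(
            box_edge=self.box_edge,
            protein_center=np.full(3, self.box_edge / 2),
            protein_radius=self.protein_radius,
            channels=tuple((a, self.channel_radius) for a in axes),
            site_radius=self.site_radius,
            diffusion_coeff=self.diffusion_coeff,
            timestep=self.timestep,
        )

    def to_dict(self):
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def load_config(path=None, overrides=None) -> RunConfig:
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("anchor_pair", "two_state_means", "two_state_sds", "bottleneck_pair"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data).validate()


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
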