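"""Generator specifications and ground-truth records."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ..errors import ConfigError

KINDS = ("free_diffusion", "rotational_diffusion", "staged_association",
         "conformer_chain", "bound_complex")


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic-trajectory generator.

    Only the fields relevant to ``kind`` are read.  Units: D_trans in
    cm^2/s, D_rot in rad^2/ps, distances/radii/noise in Angstrom, stage
    durations in ns, switch rates per ns, dt in ps.
    """

    kind: str
    dt: float = 1.0
    n_frames: int = 1000
    seed: int = 0
    D_trans: float = 0.27e-5
    D_rot: float = 30.7e-5
    stage_distances: tuple = (25.0, 17.0, 16.0)
    stage_durations: tuple = (200.0, 300.0, 500.0)
    noise_sigma: float = 0.5
    ou_relaxation_frames: float = 100.0
    switch_rate_fwd: float = 0.5
    switch_rate_rev: float = 0.5
    # default patch: a mutually adjacent ligand group on the default
    # 60-anchor Fibonacci layout
    patch_ligand_ids: tuple = (17, 22, 25, 30, 38, 43)
    confinement_radius: float = 3.0
    contact_distance: float = 2.0
    box_length: float = 200.0  # A

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigError(f"unknown generator kind {self.kind!r}")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.noise_sigma < 0 or self.confinement_radius <= 0:
            raise ConfigError("noise and radii must be positive")
        if any(d <= 0 for d in self.stage_durations):
            raise ConfigError("stage durations must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Per-frame labels plus the true generator parameters."""

    spec: dict
    stage_labels: np.ndarray | None = None
    conformer_labels: np.ndarray | None = None
    bound_flags: np.ndarray | None = None
    patch_ligand_ids: tuple | None = None
    extras: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x
        return {
            "spec": self.spec,
            "stage_labels": conv(self.stage_labels),
            "conformer_labels": conv(self.conformer_labels),
            "bound_flags": conv(self.bound_flags),
            "patch_ligand_ids": self.patch_ligand_ids,
            "extras": {k: conv(v) for k, v in self.extras.items()},
        }
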