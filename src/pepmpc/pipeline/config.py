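"""Pipeline configuration (YAML-backed)."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import yaml

from ..errors import ConfigError
from ..bd_docking.config import DockingConfig


@dataclass
class PipelineConfig:
    """Settings for one end-to-end run.

    The docking sub-config is desk-scaled by default (few short runs);
    production-scale counts can be restored through the ``docking``
    mapping of the YAML file.
    """

    sequence: str = "HWDDD"
    output_dir: str = "pepmpc_out"
    seed: int = 0
    # nanocluster geometry
    n_core: int = 144
    n_ligands: int = 60
    chain_beads: int = 9
    core_radius: float = 0.9            # nm
    # analysis cutoffs
    ligand_contact_cutoff: float = 3.0  # A, inclusive
    docking_contact_cutoff: float = 3.5  # A, strict
    cluster_cutoff_nm: float = 0.1
    # synthetic refinement stage
    n_refine_frames: int = 400
    refine_dt: float = 10.0             # ps
    n_patch_ligands: int = 4
    stage_distances: tuple = (25.0, 17.0, 16.0)
    stage_durations: tuple = (0.5, 0.75, 1.0)   # ns, desk scale
    docking: DockingConfig = field(default_factory=lambda: DockingConfig(
        n_runs=4, run_length=0.5, n_record=200, start_separation=35.0))
    required_files: tuple = ()

    def validate(self) -> None:
        if not self.sequence:
            raise ConfigError("sequence must be non-empty")
        if self.n_refine_frames < 10:
            raise ConfigError("n_refine_frames too small")
        for path in self.required_files:
            if not os.path.exists(path):
                raise ConfigError(f"required file missing: {path}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["docking"] = self.docking.to_dict()
        return d


def load_pipeline_config(path: str) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    docking_raw = raw.pop("docking", {})
    cfg = PipelineConfig(**raw)
    if docking_raw:
        base = cfg.docking.to_dict()
        base.update(docking_raw)
        base.pop("grid_points", None)
        cfg.docking = DockingConfig(**base)
    cfg.validate()
    return cfg
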