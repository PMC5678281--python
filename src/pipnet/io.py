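"""CSV schemas, run configuration and manifests.

Panel CSV schema (one row per replicate measurement):
    genotype, inhibitor, species, time_s, replicate, value, sd

Trajectory CSV schema: time_s, one column per species, then one
``flux_<reaction id>`` column per reaction.

Every run driven by the CLI writes a ``manifest.json`` capturing the
configuration hash, the seed and the package version, so any output is
regenerable from config plus seed alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .fitting import ExperimentData
from .fluxes import FluxDecomposition
from .model import InhibitorEvent
from .simulate import Protocol, Trajectory

__all__ = [
    "PANEL_COLUMNS",
    "panel_to_frame",
    "panel_to_csv",
    "panel_from_csv",
    "trajectory_to_csv",
    "decomposition_to_frame",
    "RunConfig",
    "write_manifest",
]

PANEL_COLUMNS = ["genotype", "inhibitor", "species", "time_s", "replicate",
                 "value", "sd"]


def panel_to_frame(experiments: Sequence[ExperimentData]) -> pd.DataFrame:
    rows = []
    for exp in experiments:
        obs = exp.observations.copy()
        obs.insert(0, "genotype", exp.genotype.name)
        obs.insert(1, "inhibitor", exp.protocol.inhibitor is not None)
        if "sd" not in obs.columns:
            obs["sd"] = 0.0
        rows.append(obs[PANEL_COLUMNS])
    return pd.concat(rows, ignore_index=True)


def panel_to_csv(experiments: Sequence[ExperimentData], path: str) -> None:
    panel_to_frame(experiments).to_csv(path, index=False)


def panel_from_csv(
    path: str,
    inhibitor_time: float = 60.0,
    t_end: float = 900.0,
) -> list[ExperimentData]:
    """Read a panel CSV back into experiment objects.

    Genotype names are resolved against the built-in panel; the inhibitor
    column selects the +PI3K-inhibitor protocol arm (full inhibition at
    ``inhibitor_time``).
    """
    from .synth import GENOTYPES

    frame = pd.read_csv(path)
    missing = set(PANEL_COLUMNS) - {"sd"} - set(frame.columns)
    if missing:
        raise ValueError(f"panel CSV missing columns {sorted(missing)}")
    experiments = []
    for (geno_name, inh), block in frame.groupby(["genotype", "inhibitor"],
                                                 sort=False):
        if geno_name not in GENOTYPES:
            raise KeyError(f"unknown genotype {geno_name!r} in panel CSV")
        times = tuple(sorted(block["time_s"].unique()))
        proto = Protocol(
            inhibitor=InhibitorEvent(inhibitor_time, 0.0) if inh else None,
            t_end=t_end,
            output_times=times,
        )
        obs = block[[c for c in ("species", "time_s", "replicate", "value", "sd")
                     if c in block.columns]].reset_index(drop=True)
        experiments.append(ExperimentData(genotype=GENOTYPES[geno_name],
                                          protocol=proto, observations=obs))
    return experiments


def trajectory_to_csv(trajectory: Trajectory, path: str) -> None:
    trajectory.to_frame().to_csv(path, index=False)


def decomposition_to_frame(decomp: FluxDecomposition) -> pd.DataFrame:
    return pd.DataFrame(
        [{"genotype": decomp.genotype, "route": route, "max_flux": flux,
          "window_start_s": decomp.window[0], "window_end_s": decomp.window[1]}
         for route, flux in decomp.maxima.items()]
    )


@dataclass
class RunConfig:
    """Configuration of one CLI run."""

    command: str
    model_source: str = "builtin"
    genotype: str = "WT"
    egf_dose: float = 1.0
    inhibitor: bool = False
    inhibitor_time: float = 60.0
    t_end: float = 900.0
    cv: float = 0.15
    seed: int = 0
    out_dir: str = "."
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_manifest(config: RunConfig, out_dir: Optional[str] = None) -> Path:
    from . import __version__

    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": config.command,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
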