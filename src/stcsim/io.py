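"""Configuration, snapshots and tabular result serialization.

Everything is plain text: YAML configs, JSON snapshots (exact float
round-trip via repr), headered TSV for user-supplied interaction matrices
and fitness vectors, and tidy CSV for trajectories and epoch summaries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community import Community
from .evolution import EpochSummary
from .params import ModelParams, ParameterError

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "save_snapshot",
    "load_snapshot",
    "export_interactions",
    "import_interactions",
    "export_fitnesses",
    "import_fitnesses",
    "summaries_to_frame",
    "write_summaries",
    "read_summaries",
    "write_trajectory",
]


@dataclass
class RunConfig:
    """Model parameters plus run control; (config, seed) reproduces a run."""

    params: ModelParams = dataclasses.field(default_factory=ModelParams)
    T_max: int = 100
    mode: str = "unrelated"
    checkpoint_every: int = 10
    window_fraction: float = 0.5
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.T_max < 0:
            raise ParameterError(f"T_max must be >= 0, got {self.T_max}")
        if self.mode not in ("unrelated", "mutant"):
            raise ParameterError(f"mode must be 'unrelated' or 'mutant', got {self.mode}")
        if not 0 < self.window_fraction <= 1:
            raise ParameterError("window_fraction must lie in (0, 1]")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(
            T_max=self.T_max,
            mode=self.mode,
            checkpoint_every=self.checkpoint_every,
            window_fraction=self.window_fraction,
            replicates=self.replicates,
        )
        return d


_RUN_KEYS = ("T_max", "mode", "checkpoint_every", "window_fraction", "replicates")


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config; missing keys take defaults, unknown keys error.

    Config keys mirror the ``ModelParams`` field names exactly, plus the
    run-control keys ``T_max``, ``mode``, ``checkpoint_every``,
    ``window_fraction`` and ``replicates``.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ParameterError(f"config must be a key-value document, got {type(data)}")
    param_fields = {f.name for f in dataclasses.fields(ModelParams)}
    problems = [k for k in data if k not in param_fields and k not in _RUN_KEYS]
    if problems:
        raise ParameterError(f"unknown config keys: {sorted(problems)}")
    params = ModelParams.from_dict({k: v for k, v in data.items() if k in param_fields})
    run_kwargs = {k: data[k] for k in _RUN_KEYS if k in data}
    return RunConfig(params=params, **run_kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config as canonically sorted YAML (byte-stable round trip)."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False)
    )


def save_snapshot(community: Community, path: str | Path) -> None:
    """Write the full community state (params, V, s, nu, t, registry) as JSON."""
    Path(path).write_text(json.dumps(community.to_dict()))


def load_snapshot(path: str | Path) -> Community:
    return Community.from_dict(json.loads(Path(path).read_text()))


def export_interactions(V: np.ndarray, ids: np.ndarray, path: str | Path) -> None:
    """Write an interaction matrix as headered TSV (row/col = strain ids)."""
    df = pd.DataFrame(V, index=ids, columns=ids)
    df.to_csv(path, sep="\t", index_label="strain_id", float_format="%.17g")


def import_interactions(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col="strain_id", float_precision="round_trip")
    ids = df.index.to_numpy(dtype=int)
    cols = df.columns.to_numpy(dtype=int)
    if not np.array_equal(ids, cols):
        raise ValueError("interaction TSV row and column ids disagree")
    return df.to_numpy(dtype=float), ids


def export_fitnesses(s: np.ndarray, ids: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"strain_id": ids, "s": s}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def import_fitnesses(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df["s"].to_numpy(dtype=float), df["strain_id"].to_numpy(dtype=int)


def summaries_to_frame(summaries: list[EpochSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])


def write_summaries(summaries: list[EpochSummary], path: str | Path) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)


def read_summaries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_trajectory(
    times: np.ndarray,
    traj: np.ndarray,
    ids: np.ndarray,
    path: str | Path,
) -> None:
    """Tidy trajectory CSV with columns (t, strain_id, island, nu)."""
    n_t, n_strains, n_islands = traj.shape
    t_col = np.repeat(times, n_strains * n_islands)
    id_col = np.tile(np.repeat(ids, n_islands), n_t)
    isl_col = np.tile(np.arange(n_islands), n_t * n_strains)
    pd.DataFrame(
        {"t": t_col, "strain_id": id_col, "island": isl_col, "nu": traj.ravel()}
    ).to_csv(path, index=False)
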