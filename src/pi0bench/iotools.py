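"""Configuration loading, run manifests, file output, and test fixtures."""

from __future__ import annotations

import dataclasses
import getpass
import hashlib
import json
import logging
import socket
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import (PValueSet, SimulationConfig, bum_mixture_pvalues,
                        simulate_study, uniform_grid_pvalues)

__all__ = [
    "load_config",
    "resolve_simulation_config",
    "RunManifest",
    "write_study_csv",
    "write_pvalues",
    "read_pvalues",
    "generate_fixture",
]

logger = logging.getLogger("pi0bench")

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}

#: keys accepted in a sweep configuration file, beyond simulation settings
_SWEEP_FIELDS = {"pi0_grid", "rho_grid", "n_grid", "R", "threshold",
                 "master_seed", "reference"}


def load_config(path: str | Path, sweep: bool = False) -> dict:
    """Load and validate a YAML/JSON configuration file.

    Missing keys get the documented defaults; unknown keys are rejected by
    name.  With ``sweep=True``, grid/replication keys are also accepted.
    Loading is idempotent: dumping the resolved form and reloading it gives
    the same resolved form.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    allowed = _SIM_FIELDS | (_SWEEP_FIELDS if sweep else set())
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    sim_kwargs = {k: v for k, v in raw.items() if k in _SIM_FIELDS}
    resolved = asdict(SimulationConfig(**sim_kwargs))  # validates ranges
    if sweep:
        resolved["pi0_grid"] = list(raw.get("pi0_grid", [resolved["pi0"]]))
        resolved["rho_grid"] = list(raw.get("rho_grid", [resolved["rho"]]))
        if "n_grid" in raw:
            resolved["n_grid"] = list(raw["n_grid"])
        resolved["R"] = int(raw.get("R", 100))
        resolved["threshold"] = float(raw.get("threshold", 1e-5))
        resolved["master_seed"] = int(raw.get("master_seed", 0))
        resolved["reference"] = str(raw.get("reference", "ZG04"))
    return resolved


def resolve_simulation_config(resolved: dict) -> SimulationConfig:
    """Build a SimulationConfig from a resolved configuration mapping."""
    return SimulationConfig(**{k: v for k, v in resolved.items()
                               if k in _SIM_FIELDS})


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every command's outputs."""

    command: str
    config: dict
    seed: int | None
    version: str = ""
    started: str = ""
    finished: str = ""
    outputs: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__
            self.version = __version__
        if not self.started:
            self.started = datetime.now(timezone.utc).isoformat()

    def add_output(self, path: str | Path) -> None:
        path = Path(path)
        self.outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: str | Path) -> Path:
        self.finished = datetime.now(timezone.utc).isoformat()
        path = Path(path)
        record = dataclasses.asdict(self)
        try:
            record["host"] = socket.gethostname()
            record["user"] = getpass.getuser()
        except OSError:
            pass
        path.write_text(json.dumps(record, indent=2, default=str) + "\n")
        return path


# ---------------------------------------------------------------------------
# file formats: expression studies and p-value vectors
# ---------------------------------------------------------------------------

def write_study_csv(study, prefix: str | Path) -> tuple[Path, Path]:
    """Write a study as <prefix>.csv (genes x arrays, condition header row)
    plus <prefix>.truth.csv (gene, is_null, true_effect)."""
    prefix = Path(prefix)
    expr_path = prefix.with_suffix(".csv")
    n = study.values.shape[1]
    cols = [f"{c}_{i}" for i, c in enumerate(study.condition)]
    pd.DataFrame(study.values, columns=cols,
                 index=pd.Index([f"gene_{g}" for g in range(study.n_genes)],
                                name="gene")).to_csv(expr_path)
    truth_path = prefix.with_suffix(".truth.csv")
    pd.DataFrame({
        "gene": [f"gene_{g}" for g in range(study.n_genes)],
        "is_null": study.is_null.astype(int),
        "true_effect": study.true_effect,
    }).to_csv(truth_path, index=False)
    return expr_path, truth_path


def write_pvalues(pvals: PValueSet, path: str | Path) -> Path:
    """Single-column CSV of p-values (JSON if the path ends in .json)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps({
            "p": pvals.p.tolist(), "df": pvals.df,
            "config_digest": pvals.config_digest,
        }) + "\n")
    else:
        pd.DataFrame({"p": pvals.p}).to_csv(path, index=False)
    return path


def read_pvalues(path: str | Path) -> PValueSet:
    """Read a p-value vector from single-column CSV or JSON."""
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        return PValueSet(p=np.asarray(data["p"], float),
                         df=int(data.get("df", 0)),
                         config_digest=data.get("config_digest", ""))
    frame = pd.read_csv(path)
    return PValueSet(p=frame.iloc[:, 0].to_numpy(float), df=0,
                     config_digest=path.name)


# ---------------------------------------------------------------------------
# deterministic fixtures shared by the test suite and the CLI
# ---------------------------------------------------------------------------

def generate_fixture(kind: str, seed: int = 0, **kwargs):
    """Small deterministic datasets: 'uniform_grid_pvalues' (M=100 grid),
    'bum_mixture_pvalues' (M=5000 BUM draw), or 'tiny_study' (10 genes)."""
    if kind == "uniform_grid_pvalues":
        return uniform_grid_pvalues(kwargs.get("M", 100))
    if kind == "bum_mixture_pvalues":
        return bum_mixture_pvalues(M=kwargs.get("M", 5000),
                                   w=kwargs.get("w", 0.7),
                                   a=kwargs.get("a", 0.2), seed=seed)
    if kind == "tiny_study":
        cfg = SimulationConfig(M=kwargs.get("M", 10), pi0=kwargs.get("pi0", 0.8),
                               rho=kwargs.get("rho", 0.0), k=kwargs.get("k", 5),
                               n1=kwargs.get("n1", 4), n2=kwargs.get("n2", 4),
                               seed=seed)
        return simulate_study(cfg)
    raise ValueError(f"unknown fixture kind {kind!r}")
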