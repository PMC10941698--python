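"""Run-configuration files and on-disk simulation results (delimited text)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from . import timegrid
from .engine import SimulationConfig, SimulationResult
from .parameters import InterventionSpec


def intervention_from_dict(d: dict) -> InterventionSpec:
    start = d.get("start", 2023)
    start_month = timegrid.month_index(int(start)) if start < 10000 else int(start)
    return InterventionSpec(
        pop=pd.Series(d.get("pop", {}), dtype=float),
        ppfp=pd.Series(d.get("ppfp", {}), dtype=float),
        start_month=start_month,
    )


def intervention_to_dict(iv: InterventionSpec) -> dict:
    return {"start": timegrid.year_of(iv.start_month),
            "pop": {k: float(v) for k, v in iv.pop.items() if v != 1.0},
            "ppfp": {k: float(v) for k, v in iv.ppfp.items() if v != 1.0}}


def load_config(path: str | Path) -> SimulationConfig:
    """Read a run configuration (YAML: agents, start, end, seed, intervention...)."""
    d = yaml.safe_load(Path(path).read_text())
    iv = intervention_from_dict(d["intervention"]) if d.get("intervention") else None
    return SimulationConfig(
        n_agents=int(d["agents"]),
        start_month=timegrid.month_index(int(d["start"])),
        end_month=timegrid.month_index(int(d["end"])),
        seed=int(d.get("seed", 0)),
        intervention=iv,
        scale_target_population=(int(d["scale_target_population"])
                                 if d.get("scale_target_population") else None),
    )


def save_result(result: SimulationResult, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.monthly.to_csv(out / "monthly.csv", index_label="month")
    result.events.to_csv(out / "events.csv", index=False)
    result.appointments.to_csv(out / "appointments.csv", index=False)
    result.pyramids.to_csv(out / "pyramids.csv", index=False)
    cfg = result.config
    meta = {
        "agents": cfg.n_agents,
        "start": timegrid.year_of(cfg.start_month),
        "end": timegrid.year_of(cfg.end_month),
        "seed": cfg.seed,
        "scale_target_population": cfg.scale_target_population,
        "intervention": (intervention_to_dict(cfg.intervention)
                         if cfg.intervention else None),
        "n_rescaled": result.n_rescaled,
    }
    (out / "config.yaml").write_text(yaml.safe_dump(meta))
    return out


def load_result(result_dir: str | Path) -> SimulationResult:
    d = Path(result_dir)
    meta = yaml.safe_load((d / "config.yaml").read_text())
    iv = (intervention_from_dict(meta["intervention"])
          if meta.get("intervention") else None)
    cfg = SimulationConfig(
        n_agents=int(meta["agents"]),
        start_month=timegrid.month_index(int(meta["start"])),
        end_month=timegrid.month_index(int(meta["end"])),
        seed=int(meta.get("seed", 0)),
        intervention=iv,
        scale_target_population=meta.get("scale_target_population"),
    )
    return SimulationResult(
        monthly=pd.read_csv(d / "monthly.csv", index_col="month"),
        events=pd.read_csv(d / "events.csv"),
        appointments=pd.read_csv(d / "appointments.csv"),
        pyramids=pd.read_csv(d / "pyramids.csv"),
        config=cfg,
        n_rescaled=int(meta.get("n_rescaled", 0)),
    )
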