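"""Run configuration: a validated, file-round-trippable description of a run.

Configs are JSON or YAML; unknown keys are rejected loudly so a typo in a
field name cannot silently fall back to a default.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .acquisition import PSOSettings
from .ego import EGOConfig, ProblemSpec
from .space import SolutionSpace

__all__ = ["RunConfig", "load_config", "build_problem"]


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PSOConfig(_Forbid):
    swarm_size: int = 40
    iterations: int = 200
    inertia: float = 0.7298
    cognitive: float = 1.49618
    social: float = 1.49618


class ProblemConfig(_Forbid):
    """Either a built-in problem name or a user factory 'pkg.module:function'.

    A user factory is imported and called with ``params`` as keyword
    arguments; it must return a (ProblemSpec, simulator) pair, the
    simulator implementing the TrialSimulator contract.
    """

    name: str | None = None
    module: str | None = None
    params: dict = Field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = Field(default_factory=dict)
    ref_point: list[float] | None = None

    @field_validator("name")
    @classmethod
    def _known(cls, v: str | None) -> str | None:
        if v is not None and v not in {"cluster", "pace"}:
            raise ValueError(f"unknown problem {v!r}; choose 'cluster' or 'pace'")
        return v

    @model_validator(mode="after")
    def _one_source(self) -> "ProblemConfig":
        if (self.name is None) == (self.module is None):
            raise ValueError("give exactly one of problem 'name' or 'module'")
        return self


class EGOSection(_Forbid):
    iterations: int = 30
    initial_design_size: int | None = None
    n_per_eval: int = 100
    quantile_level: float = 0.9
    seed: int = 0
    pso: PSOConfig = Field(default_factory=PSOConfig)
    gp_restarts: int = 10


class RunConfig(_Forbid):
    problem: ProblemConfig
    ego: EGOSection = Field(default_factory=EGOSection)
    output_dir: str = "ssdopt_output"

    def ego_config(self, checkpoint_path: str | None = None) -> EGOConfig:
        p = self.ego.pso
        return EGOConfig(
            iterations=self.ego.iterations,
            initial_design_size=self.ego.initial_design_size,
            n_per_eval=self.ego.n_per_eval,
            quantile_level=self.ego.quantile_level,
            root_seed=self.ego.seed,
            pso=PSOSettings(
                swarm_size=p.swarm_size,
                iterations=p.iterations,
                inertia=p.inertia,
                cognitive=p.cognitive,
                social=p.social,
            ),
            gp_restarts=self.ego.gp_restarts,
            checkpoint_path=checkpoint_path,
        )


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return RunConfig.model_validate(data)


def _override_space(space: SolutionSpace, bounds: dict) -> SolutionSpace:
    if not bounds:
        return space
    lower = space.lower.copy()
    upper = space.upper.copy()
    for name, (lo, hi) in bounds.items():
        if name not in space.names:
            raise ValueError(f"unknown design parameter {name!r} in bounds")
        i = space.names.index(name)
        lower[i], upper[i] = lo, hi
    return SolutionSpace(space.names, lower, upper, space.integer)


def build_problem(cfg: ProblemConfig) -> tuple[ProblemSpec, object]:
    """Instantiate a built-in problem from its config section."""
    from .problems import (
        ClusterTrialParams,
        MultilevelTrialParams,
        default_cluster_space,
        default_multilevel_space,
        make_cluster_problem,
        make_pace_problem,
    )
    from dataclasses import replace as dc_replace

    if cfg.module is not None:
        import importlib

        mod_name, _, attr = cfg.module.partition(":")
        if not attr:
            raise ValueError("user problem must be 'package.module:factory'")
        factory = getattr(importlib.import_module(mod_name), attr)
        problem, sim = factory(**cfg.params)
        if cfg.bounds:
            problem = dc_replace(problem, space=_override_space(problem.space, cfg.bounds))
        if cfg.ref_point is not None:
            problem = dc_replace(problem, ref_point=np.asarray(cfg.ref_point, dtype=float))
        return problem, sim
    if cfg.name == "cluster":
        params = ClusterTrialParams(**cfg.params)
        space = _override_space(default_cluster_space(), cfg.bounds)
        problem, sim = make_cluster_problem(params, space)
    else:
        extra = {
            k: v for k, v in cfg.params.items()
            if k in {"type2_threshold", "type1_threshold", "decision_rule"}
        }
        core = {k: v for k, v in cfg.params.items() if k not in extra}
        if "effect" in core:
            core["effect"] = tuple(core["effect"])
        params = MultilevelTrialParams(**core)
        space = _override_space(default_multilevel_space(), cfg.bounds)
        problem, sim = make_pace_problem(params, space=space, **extra)
    if cfg.ref_point is not None:
        problem = dc_replace(problem, ref_point=np.asarray(cfg.ref_point, dtype=float))
    return problem, sim
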