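"""Run configuration: a YAML-backed description of a complete simulation.

All physical quantities are CGS (cm, g, s): density in g/cm^3, viscosity in
g/(cm s), flow rate per unit depth in cm^2/s.  Unknown keys are rejected so
that typos fail loudly; every defaulted field is visible in ``to_dict``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .fem import FluidProperties
from .geometry import (DeformationParams, ModularGeometry, build_chain,
                       build_tree)
from .interface_basis import build_basis_set
from .timestepping import BDFScheme, InflowSpec, NewtonConfig

__all__ = ["RunConfig", "load_config", "build_geometry_from_config"]


@dataclass
class GeometryConfig:
    type: str = "chain"  # 'chain' | 'tree'
    kinds: list = field(default_factory=lambda: ["T1", "T1"])
    trunk: list = field(default_factory=list)
    branches: list = field(default_factory=list)
    resolution: int = 6
    params: dict = field(default_factory=dict)  # subdomain index -> value dict


@dataclass
class DiscretizationConfig:
    dt: float = 2.5e-3
    t_end: float = 0.3
    bdf_order: int = 2
    basis_degree: int = 5


@dataclass
class SolverConfig:
    newton_tol: float = 1e-6
    max_iter: int = 20
    exact_tangent: bool = True
    linear: str = "direct"  # 'direct' | 'block'
    policy: str = "simple"  # local inverse policy for 'block'
    krylov_tol: float = 1e-8
    n_reuse: int = 20


@dataclass
class RomConfig:
    eps_u: float = 1e-3
    eps_p: float = 1e-4
    n_configurations: int = 5
    halfwidth_ratio: float = 0.10
    halfwidth_angle_deg: float = 10.0
    n_c: int | None = None
    use_tensor: bool = False
    archive: str = "basis_archive"


@dataclass
class InflowConfig:
    Q0: float = 1.0
    t_ramp: float = -2.0e-2
    t0: float = 0.0


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    inflow: InflowConfig = field(default_factory=InflowConfig)
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    rom: RomConfig = field(default_factory=RomConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str):
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {
            "geometry": GeometryConfig,
            "fluid": FluidProperties,
            "inflow": InflowConfig,
            "discretization": DiscretizationConfig,
            "solver": SolverConfig,
            "rom": RomConfig,
        }
        kwargs = {}
        for key, val in data.items():
            if key == "seed":
                kwargs["seed"] = int(val)
                continue
            if key not in sections:
                raise ValueError(f"unknown configuration key '{key}'")
            klass = sections[key]
            fields = {f for f in klass.__dataclass_fields__}
            unknown = set(val) - fields
            if unknown:
                raise ValueError(f"unknown key(s) {sorted(unknown)} in section '{key}'")
            kwargs[key] = klass(**val)
        return cls(**kwargs)

    # --- object builders --------------------------------------------------
    def scheme(self) -> BDFScheme:
        return BDFScheme(self.discretization.bdf_order, self.discretization.dt)

    def newton(self) -> NewtonConfig:
        return NewtonConfig(tol=self.solver.newton_tol, max_iter=self.solver.max_iter,
                            exact_tangent=self.solver.exact_tangent)

    def inflow_spec(self) -> InflowSpec:
        return InflowSpec(Q0=self.inflow.Q0, t_ramp=self.inflow.t_ramp, t0=self.inflow.t0)

    def basis(self):
        return build_basis_set(2, self.discretization.basis_degree)


def load_config(path: str) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f)
    return RunConfig.from_dict(data or {})


def _params_list(cfg: GeometryConfig, kinds: list) -> list:
    out = []
    for j, kind in enumerate(kinds):
        vals = cfg.params.get(j, cfg.params.get(str(j)))
        if vals is None:
            out.append(DeformationParams.identity(kind))
        else:
            base = DeformationParams.identity(kind)
            merged = dict(base.values)
            merged.update(vals)
            out.append(DeformationParams(merged))
    return out


def build_geometry_from_config(cfg: GeometryConfig) -> ModularGeometry:
    if cfg.type == "chain":
        return build_chain(cfg.kinds, _params_list(cfg, cfg.kinds), cfg.resolution)
    if cfg.type == "tree":
        kinds = list(cfg.trunk) + ["B"] + [k for br in cfg.branches for k in br]
        params = _params_list(cfg, kinds)
        pdict = {j: p for j, p in enumerate(params)}
        return build_tree(cfg.trunk, tuple(cfg.branches), pdict, cfg.resolution)
    raise ValueError(f"unknown geometry type '{cfg.type}'")


def geometry_factory_from_config(cfg: GeometryConfig):
    """(kinds, base_params, factory) for the offline sampling loop."""
    if cfg.type == "chain":
        kinds = list(cfg.kinds)
        factory = lambda params: build_chain(kinds, params, cfg.resolution)
    elif cfg.type == "tree":
        kinds = list(cfg.trunk) + ["B"] + [k for br in cfg.branches for k in br]

        def factory(params):
            pdict = {j: p for j, p in enumerate(params)}
            return build_tree(cfg.trunk, tuple(cfg.branches), pdict, cfg.resolution)
    else:
        raise ValueError(f"unknown geometry type '{cfg.type}'")
    base = _params_list(cfg, kinds)
    return kinds, base, factory
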