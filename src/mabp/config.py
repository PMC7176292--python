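"""Run configuration: a single YAML mapping, schema-validated.

Units are fixed package-wide (Å, ps, kcal/mol, radians; see
:mod:`mabp.units`) and documented field by field in :data:`SCHEMA`.
Configurations round-trip losslessly through YAML, and every run embeds
its configuration plus a content hash in its output manifest for
provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .bias_grid import BiasGrid, GridSpec
from .cvs import RestraintSet
from .potentials import ToySystem, make_system

#: Field-by-field schema (name -> (type, required, unit/meaning)).
SCHEMA = {
    "system.name": (str, True, "toy system: double_well | harmonic | cosine_well | mueller_brown | host_guest"),
    "system.params": (dict, False, "keyword overrides for the system (Å, ps, kcal/mol)"),
    "grid.bins": (list, True, "bins per CV dimension"),
    "grid.lo": (list, True, "lower CV range per dim (Å or rad)"),
    "grid.hi": (list, True, "upper CV range per dim (Å or rad)"),
    "grid.periodic": (list, True, "periodic flag per dim"),
    "bias.b": (float, False, "bias fraction in (0,1)"),
    "bias.c": (float, False, "deposition rate per time step (0 disables the potential)"),
    "bias.alpha": (int, False, "mollifier half-width, bins"),
    "bias.flim": (float, False, "overfill fill-limit, kcal/mol (0 disables deposition)"),
    "bias.kT": (float, False, "thermal energy, kcal/mol"),
    "restraints.cylinder_radius": (float, False, "flat-bottom cylinder radius, Å"),
    "restraints.cv_cap": (float, False, "maximal allowed CV value, Å"),
    "restraints.k": (float, False, "restraint force constant, kcal/mol/Å²"),
    "n_steps": (int, True, "number of dynamics steps"),
    "stride": (int, True, "frame/CV save stride, steps"),
    "seed": (int, True, "RNG seed"),
}


@dataclass
class RunConfig:
    """Machine-readable home of a full sampler run."""

    system_name: str
    system_params: dict = field(default_factory=dict)
    grid_bins: tuple = (480,)
    grid_lo: tuple = (0.0,)
    grid_hi: tuple = (60.0,)
    grid_periodic: tuple = (False,)
    b: float = 0.9
    c: float = 0.005
    alpha: int = 20
    flim: float = 17.0
    kT: float = 0.6163
    use_restraints: bool = False
    cylinder_radius: float = 18.0
    cv_cap: float = 22.0
    restraint_k: float = 10.0
    n_steps: int = 10000
    stride: int = 10
    seed: int = 0

    # ------------------------------------------------------------- builders

    def build_system(self) -> ToySystem:
        return make_system(self.system_name, **self.system_params)

    def build_grid(self) -> BiasGrid:
        return BiasGrid(
            GridSpec(
                bins=tuple(self.grid_bins),
                lo=tuple(self.grid_lo),
                hi=tuple(self.grid_hi),
                periodic=tuple(self.grid_periodic),
                b=self.b,
                c=self.c,
                alpha=self.alpha,
                flim=self.flim,
                kT=self.kT,
            )
        )

    def build_restraints(self) -> RestraintSet | None:
        if not self.use_restraints:
            return None
        return RestraintSet(
            cylinder_radius=self.cylinder_radius,
            cv_cap=self.cv_cap,
            k_cyl=self.restraint_k,
            k_cap=self.restraint_k,
        )

    # ---------------------------------------------------------------- (de)ser

    def to_dict(self) -> dict:
        d = {
            "system": {"name": self.system_name, "params": dict(self.system_params)},
            "grid": {
                "bins": list(self.grid_bins),
                "lo": list(self.grid_lo),
                "hi": list(self.grid_hi),
                "periodic": list(bool(p) for p in self.grid_periodic),
            },
            "bias": {
                "b": self.b,
                "c": self.c,
                "alpha": self.alpha,
                "flim": self.flim,
                "kT": self.kT,
            },
            "n_steps": self.n_steps,
            "stride": self.stride,
            "seed": self.seed,
        }
        if self.use_restraints:
            d["restraints"] = {
                "cylinder_radius": self.cylinder_radius,
                "cv_cap": self.cv_cap,
                "k": self.restraint_k,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def need(mapping, key, ctx):
            if key not in mapping:
                raise ValueError(f"config missing required key '{ctx}{key}'")
            return mapping[key]

        system = need(d, "system", "")
        grid = need(d, "grid", "")
        bias = d.get("bias", {})
        restr = d.get("restraints")
        bins = [int(b) for b in need(grid, "bins", "grid.")]
        lo = [float(x) for x in need(grid, "lo", "grid.")]
        hi = [float(x) for x in need(grid, "hi", "grid.")]
        periodic = [bool(p) for p in need(grid, "periodic", "grid.")]
        if not (len(bins) == len(lo) == len(hi) == len(periodic)):
            raise ValueError("grid bins/lo/hi/periodic must have equal lengths")
        cfg = cls(
            system_name=str(need(system, "name", "system.")),
            system_params=dict(system.get("params", {})),
            grid_bins=tuple(bins),
            grid_lo=tuple(lo),
            grid_hi=tuple(hi),
            grid_periodic=tuple(periodic),
            b=float(bias.get("b", 0.9)),
            c=float(bias.get("c", 0.005)),
            alpha=int(bias.get("alpha", 20)),
            flim=float(bias.get("flim", 17.0)),
            kT=float(bias.get("kT", 0.6163)),
            use_restraints=restr is not None,
            n_steps=int(need(d, "n_steps", "")),
            stride=int(need(d, "stride", "")),
            seed=int(need(d, "seed", "")),
        )
        if restr is not None:
            cfg.cylinder_radius = float(restr.get("cylinder_radius", 18.0))
            cfg.cv_cap = float(restr.get("cv_cap", 22.0))
            cfg.restraint_k = float(restr.get("k", 10.0))
        # fail fast on invalid physics
        cfg.build_grid()
        cfg.build_system()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(d)

    def hash(self) -> str:
        """Stable content hash for provenance stamping."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
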