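"""Seeded BAOAB Langevin dynamics coupled to the adaptive bias.

The integrator advances the toy system under the total force

    F_total = -∇U  -  Σ_k (∂V/∂cv_k) ∇cv_k  -  ∇(restraints)

with one mollified bias deposit per step at the current CV point. Runs
are pure functions of ``(system, configuration, seed)``: the same seed
reproduces trajectories bit-identically, and a run with the bias disabled
(``c = 0`` or ``flim = 0``) consumes the random stream identically to an
unbiased run, so the two are comparable step by step.

An external engine can reuse the same coupling by calling
:func:`bias_and_restraint_forces` from its own force loop (provider
contract: give coordinates, receive bias + restraint forces).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bias_grid import BiasGrid
from .cvs import RestraintSet, restraint_energy_force
from .potentials import ToySystem
from .units import KCAL_MOL_TO_AMU_A2_PS2

logger = logging.getLogger(__name__)

#: Coordinates beyond this magnitude (Å) abort the run as a numerical blow-up.
BLOWUP_THRESHOLD = 1.0e3


@dataclass
class Trajectory:
    """Saved frames, CV trace and provenance of one run.

    ``cv_trace`` is recomputed from the stored frames by the same CV
    objects that drove the run, so it is bit-identically reproducible
    from ``frames``.
    """

    frames: np.ndarray  # (n_saved, n_particles, dim)
    cv_trace: np.ndarray  # (n_saved, n_cvs)
    times: np.ndarray  # ps
    stride: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def to_xyz(self, path, labels=None) -> None:
        """Write frames as multi-model XYZ (coordinates padded to 3D)."""
        n = self.frames.shape[1]
        labels = labels or ["C"] * n
        with open(path, "w") as fh:
            for k in range(self.n_frames):
                fh.write(f"{n}\n")
                fh.write(f"frame {k} time_ps {self.times[k]:.6f}\n")
                xyz = np.zeros((n, 3))
                xyz[:, : self.frames.shape[2]] = self.frames[k]
                for lab, row in zip(labels, xyz):
                    fh.write(
                        f"{lab} {row[0]:.6f} {row[1]:.6f} {row[2]:.6f}\n"
                    )

    def cv_to_tsv(self, path, cv_labels=None) -> None:
        ncv = self.cv_trace.shape[1]
        cv_labels = cv_labels or [f"cv{i + 1}" for i in range(ncv)]
        with open(path, "w") as fh:
            fh.write("time_ps\t" + "\t".join(cv_labels) + "\n")
            for t, row in zip(self.times, self.cv_trace):
                vals = "\t".join(f"{v:.6f}" for v in row)
                fh.write(f"{t:.6f}\t{vals}\n")


def read_xyz(path) -> tuple[np.ndarray, list[str]]:
    """Read a multi-model XYZ file; returns (frames (n, atoms, 3), labels)."""
    frames = []
    labels: list[str] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i])
        block = lines[i + 2 : i + 2 + n]
        coords = np.empty((n, 3))
        labels = []
        for j, ln in enumerate(block):
            parts = ln.split()
            labels.append(parts[0])
            coords[j] = [float(p) for p in parts[1:4]]
        frames.append(coords)
        i += 2 + n
    return np.array(frames), labels


def read_cv_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a CV trace TSV; returns (times, cv_trace)."""
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    return data[:, 0], data[:, 1:]


def bias_and_restraint_forces(
    system: ToySystem,
    coords: np.ndarray,
    cvs,
    grid: BiasGrid | None,
    restraints: RestraintSet | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bias + restraint forces on all particles at given coordinates.

    Returns ``(forces, cv_values)``. This is the provider contract for
    coupling an external coordinate/force engine to the bias.
    """
    f = np.zeros_like(coords, dtype=float)
    if not cvs:
        return f, np.empty(0)
    vals = np.empty(len(cvs))
    grads = []
    for k, cv in enumerate(cvs):
        vals[k], g = cv.gradient(coords)
        grads.append(g)
    if grid is not None:
        _, dv_dcv = grid.bias_potential_and_force(vals)
        for k in range(len(cvs)):
            if dv_dcv[k] != 0.0:
                f -= dv_dcv[k] * grads[k]
    if restraints is not None:
        lig = list(getattr(system, "ligand_indices", range(coords.shape[0])))
        cog = coords[lig].mean(axis=0)
        origin = system.restraint_origin(coords)
        _, f_cog, de_dcv = restraint_energy_force(cog, vals, restraints, origin)
        f[lig] += f_cog / len(lig)
        for k in range(len(cvs)):
            if de_dcv[k] != 0.0:
                f -= de_dcv[k] * grads[k]
    return f, vals


def _run(
    system: ToySystem,
    cvs,
    n_steps: int,
    stride: int,
    seed: int,
    grid: BiasGrid | None = None,
    restraints: RestraintSet | None = None,
) -> Trajectory:
    if grid is not None and cvs is not None and grid.n_dims != len(cvs):
        raise ValueError(
            f"CV dimensionality ({len(cvs)}) does not match grid "
            f"({grid.n_dims}D)"
        )
    cvs = cvs or []
    rng = np.random.default_rng(seed)
    x = system.initial_coords(rng).astype(float).copy()
    masses = system.masses.astype(float)[:, None]
    mobile = system.mobile[:, None]
    dt = system.dt
    conv = KCAL_MOL_TO_AMU_A2_PS2

    c1 = np.exp(-system.friction * dt)
    sigma_v = np.sqrt(system.kT * conv / masses)
    c2 = sigma_v * np.sqrt(1.0 - c1 * c1)

    v = rng.standard_normal(x.shape) * sigma_v
    v[~mobile[:, 0]] = 0.0

    def total_force(coords):
        u, f = system.energy_forces(coords)
        fb, vals = bias_and_restraint_forces(system, coords, cvs, grid, restraints)
        return f + fb, vals

    def cv_values(coords):
        return np.array([cv.value(coords) for cv in cvs]) if cvs else np.empty(0)

    f_tot, cv_now = total_force(x)
    frames, trace, times = [], [], []
    half = 0.5 * dt

    for step in range(n_steps):
        if grid is not None and cvs:
            grid.deposit(cv_now)
        # BAOAB splitting
        v += half * f_tot * conv / masses
        x += half * v * mobile
        v = c1 * v + c2 * rng.standard_normal(x.shape)
        v[~mobile[:, 0]] = 0.0
        x += half * v * mobile
        f_tot, cv_now = total_force(x)
        v += half * f_tot * conv / masses

        if (step + 1) % stride == 0:
            frames.append(x.copy())
            trace.append(cv_now.copy())
            times.append((step + 1) * dt)
            if np.max(np.abs(x)) > BLOWUP_THRESHOLD:
                raise RuntimeError(
                    f"numerical blow-up at step {step + 1}: "
                    f"max |coordinate| = {np.max(np.abs(x)):.3g} Å "
                    f"(dt or forces too large)"
                )

    meta = {
        "system": system.name,
        "seed": int(seed),
        "n_steps": int(n_steps),
        "stride": int(stride),
        "dt_ps": float(dt),
        "kT": float(system.kT),
        "friction_per_ps": float(system.friction),
        "biased": grid is not None,
    }
    return Trajectory(
        frames=np.array(frames),
        cv_trace=np.array(trace) if cvs else np.empty((len(frames), 0)),
        times=np.array(times),
        stride=stride,
        metadata=meta,
    )


def run_mabp(
    system: ToySystem,
    cvs,
    grid: BiasGrid,
    restraints: RestraintSet | None,
    n_steps: int,
    stride: int,
    seed: int,
) -> tuple[Trajectory, BiasGrid]:
    """Biased (mABP) run: one kernel deposit per step, bias force coupled
    through the CV gradients. Returns the trajectory and the filled grid."""
    traj = _run(system, cvs, n_steps, stride, seed, grid=grid, restraints=restraints)
    return traj, grid


def run_unbiased(
    system: ToySystem,
    cvs,
    n_steps: int,
    stride: int,
    seed: int,
) -> Trajectory:
    """Unbiased reference run with identical seed handling to the biased one."""
    return _run(system, cvs, n_steps, stride, seed)
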