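"""Analytic toy systems for the sampler.

These are desk-scale stand-ins for the membrane receptor systems the
method is designed for: every shipped potential has an analytic free
energy along its declared CVs (for a toy, the landscape *is* the potential
up to a constant), so bias-recovery accuracy can be measured exactly.

Units follow :mod:`mabp.units`: Å, kcal/mol, ps, amu.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .bias_grid import BiasGrid, GridSpec
from .cvs import (
    AtomGroup,
    CoordinateCV,
    DynamicReference,
    RestraintSet,
    RMSDistanceCV,
)


class ToySystem:
    """Base interface: particle layout, thermostat parameters and forces."""

    name: str = "toy"
    dim: int = 1
    kT: float = units.DEFAULT_KT
    friction: float = 20.0  # 1/ps
    dt: float = 0.002  # ps

    @property
    def n_particles(self) -> int:
        return len(self.masses)

    @property
    def masses(self) -> np.ndarray:
        raise NotImplementedError

    @property
    def mobile(self) -> np.ndarray:
        """Boolean mask of particles the integrator moves."""
        return np.ones(self.n_particles, dtype=bool)

    def initial_coords(self, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def energy_forces(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        raise NotImplementedError

    def default_cvs(self):
        raise NotImplementedError


@dataclass
class DoubleWell1D(ToySystem):
    """One particle in U(x) = h (x² − 1)² kcal/mol.

    Barrier height ``h`` between the wells at x = ±1 Å. The free energy
    along x is U itself, which makes this the primary accuracy oracle.
    """

    h: float = 2.0
    kT: float = units.DEFAULT_KT
    friction: float = 20.0
    dt: float = 0.002
    mass: float = 1.0
    x0: float = -1.0

    name = "double_well"
    dim = 1

    @property
    def masses(self) -> np.ndarray:
        return np.array([self.mass])

    def initial_coords(self, rng) -> np.ndarray:
        return np.array([[self.x0]], dtype=float)

    def potential(self, x):
        return self.h * (np.asarray(x) ** 2 - 1.0) ** 2

    def energy_forces(self, x):
        q = float(x[0, 0])
        u = self.h * (q * q - 1.0) ** 2
        f = -4.0 * self.h * q * (q * q - 1.0)
        return u, np.array([[f]])

    def default_cvs(self):
        return [CoordinateCV(0, 0, label="x")]

    def analytic_fes(self, centers: np.ndarray) -> np.ndarray:
        u = self.potential(centers)
        return u - u.min()


@dataclass
class Harmonic1D(ToySystem):
    """One particle in U(x) = ½ k x²; equipartition oracle (var x = kT/k)."""

    k: float = 2.0
    kT: float = units.DEFAULT_KT
    friction: float = 20.0
    dt: float = 0.002
    mass: float = 1.0

    name = "harmonic"
    dim = 1

    @property
    def masses(self) -> np.ndarray:
        return np.array([self.mass])

    def initial_coords(self, rng) -> np.ndarray:
        return np.zeros((1, 1))

    def energy_forces(self, x):
        q = float(x[0, 0])
        return 0.5 * self.k * q * q, np.array([[-self.k * q]])

    def default_cvs(self):
        return [CoordinateCV(0, 0, label="x")]


@dataclass
class CosineWell1D(ToySystem):
    """Periodic 1D toy U(θ) = h (1 − cos θ): the dihedral-mode stand-in.

    The coordinate is treated as an angle in radians on a periodic grid
    over [0, 2π).
    """

    h: float = 2.0
    kT: float = units.DEFAULT_KT
    friction: float = 20.0
    dt: float = 0.002
    mass: float = 1.0
    theta0: float = 0.0

    name = "cosine_well"
    dim = 1

    @property
    def masses(self) -> np.ndarray:
        return np.array([self.mass])

    def initial_coords(self, rng) -> np.ndarray:
        return np.array([[self.theta0]], dtype=float)

    def potential(self, theta):
        return self.h * (1.0 - np.cos(np.asarray(theta)))

    def energy_forces(self, x):
        q = float(x[0, 0])
        return self.h * (1.0 - np.cos(q)), np.array([[-self.h * np.sin(q)]])

    def default_cvs(self):
        return [CoordinateCV(0, 0, label="theta")]

    def analytic_fes(self, centers: np.ndarray) -> np.ndarray:
        u = self.potential(centers)
        return u - u.min()


# Classic Müller–Brown surface parameters (dimensionless) and an energy
# scale mapping its ~146-unit global well onto a few kcal/mol.
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


@dataclass
class MuellerBrown2D(ToySystem):
    """Scaled Müller–Brown surface: a 2D sum of anisotropic Gaussians.

    Three minima connected by two saddles; globally confining. With the
    default scale 0.04 the deepest well sits ~5.9 kcal/mol below zero and
    the largest barrier out of it is ~3 kcal/mol.
    """

    scale: float = 0.04
    kT: float = units.DEFAULT_KT
    friction: float = 20.0
    dt: float = 0.001
    mass: float = 1.0

    name = "mueller_brown"
    dim = 2

    #: CV-grid window covering the three wells.
    domain = ((-1.75, 1.25), (-0.5, 2.25))
    #: Location of the global minimum (unscaled MB convention).
    global_minimum = (-0.558, 1.442)

    @property
    def masses(self) -> np.ndarray:
        return np.array([self.mass])

    def initial_coords(self, rng) -> np.ndarray:
        return np.array([[0.62, 0.03]])  # shallowest-well basin

    def potential(self, x, y):
        x = np.asarray(x, dtype=float)[..., None]
        y = np.asarray(y, dtype=float)[..., None]
        e = (
            _MB_a * (x - _MB_x0) ** 2
            + _MB_b * (x - _MB_x0) * (y - _MB_y0)
            + _MB_c * (y - _MB_y0) ** 2
        )
        return self.scale * np.sum(_MB_A * np.exp(e), axis=-1)

    def energy_forces(self, x):
        px, py = float(x[0, 0]), float(x[0, 1])
        dx = px - _MB_x0
        dy = py - _MB_y0
        e = _MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2
        terms = _MB_A * np.exp(e)
        u = self.scale * terms.sum()
        dudx = self.scale * np.sum(terms * (2 * _MB_a * dx + _MB_b * dy))
        dudy = self.scale * np.sum(terms * (_MB_b * dx + 2 * _MB_c * dy))
        return u, np.array([[-dudx, -dudy]])

    def default_cvs(self):
        return [CoordinateCV(0, 0, label="x"), CoordinateCV(0, 1, label="y")]

    def analytic_fes(self, cx: np.ndarray, cy: np.ndarray) -> np.ndarray:
        u = self.potential(cx[:, None], cy[None, :])
        return u - u.min()


@dataclass
class HostGuest3D(ToySystem):
    """A 3D host–guest binding toy exercising the full binding construction.

    The "ligand" is a 4-particle chain split into two 2-atom groups (the
    flexible and rigid moieties of the two-RMS-distance CV construction);
    the "receptor" is six fixed dummy Cα atoms forming the two dynamic
    reference selections below the binding pocket at the origin. The
    pocket is a set of per-atom Gaussian wells pinned at the constructed
    bound pose, so the bound state has a definite pose (and hence a
    definite CV cell) rather than a free-rotating minimum.

    Along the +z approach axis the ligand center of geometry sees, in
    order: a flat solvent region, a Gaussian gate ridge (the binding
    barrier), the pocket, a tall wall, and a decoy well behind it — the
    tunable spurious-escape channel that an overfilled bias can push the
    ligand through. Flat-bottom walls confine the toy laterally and in z
    so unbiased runs remain bounded without restraints.
    """

    pocket_depth: float = 2.0  # kcal/mol per ligand atom (pose wells)
    pocket_sigma: float = 0.7  # Å
    funnel_depth: float = 2.0  # wide COG capture well, kcal/mol
    funnel_sigma: float = 2.0  # Å
    gate_height: float = 8.0
    gate_z: float = 2.5
    gate_sigma: float = 0.8  # steep pocket side
    gate_sigma_out: float = 3.0  # wide solvent-side ramp
    wall_height: float = 16.0
    wall_z: float = -1.8
    wall_sigma: float = 0.6
    decoy_depth: float = 1.0
    decoy_z: float = -3.2
    decoy_sigma: float = 0.8
    bond_k: float = 100.0  # kcal/mol/Å²
    bond_r0: float = 1.5  # Å
    confine_radius: float = 2.0  # lateral flat-bottom wall, Å
    confine_z: tuple[float, float] = (-4.5, 8.0)
    confine_k: float = 10.0
    start_z: float = 7.0
    kT: float = units.DEFAULT_KT
    friction: float = 2.0
    dt: float = 0.005
    ligand_mass: float = 12.0

    name = "host_guest"
    dim = 3

    # particle layout: 0-3 ligand chain, 4-6 reference A, 7-9 reference B
    ligand_indices = (0, 1, 2, 3)
    group1_indices = (0, 1)
    group2_indices = (2, 3)
    ref1_indices = (4, 5, 6)
    ref2_indices = (7, 8, 9)

    _receptor_coords = np.array(
        [
            [-2.0, 0.0, -3.0], [-1.5, 0.5, -3.0], [-1.0, -0.5, -3.0],  # ref A
            [1.0, 0.5, -3.0], [1.5, -0.5, -3.0], [2.0, 0.0, -3.0],  # ref B
        ]
    )

    @property
    def masses(self) -> np.ndarray:
        return np.concatenate([np.full(4, self.ligand_mass), np.full(6, 1e9)])

    @property
    def mobile(self) -> np.ndarray:
        m = np.zeros(10, dtype=bool)
        m[list(self.ligand_indices)] = True
        return m

    def _ligand_chain(self, cog: np.ndarray) -> np.ndarray:
        offs = (np.arange(4) - 1.5) * self.bond_r0
        pts = np.zeros((4, 3))
        pts[:, 0] = offs
        return pts + np.asarray(cog)

    def initial_coords(self, rng) -> np.ndarray:
        x = np.empty((10, 3))
        x[:4] = self._ligand_chain(np.array([0.0, 0.0, self.start_z]))
        x[4:] = self._receptor_coords
        return x

    def bound_coords(self) -> np.ndarray:
        """The constructed pocket pose (ligand chain centered on the pocket)."""
        x = np.empty((10, 3))
        x[:4] = self._ligand_chain(np.zeros(3))
        x[4:] = self._receptor_coords
        return x

    # ------------------------------------------------------------- energy

    def _axial_profile(self, z: float) -> tuple[float, float]:
        """z-dependent site terms on the ligand COG: (U, dU/dz).

        The gate ridge is asymmetric: a wide ramp on the solvent side
        (so the adaptive bias can climb it cell by cell) and a steep
        flank on the pocket side (so its tail does not raise the pocket).
        Both halves share the crest value and zero slope there, keeping
        the profile C¹.
        """
        u = 0.0
        du = 0.0
        sig_gate = self.gate_sigma_out if z > self.gate_z else self.gate_sigma
        for height, z0, sig in (
            (self.gate_height, self.gate_z, sig_gate),
            (self.wall_height, self.wall_z, self.wall_sigma),
        ):
            g = height * np.exp(-((z - z0) ** 2) / (2 * sig**2))
            u += g
            du += -g * (z - z0) / sig**2
        return u, du

    def energy_forces(self, x):
        lig = x[:4]
        u = 0.0
        f = np.zeros_like(x)

        # ligand chain bonds
        for i in range(3):
            d = lig[i + 1] - lig[i]
            r = float(np.linalg.norm(d))
            ex = r - self.bond_r0
            u += 0.5 * self.bond_k * ex * ex
            fb = -self.bond_k * ex * d / r
            f[i + 1] += fb
            f[i] -= fb

        cog = lig.mean(axis=0)
        grad_cog = np.zeros(3)

        # pocket: per-atom wells pinned at the constructed bound pose,
        # plus a wide COG funnel that captures approaches below the gate
        pose = self._ligand_chain(np.zeros(3))
        d_pose = lig - pose
        r2 = np.sum(d_pose * d_pose, axis=1)
        gp = -self.pocket_depth * np.exp(-r2 / (2 * self.pocket_sigma**2))
        u += float(gp.sum())
        f[:4] += gp[:, None] * d_pose / self.pocket_sigma**2

        gf = -self.funnel_depth * np.exp(
            -float(np.dot(cog, cog)) / (2 * self.funnel_sigma**2)
        )
        u += gf
        grad_cog += -gf * cog / self.funnel_sigma**2

        # axial gate / wall / decoy profile on the COG
        ua, dua = self._axial_profile(float(cog[2]))
        u += ua
        grad_cog[2] += dua

        # decoy well behind the wall (3D Gaussian on the COG)
        d_dec = cog - np.array([0.0, 0.0, self.decoy_z])
        gd = -self.decoy_depth * np.exp(
            -float(np.dot(d_dec, d_dec)) / (2 * self.decoy_sigma**2)
        )
        u += gd
        grad_cog += -gd * d_dec / self.decoy_sigma**2

        # flat-bottom confinement (solvent box stand-in)
        rho = float(np.hypot(cog[0], cog[1]))
        if rho > self.confine_radius:
            ex = rho - self.confine_radius
            u += 0.5 * self.confine_k * ex * ex
            grad_cog[:2] += self.confine_k * ex * np.array(cog[:2]) / rho
        zlo, zhi = self.confine_z
        if cog[2] < zlo:
            u += 0.5 * self.confine_k * (cog[2] - zlo) ** 2
            grad_cog[2] += self.confine_k * (cog[2] - zlo)
        elif cog[2] > zhi:
            u += 0.5 * self.confine_k * (cog[2] - zhi) ** 2
            grad_cog[2] += self.confine_k * (cog[2] - zhi)

        f[:4] -= grad_cog / 4.0
        return float(u), f

    # ---------------------------------------------------------- CV plumbing

    def default_cvs(self):
        ref1 = DynamicReference(AtomGroup(self.ref1_indices, "refA"))
        ref2 = DynamicReference(AtomGroup(self.ref2_indices, "refB"))
        return [
            RMSDistanceCV(AtomGroup(self.group1_indices, "lig-flex"), ref1, "CV1"),
            RMSDistanceCV(AtomGroup(self.group2_indices, "lig-rigid"), ref2, "CV2"),
        ]

    def restraint_origin(self, coords: np.ndarray) -> np.ndarray:
        """Geometric center of the two CV reference points."""
        r1 = coords[list(self.ref1_indices)].mean(axis=0)
        r2 = coords[list(self.ref2_indices)].mean(axis=0)
        return 0.5 * (r1 + r2)

    def default_restraints(self) -> RestraintSet:
        return RestraintSet(cylinder_radius=3.0, cv_cap=12.5)

    def default_grid(self, flim: float = 20.0) -> BiasGrid:
        """Toy-scaled analogue of the binding CV grid.

        Coarser bins and a much larger deposition rate than the receptor
        setups: the toy must flood kcal/mol-scale wells within ~10⁵ steps
        rather than 10⁹.
        """
        return BiasGrid(
            GridSpec(
                bins=(16, 16),
                lo=(0.0, 0.0),
                hi=(16.0, 16.0),
                periodic=(False, False),
                b=0.9,
                c=0.3,
                alpha=3,
                flim=flim,
                kT=self.kT,
            )
        )

    def pocket_cv(self) -> np.ndarray:
        """CV values of the constructed pocket pose."""
        x = self.bound_coords()
        return np.array([cv.value(x) for cv in self.default_cvs()])

    #: Anchor point for the event-monitor distance; sits below the gate so
    #: the bound threshold can only be reached from inside the pocket (the
    #: analogue of the conserved aspartate carboxyl carbon).
    monitor_anchor = np.array([0.0, 0.0, -2.5])

    def monitor_distance(self, frames: np.ndarray) -> np.ndarray:
        """Anchor-to-amine-analog distance per frame (ligand atom 1 to the
        buried anchor), the series the hysteresis event criterion runs on."""
        frames = np.asarray(frames)
        if frames.ndim == 2:
            frames = frames[None]
        return np.linalg.norm(frames[:, 1, :] - self.monitor_anchor, axis=1)


_SYSTEMS = {
    "double_well": DoubleWell1D,
    "harmonic": Harmonic1D,
    "cosine_well": CosineWell1D,
    "mueller_brown": MuellerBrown2D,
    "host_guest": HostGuest3D,
}


def make_system(name: str, **params) -> ToySystem:
    """Instantiate a shipped toy system by name."""
    try:
        cls = _SYSTEMS[name]
    except KeyError:
        raise ValueError(
            f"unknown system '{name}'; available: {sorted(_SYSTEMS)}"
        ) from None
    return cls(**params)
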