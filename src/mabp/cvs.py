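"""Collective variables and binding-simulation restraints.

The ligand-binding CV construction follows the two-RMS-distance scheme:
the ligand is decomposed into two atom groups (e.g. a flexible and a rigid
moiety) and each group's RMS distance to a dynamically updated receptor
reference point — the center of geometry of a Cα selection — is one CV.
A flat-bottom cylindrical restraint around the receptor center plus a cap
on the CV values keeps the ligand from diffusing away.

A periodic torsion CV is provided for dihedral free-energy landscapes.
All analytic gradients follow the chain-rule contracts needed to couple
the grid bias into Langevin dynamics; they are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default cylindrical restraint radius, Å.
DEFAULT_CYLINDER_RADIUS = 18.0
#: Default cap on the RMS-distance CVs, Å.
DEFAULT_CV_CAP = 22.0
#: Default flat-bottom force constant, kcal/mol/Å².
DEFAULT_RESTRAINT_K = 10.0


@dataclass(frozen=True)
class AtomGroup:
    """A labelled set of atom indices (0-based)."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(idx) == 0:
            raise ValueError(f"atom group '{self.label}' is empty")
        if len(set(idx)) != len(idx):
            raise ValueError(f"atom group '{self.label}' has duplicate indices")
        if any(i < 0 for i in idx):
            raise ValueError(f"atom group '{self.label}' has negative indices")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class DynamicReference:
    """A reference point recomputed from current coordinates every call.

    The rule is center-of-geometry of the receptor selection, so the
    reference tracks receptor motion deterministically.
    """

    receptor_selection: AtomGroup

    def position(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords)[list(self.receptor_selection.indices)].mean(axis=0)


# --------------------------------------------------------------------- CV math


def rms_distance_cv(group_coords: np.ndarray, reference: np.ndarray) -> float:
    """RMS of the atom-to-point distances: sqrt((1/n) Σ ‖xᵢ − r‖²).

    A single-point reference admits no superposition, so this is the only
    self-consistent reading of an "RMSD to a center of geometry" CV.
    """
    x = np.atleast_2d(np.asarray(group_coords, dtype=float))
    if x.shape[0] == 0:
        raise ValueError("empty atom group")
    d = x - np.asarray(reference, dtype=float)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def rms_distance_gradient(
    group_coords: np.ndarray,
    reference: np.ndarray,
    n_reference_atoms: int = 1,
) -> tuple[float, np.ndarray, np.ndarray]:
    """CV value plus gradients w.r.t. ligand atoms and reference atoms.

    Returns ``(cv, grad_group, grad_ref_atom)`` where ``grad_group`` has one
    row per group atom (``(xᵢ − r)/(n·cv)``) and ``grad_ref_atom`` is the
    (identical) gradient row for *each* of the ``m`` reference atoms,
    ``−(1/m)·Σᵢ (xᵢ − r)/(n·cv)``, so the total gradient sums to zero.
    The gradient is singular at cv = 0 and defined as zero there.
    """
    x = np.atleast_2d(np.asarray(group_coords, dtype=float))
    r = np.asarray(reference, dtype=float)
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty atom group")
    d = x - r
    cv = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
    if cv == 0.0:
        return 0.0, np.zeros_like(x), np.zeros(x.shape[1])
    grad_group = d / (n * cv)
    grad_ref = -grad_group.sum(axis=0) / n_reference_atoms
    return cv, grad_group, grad_ref


def dihedral_cv(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, mapped to [0, 2π).

    Standard atan2 convention: zero for a planar cis arrangement, π for
    trans. Degenerate (collinear) geometry raises.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    b2n = np.linalg.norm(b2)
    if n1n < 1e-10 * b2n * np.linalg.norm(b1) or n2n < 1e-10 * b2n * np.linalg.norm(b3):
        raise ValueError("degenerate dihedral: three consecutive points collinear")
    phi = np.arctan2(np.dot(np.cross(n1, n2), b2) / b2n, np.dot(n1, n2))
    return float(phi % (2.0 * np.pi))


def dihedral_gradient(p1, p2, p3, p4) -> tuple[float, np.ndarray]:
    """Torsion value in [0, 2π) and its gradient w.r.t. the four points.

    Uses the classical normal-vector formulas; the gradient of the
    wrapped angle equals the gradient of the signed angle everywhere but
    at the branch cut, where the two differ by a constant only.
    """
    pts = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    phi = dihedral_cv(*pts)
    b1 = pts[1] - pts[0]
    b2 = pts[2] - pts[1]
    b3 = pts[3] - pts[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    g1 = -b2n / np.dot(n1, n1) * n1
    g4 = b2n / np.dot(n2, n2) * n2
    f = np.dot(b1, b2) / np.dot(b2, b2)
    h = np.dot(b3, b2) / np.dot(b2, b2)
    g2 = -(1.0 + f) * g1 + h * g4
    g3 = f * g1 - (1.0 + h) * g4
    return phi, np.stack([g1, g2, g3, g4])


# ------------------------------------------------------------------ CV objects


@dataclass(frozen=True)
class RMSDistanceCV:
    """RMS-distance CV between a ligand group and a dynamic receptor reference."""

    ligand: AtomGroup
    reference: DynamicReference
    label: str = ""

    def value(self, coords: np.ndarray) -> float:
        coords = np.asarray(coords)
        r = self.reference.position(coords)
        return rms_distance_cv(coords[list(self.ligand.indices)], r)

    def gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """CV value and a full-shape gradient array (zero off-group)."""
        coords = np.asarray(coords)
        r = self.reference.position(coords)
        m = len(self.reference.receptor_selection)
        cv, g_lig, g_ref = rms_distance_gradient(
            coords[list(self.ligand.indices)], r, n_reference_atoms=m
        )
        grad = np.zeros_like(coords, dtype=float)
        grad[list(self.ligand.indices)] = g_lig
        for i in self.reference.receptor_selection.indices:
            grad[i] += g_ref
        return cv, grad


@dataclass(frozen=True)
class DihedralCV:
    """Periodic torsion CV over four atoms."""

    atoms: tuple[int, int, int, int]
    label: str = ""

    def value(self, coords: np.ndarray) -> float:
        coords = np.asarray(coords)
        return dihedral_cv(*(coords[i] for i in self.atoms))

    def gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = np.asarray(coords)
        phi, g = dihedral_gradient(*(coords[i] for i in self.atoms))
        grad = np.zeros_like(coords, dtype=float)
        for row, i in zip(g, self.atoms):
            grad[i] = row
        return phi, grad


@dataclass(frozen=True)
class CoordinateCV:
    """A bare Cartesian coordinate as CV — used by the analytic toy systems."""

    particle: int = 0
    axis: int = 0
    label: str = ""

    def value(self, coords: np.ndarray) -> float:
        return float(np.asarray(coords)[self.particle, self.axis])

    def gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = np.asarray(coords)
        grad = np.zeros_like(coords, dtype=float)
        grad[self.particle, self.axis] = 1.0
        return self.value(coords), grad


# ------------------------------------------------------------------ restraints


@dataclass(frozen=True)
class RestraintSet:
    """Flat-bottom restraints confining the ligand near the receptor.

    A cylindrical wall of radius ``cylinder_radius`` about ``cylinder_axis``
    through the receptor center, combined with a harmonic cap on each CV
    above ``cv_cap``. Energy is exactly zero strictly inside both flat
    regions and C¹-continuous at the boundaries.
    """

    cylinder_radius: float = DEFAULT_CYLINDER_RADIUS
    cylinder_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    cv_cap: float = DEFAULT_CV_CAP
    k_cyl: float = DEFAULT_RESTRAINT_K
    k_cap: float = DEFAULT_RESTRAINT_K

    def __post_init__(self) -> None:
        ax = np.asarray(self.cylinder_axis, dtype=float)
        nrm = np.linalg.norm(ax)
        if nrm == 0:
            raise ValueError("cylinder axis must be a nonzero vector")
        object.__setattr__(self, "cylinder_axis", tuple(ax / nrm))
        if self.cylinder_radius <= 0 or self.cv_cap <= 0:
            raise ValueError("cylinder radius and CV cap must be positive")
        if self.k_cyl < 0 or self.k_cap < 0:
            raise ValueError("force constants must be non-negative")


def restraint_energy_force(
    ligand_cog: np.ndarray,
    cv_values,
    restraints: RestraintSet,
    origin: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Flat-bottom restraint energy and its derivatives.

    Parameters
    ----------
    ligand_cog:
        Ligand center of geometry, Å.
    cv_values:
        Current values of the (one or two) RMS-distance CVs, Å.
    restraints:
        Restraint geometry and force constants.
    origin:
        Cylinder origin — the geometric center of the CV reference points,
        recomputed dynamically by the caller.

    Returns
    -------
    (energy, force_cog, de_dcv):
        Energy in kcal/mol, the force on the ligand COG (negative gradient,
        kcal/mol/Å) and dE/dcv per CV (to be chained through each CV's
        gradient by the integrator).
    """
    cog = np.asarray(ligand_cog, dtype=float)
    axis = np.asarray(restraints.cylinder_axis, dtype=float)
    cvs = np.atleast_1d(np.asarray(cv_values, dtype=float))

    d = cog - np.asarray(origin, dtype=float)
    d_perp = d - np.dot(d, axis) * axis
    rho = float(np.linalg.norm(d_perp))

    energy = 0.0
    force_cog = np.zeros(3)
    if rho > restraints.cylinder_radius:
        excess = rho - restraints.cylinder_radius
        energy += 0.5 * restraints.k_cyl * excess**2
        force_cog -= restraints.k_cyl * excess * d_perp / rho

    de_dcv = np.zeros(len(cvs))
    over = cvs > restraints.cv_cap
    if over.any():
        exc = cvs[over] - restraints.cv_cap
        energy += float(0.5 * restraints.k_cap * np.sum(exc**2))
        de_dcv[over] = restraints.k_cap * exc
    return energy, force_cog, de_dcv
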