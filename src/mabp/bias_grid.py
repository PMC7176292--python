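"""Grid-based mollified adaptive biasing potential (mABP) with overfill protection.

The sampler accumulates mollified sampling mass ``S`` on a 1D or 2D grid
over collective-variable space. The repulsive bias applied to the dynamics
is the flooding-type log form

    V(cell) = b * kT * ln(c * S(cell) + 1)

with bias fraction ``b`` in (0, 1), deposition rate ``c`` per time step and
a compact mollifier kernel of half-width ``alpha`` bins. Each visit deposits
kernel mass at the current CV value, importance-weighted by ``exp(V/kT)`` at
the deposit center so that ``S`` estimates the *unbiased* visit density and
the free-energy estimator ``F = -V/b`` converges to the true landscape
(without this weight the stationary bias solves ``V = -b/(1+b) * U`` and the
estimator would be low by the factor ``1+b``).

Overfill protection caps the bias at a fill-limit ``flim``: every deposit is
scaled by ``g = clip(1 - V_center/flim, 0, 1)``, which saturates the bias
smoothly and prevents it from pushing the system over unphysical barriers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .kernels import MollifierKernel
from .landscape import FESLandscape

_CHECKPOINT_MAGIC = "mabp-checkpoint"
_CHECKPOINT_VERSION = 1


@dataclass
class GridSpec:
    """Geometry and biasing parameters for a bias grid.

    ``c == 0`` and ``flim == 0`` are accepted as the documented
    disabled-bias limits (no potential / no deposition, respectively).
    """

    bins: tuple[int, ...]
    lo: tuple[float, ...]
    hi: tuple[float, ...]
    periodic: tuple[bool, ...]
    b: float = 0.9
    c: float = 0.005
    alpha: int = 20
    flim: float = 17.0
    kT: float = 0.6163

    def __post_init__(self) -> None:
        self.bins = tuple(int(b) for b in np.atleast_1d(self.bins))
        self.lo = tuple(float(x) for x in np.atleast_1d(self.lo))
        self.hi = tuple(float(x) for x in np.atleast_1d(self.hi))
        self.periodic = tuple(bool(p) for p in np.atleast_1d(self.periodic))


class BiasGrid:
    """Discretized CV-space accumulator for the mABP bias.

    Holds the mollified sampling mass ``S`` (``weight``), derives the bias
    potential lazily from it, and enforces the overfill cap at deposit
    centers. Supports 1 or 2 dimensions, each optionally periodic.
    """

    def __init__(self, spec: GridSpec):
        n_dims = len(spec.bins)
        if n_dims not in (1, 2):
            raise ValueError(f"only 1D and 2D grids are supported, got {n_dims}D")
        if not (len(spec.lo) == len(spec.hi) == len(spec.periodic) == n_dims):
            raise ValueError("bins/lo/hi/periodic must have matching lengths")
        for lo, hi in zip(spec.lo, spec.hi):
            if not hi > lo:
                raise ValueError(f"grid range requires hi > lo, got [{lo}, {hi}]")
        if not (0.0 < spec.b < 1.0):
            raise ValueError(f"bias fraction b must be in (0, 1), got {spec.b}")
        if spec.c < 0:
            raise ValueError(f"deposition rate c must be >= 0, got {spec.c}")
        if spec.flim < 0:
            raise ValueError(f"fill-limit flim must be >= 0, got {spec.flim}")
        if spec.kT <= 0:
            raise ValueError(f"kT must be positive, got {spec.kT}")
        if spec.alpha < 1:
            raise ValueError(f"alpha must be a positive integer, got {spec.alpha}")
        for nb in spec.bins:
            if nb < 2 * spec.alpha + 1:
                raise ValueError(
                    f"kernel wider than grid: need bins >= 2*alpha+1 = "
                    f"{2 * spec.alpha + 1}, got {nb}"
                )

        self.spec = spec
        self.kernel = MollifierKernel.quartic(spec.alpha)
        self.weight = np.zeros(spec.bins, dtype=float)
        self.step_count = 0
        self.clamped_deposits = 0
        if self.n_dims == 2:
            self._kernel2d = self.kernel.outer_2d()
            self._k_center = float(self._kernel2d[spec.alpha, spec.alpha])
        else:
            self._kernel2d = None
            self._k_center = float(self.kernel.profile[spec.alpha])

    # ------------------------------------------------------------ geometry

    @property
    def n_dims(self) -> int:
        return len(self.spec.bins)

    @property
    def bin_widths(self) -> tuple[float, ...]:
        s = self.spec
        return tuple((h - l) / b for l, h, b in zip(s.lo, s.hi, s.bins))

    def centers(self, dim: int) -> np.ndarray:
        w = self.bin_widths[dim]
        return self.spec.lo[dim] + (np.arange(self.spec.bins[dim]) + 0.5) * w

    def _center_index(self, cv: np.ndarray) -> tuple[tuple[int, ...], bool]:
        """Grid cell containing ``cv``; flags clamping on non-periodic dims."""
        idx = []
        clamped = False
        for d in range(self.n_dims):
            n = self.spec.bins[d]
            w = self.bin_widths[d]
            i = int(np.floor((cv[d] - self.spec.lo[d]) / w))
            if self.spec.periodic[d]:
                i %= n
            elif i < 0:
                i, clamped = 0, True
            elif i >= n:
                i, clamped = n - 1, True
            idx.append(i)
        return tuple(idx), clamped

    # ------------------------------------------------------- bias potential

    def _cell_bias(self, idx: tuple[int, ...]) -> float:
        """Raw bias potential of one cell, kcal/mol."""
        s = self.spec
        if s.c == 0.0:
            return 0.0
        return s.b * s.kT * float(np.log1p(s.c * self.weight[idx]))

    def bias_potential(self) -> np.ndarray:
        """Bias potential V over the whole grid, kcal/mol."""
        s = self.spec
        if s.c == 0.0:
            return np.zeros_like(self.weight)
        return s.b * s.kT * np.log1p(s.c * self.weight)

    # -------------------------------------------------------------- deposit

    def deposit(self, cv_value) -> float:
        """Deposit mollified kernel mass at a CV point.

        The deposit amount is ``g * exp(V_center/kT)`` with overfill factor
        ``g = clip(1 - V_center/flim, 0, 1)``; every touched cell is
        additionally clipped at the fill-limit, so no cell's bias can ever
        exceed ``flim``. Returns the total mass actually added inside the
        grid.
        """
        cv = np.atleast_1d(np.asarray(cv_value, dtype=float))
        if cv.shape != (self.n_dims,):
            raise ValueError(f"cv_value must have {self.n_dims} components")
        if not np.all(np.isfinite(cv)):
            raise ValueError(f"non-finite CV value in deposit: {cv}")
        self.step_count += 1
        return self._deposit_unchecked(cv)

    def _deposit_unchecked(self, cv: np.ndarray) -> float:
        s = self.spec
        if s.flim == 0.0:
            return 0.0
        idx, clamped = self._center_index(cv)
        if clamped:
            self.clamped_deposits += 1
        v_center = self._cell_bias(idx)
        g = min(max(1.0 - v_center / s.flim, 0.0), 1.0)
        if g == 0.0:
            return 0.0
        amount = g * float(np.exp(v_center / s.kT))
        s_cap = np.inf
        if s.c > 0.0:
            # hard cap: no cell may ever pass flim
            s_cap = float(np.expm1(s.flim / (s.b * s.kT))) / s.c
        if amount == 0.0:
            return 0.0
        return self._add_kernel(idx, amount, s_cap)

    def _add_kernel(
        self, idx: tuple[int, ...], amount: float, s_cap: float = np.inf
    ) -> float:
        """Add ``amount`` * kernel centered on cell ``idx``; cell values are
        clipped at ``s_cap`` (the fill-limit in mass units) so no cell ever
        passes the cap. Returns the mass actually added inside the grid."""
        a = self.spec.alpha
        if self.n_dims == 1:
            (i,) = idx
            n = self.spec.bins[0]
            lo, hi = i - a, i + a + 1
            if self.spec.periodic[0]:
                cells = np.arange(lo, hi) % n
                seg = amount * self.kernel.profile
            else:
                klo, khi = max(0, -lo), 2 * a + 1 - max(0, hi - n)
                seg = amount * self.kernel.profile[klo:khi]
                cells = np.arange(max(lo, 0), min(hi, n))
            old = self.weight[cells].copy()
            self.weight[cells] = np.minimum(old + seg, s_cap)
            return float(np.sum(self.weight[cells] - old))

        i, j = idx
        nx, ny = self.spec.bins
        k2 = self._kernel2d
        xlo, xhi = i - a, i + a + 1
        ylo, yhi = j - a, j + a + 1
        if self.spec.periodic[0]:
            xs = np.arange(xlo, xhi) % nx
            kxlo, kxhi = 0, 2 * a + 1
        else:
            kxlo, kxhi = max(0, -xlo), 2 * a + 1 - max(0, xhi - nx)
            xs = np.arange(max(xlo, 0), min(xhi, nx))
        if self.spec.periodic[1]:
            ys = np.arange(ylo, yhi) % ny
            kylo, kyhi = 0, 2 * a + 1
        else:
            kylo, kyhi = max(0, -ylo), 2 * a + 1 - max(0, yhi - ny)
            ys = np.arange(max(ylo, 0), min(yhi, ny))
        block = amount * k2[kxlo:kxhi, kylo:kyhi]
        sel = np.ix_(xs, ys)
        old = self.weight[sel].copy()
        self.weight[sel] = np.minimum(old + block, s_cap)
        return float(np.sum(self.weight[sel] - old))

    def deposit_many(self, points: np.ndarray) -> float:
        """Sequentially deposit many CV points; returns the maximum raw
        bias observed at any deposit-center cell immediately after its
        deposit (useful for verifying the overfill cap)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.n_dims:
            raise ValueError(f"points must have {self.n_dims} columns")
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite CV value in deposit")
        vmax = 0.0
        for cv in pts:
            self.step_count += 1
            self._deposit_unchecked(cv)
            idx, _ = self._center_index(cv)
            v = self._cell_bias(idx)
            if v > vmax:
                vmax = v
        return vmax

    # -------------------------------------------------- continuous bias

    def bias_potential_and_force(self, cv_value) -> tuple[float, np.ndarray]:
        """Multilinearly interpolated bias energy and its gradient at a point.

        Outside the range of a non-periodic dimension the edge value is
        returned with zero outward gradient; the energy is clipped at the
        fill-limit (zero gradient where clipped).
        """
        cv = np.atleast_1d(np.asarray(cv_value, dtype=float))
        s = self.spec
        grad = np.zeros(self.n_dims)
        if s.c == 0.0 or s.flim == 0.0:
            return 0.0, grad

        lo_idx = np.empty(self.n_dims, dtype=int)
        hi_idx = np.empty(self.n_dims, dtype=int)
        t = np.empty(self.n_dims)
        dscale = np.empty(self.n_dims)
        for d in range(self.n_dims):
            n = s.bins[d]
            w = self.bin_widths[d]
            u = (cv[d] - s.lo[d]) / w - 0.5
            if s.periodic[d]:
                f = np.floor(u)
                lo_idx[d] = int(f) % n
                hi_idx[d] = (lo_idx[d] + 1) % n
                t[d] = u - f
                dscale[d] = 1.0 / w
            elif u <= 0.0:
                lo_idx[d] = hi_idx[d] = 0
                t[d], dscale[d] = 0.0, 0.0
            elif u >= n - 1:
                lo_idx[d] = hi_idx[d] = n - 1
                t[d], dscale[d] = 0.0, 0.0
            else:
                f = np.floor(u)
                lo_idx[d] = int(f)
                hi_idx[d] = lo_idx[d] + 1
                t[d] = u - f
                dscale[d] = 1.0 / w

        if self.n_dims == 1:
            v0 = self._cell_bias((lo_idx[0],))
            v1 = self._cell_bias((hi_idx[0],))
            energy = (1 - t[0]) * v0 + t[0] * v1
            grad[0] = (v1 - v0) * dscale[0]
        else:
            v00 = self._cell_bias((lo_idx[0], lo_idx[1]))
            v01 = self._cell_bias((lo_idx[0], hi_idx[1]))
            v10 = self._cell_bias((hi_idx[0], lo_idx[1]))
            v11 = self._cell_bias((hi_idx[0], hi_idx[1]))
            tx, ty = t
            energy = (
                v00 * (1 - tx) * (1 - ty)
                + v01 * (1 - tx) * ty
                + v10 * tx * (1 - ty)
                + v11 * tx * ty
            )
            grad[0] = ((v10 - v00) * (1 - ty) + (v11 - v01) * ty) * dscale[0]
            grad[1] = ((v01 - v00) * (1 - tx) + (v11 - v10) * tx) * dscale[1]

        if energy >= s.flim:
            return s.flim, np.zeros(self.n_dims)
        return float(energy), grad

    # ------------------------------------------------------- free energy

    def free_energy_estimate(self) -> FESLandscape:
        """Free-energy landscape ``F = -V/b`` min-shifted over visited cells."""
        visited = self.weight > 0
        if not visited.any():
            raise ValueError("no sampling: bias grid is empty")
        F = np.where(visited, -self.bias_potential() / self.spec.b, np.nan)
        fes = FESLandscape(
            bins=self.spec.bins,
            lo=self.spec.lo,
            hi=self.spec.hi,
            periodic=self.spec.periodic,
            F=F,
            visited=visited,
            replicate_count=1,
        )
        fes.min_shift()
        return fes

    # ------------------------------------------------------- checkpointing

    def save(self, path) -> None:
        """Write a versioned ``.mabp`` checkpoint (JSON header + weights)."""
        s = self.spec
        header = {
            "format": _CHECKPOINT_MAGIC,
            "version": _CHECKPOINT_VERSION,
            "bins": list(s.bins),
            "lo": list(s.lo),
            "hi": list(s.hi),
            "periodic": [int(p) for p in s.periodic],
            "b": s.b,
            "c": s.c,
            "alpha": s.alpha,
            "flim": s.flim,
            "kT": s.kT,
            "step_count": self.step_count,
            "clamped_deposits": self.clamped_deposits,
        }
        with open(path, "wb") as fh:
            fh.write(json.dumps(header).encode() + b"\n")
            fh.write(np.ascontiguousarray(self.weight, dtype="<f8").tobytes())

    @classmethod
    def load(cls, path) -> "BiasGrid":
        with open(path, "rb") as fh:
            header_line = fh.readline()
            blob = fh.read()
        header = json.loads(header_line)
        if header.get("format") != _CHECKPOINT_MAGIC:
            raise ValueError(f"{path}: not a mabp checkpoint")
        if header["version"] != _CHECKPOINT_VERSION:
            raise ValueError(f"{path}: unsupported checkpoint version")
        spec = GridSpec(
            bins=tuple(header["bins"]),
            lo=tuple(header["lo"]),
            hi=tuple(header["hi"]),
            periodic=tuple(bool(p) for p in header["periodic"]),
            b=header["b"],
            c=header["c"],
            alpha=header["alpha"],
            flim=header["flim"],
            kT=header["kT"],
        )
        grid = cls(spec)
        grid.weight = np.frombuffer(blob, dtype="<f8").reshape(spec.bins).copy()
        grid.step_count = header["step_count"]
        grid.clamped_deposits = header.get("clamped_deposits", 0)
        return grid


def make_grid(
    bins,
    lo,
    hi,
    periodic=False,
    b: float = 0.9,
    c: float = 0.005,
    alpha: int = 20,
    flim: float = 17.0,
    kT: float = 0.6163,
) -> BiasGrid:
    """Create an empty bias grid.

    Scalars for ``bins``/``lo``/``hi``/``periodic`` describe a 1D grid;
    sequences describe one entry per dimension. The defaults are the
    binding-simulation biasing parameters (b=0.9, c=0.005 per step,
    alpha=20 bins).

    >>> g = make_grid(480, 0.0, 60.0)
    >>> g.bin_widths
    (0.125,)
    """
    bins_t = tuple(np.atleast_1d(bins).astype(int))
    n = len(bins_t)
    lo_t = tuple(np.broadcast_to(np.atleast_1d(lo).astype(float), (n,)))
    hi_t = tuple(np.broadcast_to(np.atleast_1d(hi).astype(float), (n,)))
    per_t = tuple(np.broadcast_to(np.atleast_1d(periodic).astype(bool), (n,)))
    spec = GridSpec(
        bins=bins_t, lo=lo_t, hi=hi_t, periodic=per_t,
        b=b, c=c, alpha=alpha, flim=flim, kT=kT,
    )
    return BiasGrid(spec)
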