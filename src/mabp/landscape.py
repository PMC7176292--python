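"""Free-energy landscapes over the collective-variable grid.

A :class:`FESLandscape` is the grid-shaped free-energy estimate produced
from a converged adaptive bias (``F = -V/b``, shifted so the minimum over
visited cells is zero), or an average of several such replicates. Cells
never visited by the dynamics carry no estimate and are excluded from all
statistics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

#: Default contour levels for exported landscapes, kcal/mol.
DEFAULT_CONTOUR_LEVELS = (1.0, 3.0, 5.0)


@dataclass
class FESLandscape:
    """Per-replicate or averaged free-energy estimate on a CV grid.

    Attributes
    ----------
    bins, lo, hi, periodic:
        Grid geometry per dimension (identical to the producing bias grid).
    F:
        Free energy per cell in kcal/mol, ``NaN`` where unvisited.
    visited:
        Boolean mask of cells with nonzero sampling mass.
    replicate_count:
        Number of independent runs averaged into this landscape.
    """

    bins: tuple[int, ...]
    lo: tuple[float, ...]
    hi: tuple[float, ...]
    periodic: tuple[bool, ...]
    F: np.ndarray = field(repr=False)
    visited: np.ndarray = field(repr=False)
    replicate_count: int = 1

    def __post_init__(self) -> None:
        self.bins = tuple(int(b) for b in self.bins)
        self.lo = tuple(float(x) for x in self.lo)
        self.hi = tuple(float(x) for x in self.hi)
        self.periodic = tuple(bool(p) for p in self.periodic)
        self.F = np.asarray(self.F, dtype=float)
        self.visited = np.asarray(self.visited, dtype=bool)
        if self.F.shape != self.bins:
            raise ValueError(f"F shape {self.F.shape} != bins {self.bins}")
        if self.visited.shape != self.bins:
            raise ValueError("visited mask shape mismatch")

    @property
    def n_dims(self) -> int:
        return len(self.bins)

    @property
    def bin_widths(self) -> tuple[float, ...]:
        return tuple(
            (h - l) / b for l, h, b in zip(self.lo, self.hi, self.bins)
        )

    def centers(self, dim: int) -> np.ndarray:
        """Cell-center coordinates along one dimension."""
        w = self.bin_widths[dim]
        return self.lo[dim] + (np.arange(self.bins[dim]) + 0.5) * w

    def same_geometry(self, other: "FESLandscape") -> bool:
        return (
            self.bins == other.bins
            and np.allclose(self.lo, other.lo)
            and np.allclose(self.hi, other.hi)
            and self.periodic == other.periodic
        )

    def min_shift(self) -> None:
        """Shift F in place so the minimum over visited cells is zero."""
        if not self.visited.any():
            raise ValueError("landscape has no visited cells")
        self.F = self.F - np.nanmin(self.F[self.visited])

    # ---------------------------------------------------------------- I/O

    def to_tsv(self, path) -> None:
        """Write the landscape as tab-separated text.

        Columns: cv per dimension, F in kcal/mol (NaN where unvisited) and
        a 0/1 visited flag. Grid geometry is carried in ``#`` header lines
        so the file round-trips.
        """
        buf = io.StringIO()
        buf.write("# mabp-fes v1\n")
        buf.write(f"# bins\t{'	'.join(str(b) for b in self.bins)}\n")
        buf.write(f"# lo\t{'	'.join(repr(x) for x in self.lo)}\n")
        buf.write(f"# hi\t{'	'.join(repr(x) for x in self.hi)}\n")
        buf.write(
            f"# periodic\t{'	'.join(str(int(p)) for p in self.periodic)}\n"
        )
        buf.write(f"# replicates\t{self.replicate_count}\n")
        cols = [f"cv{d + 1}" for d in range(self.n_dims)]
        buf.write("\t".join(cols + ["F_kcal_per_mol", "visited"]) + "\n")
        axes = [self.centers(d) for d in range(self.n_dims)]
        for idx in np.ndindex(*self.bins):
            coords = [f"{axes[d][idx[d]]:.6f}" for d in range(self.n_dims)]
            f = self.F[idx]
            fs = "nan" if not np.isfinite(f) else f"{f:.6f}"
            buf.write("\t".join(coords + [fs, str(int(self.visited[idx]))]) + "\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_tsv(cls, path) -> "FESLandscape":
        header: dict[str, list[str]] = {}
        values: list[float] = []
        flags: list[int] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# "):
                    parts = line[2:].split("\t")
                    header[parts[0]] = parts[1:]
                elif line.startswith("cv") or not line:
                    continue
                else:
                    parts = line.split("\t")
                    values.append(float(parts[-2]))
                    flags.append(int(parts[-1]))
        if "bins" not in header:
            raise ValueError(f"{path}: not a mabp FES file (missing header)")
        bins = tuple(int(b) for b in header["bins"])
        lo = tuple(float(x) for x in header["lo"])
        hi = tuple(float(x) for x in header["hi"])
        periodic = tuple(bool(int(p)) for p in header["periodic"])
        rep = int(header.get("replicates", ["1"])[0])
        F = np.array(values, dtype=float).reshape(bins)
        visited = np.array(flags, dtype=bool).reshape(bins)
        return cls(bins, lo, hi, periodic, F, visited, replicate_count=rep)

    def contour_lines(
        self, levels: tuple[float, ...] = DEFAULT_CONTOUR_LEVELS
    ) -> list[tuple[float, np.ndarray]]:
        """Iso-energy contour polylines of a 2D landscape.

        Returns ``(level, polyline)`` pairs where each polyline is an
        ``(n, 2)`` array of CV coordinates. Unvisited cells are treated as
        high-energy so contours close around the sampled region.
        """
        if self.n_dims != 2:
            raise ValueError("contour export requires a 2D landscape")
        from skimage import measure

        filled = np.where(self.visited, self.F, np.nanmax(self.F) + 1e3)
        out: list[tuple[float, np.ndarray]] = []
        w = self.bin_widths
        for level in levels:
            for seg in measure.find_contours(filled, level):
                cv = np.empty_like(seg)
                cv[:, 0] = self.lo[0] + (seg[:, 0] + 0.5) * w[0]
                cv[:, 1] = self.lo[1] + (seg[:, 1] + 0.5) * w[1]
                out.append((level, cv))
        return out

    def contours_to_tsv(
        self, path, levels: tuple[float, ...] = DEFAULT_CONTOUR_LEVELS
    ) -> None:
        """Write contour polylines as TSV (level, path_id, cv1, cv2)."""
        with open(path, "w") as fh:
            fh.write("level_kcal_per_mol\tpath_id\tcv1\tcv2\n")
            for pid, (level, line) in enumerate(self.contour_lines(levels)):
                for x, y in line:
                    fh.write(f"{level:g}\t{pid}\t{x:.6f}\t{y:.6f}\n")
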