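"""Landscape averaging, basin handling, frame extraction and pose clustering.

The post-processing pipeline mirrors standard practice for binding
free-energy landscapes: replicate landscapes are averaged cell-wise, a
square CV-space region around the averaged minimum is declared, all
trajectory frames inside it are extracted as a ligand-only subtrajectory,
and DBSCAN over the no-refit ligand RMSD metric picks the representative
bound pose (the medoid of the largest cluster). For 1D periodic dihedral
landscapes, basin occupancies are Boltzmann-weighted cell sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import DBSCAN

from .landscape import FESLandscape

#: Default DBSCAN pose-clustering parameters: minimum 25 points per cluster
#: with a 0.7 Å distance cutoff between points.
DEFAULT_CLUSTER_EPS = 0.7
DEFAULT_CLUSTER_MIN_PTS = 25

#: Basin expansion band above the local minimum, kcal/mol.
BASIN_EXPANSION_KCAL = 1.0


@dataclass(frozen=True)
class BasinRegion:
    """Axis-aligned CV-space box, e.g. the S1/S2/S3 dihedral basins."""

    lo: tuple[float, ...]
    hi: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        lo = tuple(float(x) for x in np.atleast_1d(self.lo))
        hi = tuple(float(x) for x in np.atleast_1d(self.hi))
        if len(lo) != len(hi):
            raise ValueError("basin lo/hi must have matching lengths")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def n_dims(self) -> int:
        return len(self.lo)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Closed-box membership of CV points, shape (n, n_dims)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((p >= lo) & (p <= hi), axis=1)


@dataclass
class ClusterResult:
    """DBSCAN pose-clustering outcome.

    ``labels`` follows scikit-learn conventions (−1 = noise). The
    representative frame is the medoid of the largest cluster — the member
    minimizing its summed RMSD to the rest of that cluster.
    """

    labels: np.ndarray
    representative: int | None
    medoids: dict[int, int]
    distance_to_medoid: np.ndarray
    eps: float
    min_pts: int

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("frame_id\tcluster\tdistance_to_medoid\n")
            for i, (lab, d) in enumerate(zip(self.labels, self.distance_to_medoid)):
                ds = f"{d:.6f}" if np.isfinite(d) else "nan"
                fh.write(f"{i}\t{lab}\t{ds}\n")


# ------------------------------------------------------------------ averaging


def average_landscapes(landscapes) -> FESLandscape:
    """Cell-wise mean of replicate landscapes.

    Each cell averages over the replicates that visited it; the visited
    mask of the result is the union, and the average is re-min-shifted.
    """
    landscapes = list(landscapes)
    if not landscapes:
        raise ValueError("need at least one landscape to average")
    first = landscapes[0]
    for other in landscapes[1:]:
        if not first.same_geometry(other):
            raise ValueError("landscapes have mismatched grid geometry")
    total = np.zeros(first.bins)
    count = np.zeros(first.bins, dtype=int)
    for fes in landscapes:
        m = fes.visited
        total[m] += fes.F[m]
        count[m] += 1
    visited = count > 0
    F = np.full(first.bins, np.nan)
    F[visited] = total[visited] / count[visited]
    out = FESLandscape(
        bins=first.bins,
        lo=first.lo,
        hi=first.hi,
        periodic=first.periodic,
        F=F,
        visited=visited,
        replicate_count=sum(l.replicate_count for l in landscapes),
    )
    out.min_shift()
    return out


# ----------------------------------------------------------------- basins


def _neighbor_shifts(n_dims: int):
    if n_dims == 1:
        return [(-1,), (1,)]
    return [
        (di, dj)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        if (di, dj) != (0, 0)
    ]


def find_minima(fes: FESLandscape, depth_threshold: float) -> list[BasinRegion]:
    """Local minima of a landscape, expanded to basin bounding boxes.

    A cell is a local minimum if it is visited, lies below
    ``depth_threshold`` and no visited neighbor is strictly lower
    (8-neighborhood in 2D, wrapping on periodic dimensions; ties count as
    minima so discretized plateaus are not lost). Each minimum is
    expanded to the connected region with ``F < F_min + 1`` kcal/mol and
    returned as its bounding box, sorted by depth; minima sharing a
    region collapse into one basin.
    """
    if not fes.visited.any():
        raise ValueError("landscape has no visited cells")
    F = fes.F
    bins = fes.bins
    minima: list[tuple[float, tuple[int, ...]]] = []
    for idx in np.ndindex(*bins):
        if not fes.visited[idx] or not F[idx] < depth_threshold:
            continue
        is_min = True
        for shift in _neighbor_shifts(fes.n_dims):
            nb = []
            ok = True
            for d, (i, s) in enumerate(zip(idx, shift)):
                j = i + s
                if fes.periodic[d]:
                    j %= bins[d]
                elif j < 0 or j >= bins[d]:
                    ok = False
                    break
                nb.append(j)
            if not ok:
                continue
            nb = tuple(nb)
            if fes.visited[nb] and F[nb] < F[idx]:
                is_min = False
                break
        if is_min:
            minima.append((float(F[idx]), idx))

    minima.sort()
    widths = fes.bin_widths
    basins: list[BasinRegion] = []
    seen: set[tuple] = set()
    for fmin, idx in minima:
        mask = fes.visited & (F < fmin + BASIN_EXPANSION_KCAL)
        labels, _ = ndimage.label(mask)
        comp = labels == labels[idx]
        # merge components that touch across a periodic seam
        for d in range(fes.n_dims):
            if not fes.periodic[d]:
                continue
            changed = True
            while changed:
                changed = False
                first = np.take(comp, 0, axis=d) & np.take(mask, 0, axis=d)
                last = np.take(comp, -1, axis=d) & np.take(mask, -1, axis=d)
                for edge_sel, other_edge in ((first, -1), (last, 0)):
                    touch = edge_sel & np.take(mask, other_edge, axis=d)
                    for lab in np.unique(np.take(labels, other_edge, axis=d)[touch]):
                        if lab and not np.all(comp[labels == lab]):
                            comp |= labels == lab
                            changed = True
        axes_idx = np.nonzero(comp)
        lo_list, hi_list = [], []
        for d in range(fes.n_dims):
            ids = np.unique(axes_idx[d])
            if (
                fes.periodic[d]
                and ids[0] == 0
                and ids[-1] == fes.bins[d] - 1
                and len(ids) < fes.bins[d]
            ):
                # unroll across the seam: indices after the largest gap
                # count as negative
                gap = int(np.argmax(np.diff(ids)))
                ids = np.concatenate([ids[gap + 1 :] - fes.bins[d], ids[: gap + 1]])
            lo_list.append(fes.lo[d] + ids.min() * widths[d])
            hi_list.append(fes.lo[d] + (ids.max() + 1) * widths[d])
        lo = tuple(lo_list)
        hi = tuple(hi_list)
        key = (lo, hi)
        if key in seen:
            continue
        seen.add(key)
        basins.append(BasinRegion(lo=lo, hi=hi, label=f"S{len(basins) + 1}"))
    return basins


# ------------------------------------------------------------- extraction


def extract_frames(traj, region: BasinRegion, ligand_indices=None):
    """Frames whose CV point lies inside the closed basin box.

    Returns ``(indices, coords)`` where ``coords`` is the ligand-atom
    subset of the selected frames. An empty selection warns but is not
    an error.
    """
    if traj.cv_trace.size == 0:
        raise ValueError("trajectory has no CV trace")
    mask = region.contains(traj.cv_trace)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        warnings.warn(
            f"no frames inside region {region.label or region.lo}",
            stacklevel=2,
        )
    frames = traj.frames[idx]
    if ligand_indices is not None:
        frames = frames[:, list(ligand_indices), :]
    return idx, frames


def align_frames(frames: np.ndarray, ref_indices) -> np.ndarray:
    """Rigid-align each frame's receptor selection onto the first frame.

    Kabsch superposition on ``ref_indices`` applied to all atoms; makes
    ligand poses comparable in the receptor frame before clustering.
    """
    from scipy.spatial.transform import Rotation

    frames = np.asarray(frames, dtype=float)
    ref_indices = list(ref_indices)
    target = frames[0, ref_indices]
    t_cen = target.mean(axis=0)
    out = np.empty_like(frames)
    for k, fr in enumerate(frames):
        mob = fr[ref_indices]
        m_cen = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(target - t_cen, mob - m_cen)
        out[k] = rot.apply(fr - m_cen) + t_cen
    return out


# ------------------------------------------------------------- clustering


def pose_rmsd_matrix(frames: np.ndarray) -> np.ndarray:
    """Pairwise ligand RMSD without re-fitting (receptor-aligned frames)."""
    frames = np.asarray(frames, dtype=float)
    n, n_atoms = frames.shape[0], frames.shape[1]
    flat = frames.reshape(n, -1)
    return squareform(pdist(flat) / np.sqrt(n_atoms))


def cluster_poses(
    frames: np.ndarray,
    eps: float = DEFAULT_CLUSTER_EPS,
    min_pts: int = DEFAULT_CLUSTER_MIN_PTS,
) -> ClusterResult:
    """DBSCAN pose clustering over the no-refit ligand RMSD metric.

    Core points need ``min_pts`` neighbors within ``eps`` Å counting
    themselves. The representative pose is the medoid of the largest
    cluster; frames in no cluster are labelled −1 (noise).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < 1:
        raise ValueError("need at least one frame to cluster")
    D = pose_rmsd_matrix(frames)
    labels = DBSCAN(eps=eps, min_samples=min_pts, metric="precomputed").fit(D).labels_

    medoids: dict[int, int] = {}
    for lab in sorted(set(labels) - {-1}):
        members = np.nonzero(labels == lab)[0]
        sums = D[np.ix_(members, members)].sum(axis=1)
        medoids[lab] = int(members[np.argmin(sums)])

    dist = np.full(len(labels), np.nan)
    for lab, med in medoids.items():
        members = labels == lab
        dist[members] = D[med, members]

    representative = None
    if medoids:
        sizes = {lab: int(np.sum(labels == lab)) for lab in medoids}
        largest = max(sizes, key=lambda k: (sizes[k], -k))
        representative = medoids[largest]
    return ClusterResult(
        labels=labels,
        representative=representative,
        medoids=medoids,
        distance_to_medoid=dist,
        eps=eps,
        min_pts=min_pts,
    )


# -------------------------------------------------------------- occupancy


def basin_occupancy(fes_1d: FESLandscape, basin: BasinRegion, kT: float) -> float:
    """Boltzmann occupancy of a basin on a 1D periodic landscape.

    occupancy = Σ_basin exp(−F/kT) / Σ_all exp(−F/kT) over cell centers.
    Basin bounds may wrap (lo > hi, or negative lo) on the periodic
    circle; membership is half-open ``[lo, hi)`` so basins partitioning
    the circle have occupancies summing to exactly one. Unvisited cells
    inside the basin are an error.
    """
    if fes_1d.n_dims != 1:
        raise ValueError("basin_occupancy requires a 1D landscape")
    if kT <= 0:
        raise ValueError("kT must be positive")
    centers = fes_1d.centers(0)
    lo, hi = basin.lo[0], basin.hi[0]
    if fes_1d.periodic[0]:
        period = fes_1d.hi[0] - fes_1d.lo[0]
        width = (hi - lo) % period
        if width == 0.0:
            width = period
        member = ((centers - lo) % period) < width
    else:
        member = (centers >= lo) & (centers < hi)
    if np.any(member & ~fes_1d.visited):
        raise ValueError("basin contains unvisited cells; cannot weight them")
    weights = np.where(fes_1d.visited, np.exp(-fes_1d.F / kT), 0.0)
    total = weights.sum()
    if total == 0.0:
        raise ValueError("landscape has no visited cells")
    return float(weights[member].sum() / total)
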