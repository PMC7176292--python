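"""Deterministic synthetic fixtures.

Each fixture is a small on-disk stand-in for one stage of the binding
workflow: ready-to-run toy configurations, a host–guest PDB with labelled
ligand groups and receptor reference dummies, trajectories with planted
cluster structure and event schedules, and landscapes with planted
minima. All outputs are pure functions of ``(kind, params, seed)`` —
regenerating with the same seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import RunConfig
from .landscape import FESLandscape
from .potentials import HostGuest3D

FIXTURE_KINDS = (
    "double_well",
    "mueller_brown",
    "cosine_well",
    "host_guest",
    "planted_traj",
    "planted_fes",
)


def generate_fixture(kind: str, out_dir, seed: int = 0, params: dict | None = None) -> dict:
    """Write a named fixture into ``out_dir``; returns its manifest.

    The manifest (also written as ``manifest.json``) records the planted
    ground truth — cluster sizes, event counts, minima locations — so
    downstream recovery can be checked exactly.
    """
    params = dict(params or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    builders = {
        "double_well": _double_well,
        "mueller_brown": _mueller_brown,
        "cosine_well": _cosine_well,
        "host_guest": _host_guest,
        "planted_traj": _planted_traj,
        "planted_fes": _planted_fes,
    }
    try:
        build = builders[kind]
    except KeyError:
        raise ValueError(
            f"unknown fixture kind '{kind}'; available: {FIXTURE_KINDS}"
        ) from None
    manifest = build(out, seed, params)
    manifest = {"kind": kind, "seed": int(seed), "params": params, **manifest}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# ------------------------------------------------------------ run configs


def _double_well(out: Path, seed: int, params: dict) -> dict:
    cfg = RunConfig(
        system_name="double_well",
        system_params={"h": params.get("h", 2.0)},
        grid_bins=(480,),
        grid_lo=(-2.5,),
        grid_hi=(2.5,),
        grid_periodic=(False,),
        b=0.9,
        c=0.005,
        alpha=20,
        flim=params.get("flim", 18.0),
        kT=params.get("kT", 0.6163),
        n_steps=params.get("n_steps", 200_000),
        stride=params.get("stride", 20),
        seed=seed,
    )
    cfg.to_yaml(out / "config.yaml")
    return {"files": ["config.yaml"], "config_hash": cfg.hash()}


def _mueller_brown(out: Path, seed: int, params: dict) -> dict:
    cfg = RunConfig(
        system_name="mueller_brown",
        grid_bins=(96, 96),
        grid_lo=(-1.75, -0.5),
        grid_hi=(1.25, 2.25),
        grid_periodic=(False, False),
        b=0.9,
        c=0.05,
        alpha=5,
        flim=params.get("flim", 10.0),
        n_steps=params.get("n_steps", 200_000),
        stride=params.get("stride", 20),
        seed=seed,
    )
    cfg.to_yaml(out / "config.yaml")
    return {"files": ["config.yaml"], "config_hash": cfg.hash()}


def _cosine_well(out: Path, seed: int, params: dict) -> dict:
    # dihedral-mode parameters: b=0.8, c=0.1/step, alpha=5 on a 300-bin
    # periodic grid over [0, 2pi)
    cfg = RunConfig(
        system_name="cosine_well",
        system_params={"h": params.get("h", 2.0)},
        grid_bins=(300,),
        grid_lo=(0.0,),
        grid_hi=(2.0 * np.pi,),
        grid_periodic=(True,),
        b=0.8,
        c=0.1,
        alpha=5,
        flim=params.get("flim", 8.0),
        n_steps=params.get("n_steps", 150_000),
        stride=params.get("stride", 20),
        seed=seed,
    )
    cfg.to_yaml(out / "config.yaml")
    return {"files": ["config.yaml"], "config_hash": cfg.hash()}


def _host_guest(out: Path, seed: int, params: dict) -> dict:
    system = HostGuest3D()
    coords = system.initial_coords(np.random.default_rng(seed))
    lines = ["REMARK   host-guest binding toy: 4-atom ligand + 6 reference dummies"]
    serial = 1
    for i in range(4):
        group = "LG1" if i in system.group1_indices else "LG2"
        x, y, z = coords[i]
        lines.append(
            f"HETATM{serial:>5} {'C' + str(i + 1):<4}{group:>4} L{1:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {'C':>2}"
        )
        serial += 1
    for j, i in enumerate(range(4, 10)):
        chain = "A" if i in system.ref1_indices else "B"
        x, y, z = coords[i]
        lines.append(
            f"ATOM  {serial:>5} {'CA':<4}{'REF':>4} {chain}{j + 1:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {'C':>2}"
        )
        serial += 1
    lines.append("END")
    (out / "host_guest.pdb").write_text("\n".join(lines) + "\n")

    cfg = RunConfig(
        system_name="host_guest",
        grid_bins=(16, 16),
        grid_lo=(0.0, 0.0),
        grid_hi=(16.0, 16.0),
        grid_periodic=(False, False),
        b=0.9,
        c=0.3,
        alpha=3,
        flim=params.get("flim", 20.0),
        use_restraints=True,
        cylinder_radius=3.0,
        cv_cap=12.5,
        n_steps=params.get("n_steps", 100_000),
        stride=params.get("stride", 50),
        seed=seed,
    )
    cfg.to_yaml(out / "config.yaml")
    return {
        "files": ["host_guest.pdb", "config.yaml"],
        "config_hash": cfg.hash(),
        "pocket_cv": [round(float(v), 6) for v in system.pocket_cv()],
    }


# -------------------------------------------------------- planted fixtures


def _planted_traj(out: Path, seed: int, params: dict) -> dict:
    n_clusters = int(params.get("n_clusters", 2))
    frames_per_cluster = int(params.get("frames_per_cluster", 100))
    jitter = float(params.get("jitter", 0.1))
    separation = float(params.get("separation", 5.0))
    n_excursions = int(params.get("n_excursions", 7))
    rng = np.random.default_rng(seed)

    base = np.zeros((4, 3))
    base[:, 0] = (np.arange(4) - 1.5) * 1.5
    frames = []
    labels = []
    for k in range(n_clusters):
        pose = base + np.array([0.0, k * separation, 0.0])
        for _ in range(frames_per_cluster):
            frames.append(pose + rng.normal(0.0, jitter, size=(4, 3)))
            labels.append(k)
    order = rng.permutation(len(frames))
    frames = np.array(frames)[order]
    labels = [int(labels[i]) for i in order]

    n_frames = len(frames)
    with open(out / "traj.xyz", "w") as fh:
        for k in range(n_frames):
            fh.write("4\n")
            fh.write(f"frame {k} time_ps {float(k):.6f}\n")
            for i in range(4):
                x, y, z = frames[k, i]
                fh.write(f"C{i + 1} {x:.6f} {y:.6f} {z:.6f}\n")

    cv = 3.0 + rng.normal(0.0, 0.2, size=(n_frames, 2))
    with open(out / "cv_trace.tsv", "w") as fh:
        fh.write("time_ps\tcv1\tcv2\n")
        for k in range(n_frames):
            fh.write(f"{float(k):.6f}\t{cv[k, 0]:.6f}\t{cv[k, 1]:.6f}\n")

    # telegraph distance series: planted excursions below 4 A separated by
    # returns above 10 A
    dwell = int(params.get("dwell", 20))
    series = []
    for _ in range(n_excursions):
        series.extend([12.0 + rng.normal(0, 0.3) for _ in range(dwell)])
        series.extend([3.0 + rng.normal(0, 0.3) for _ in range(dwell)])
    series.extend([12.0 + rng.normal(0, 0.3) for _ in range(dwell)])
    with open(out / "distances.tsv", "w") as fh:
        fh.write("time_ps\tdistance_A\n")
        for k, d in enumerate(series):
            fh.write(f"{float(k):.6f}\t{d:.6f}\n")

    return {
        "files": ["traj.xyz", "cv_trace.tsv", "distances.tsv"],
        "n_clusters": n_clusters,
        "frames_per_cluster": frames_per_cluster,
        "cluster_labels": labels,
        "n_binding_events": n_excursions,
        "n_unbinding_events": n_excursions,
    }


def _planted_fes(out: Path, seed: int, params: dict) -> dict:
    n_minima = int(params.get("n_minima", 3))
    bins = int(params.get("bins", 64))
    rng = np.random.default_rng(seed)
    lo, hi = 0.0, 10.0
    w = (hi - lo) / bins
    centers_1d = lo + (np.arange(bins) + 0.5) * w

    all_centers = np.array(
        [[2.0, 2.0], [5.0, 7.0], [8.0, 3.0], [8.5, 8.5], [2.0, 8.0]]
    )
    depths = np.array([5.0, 4.5, 4.0, 3.8, 3.6])
    centers = all_centers[:n_minima]
    depths = depths[:n_minima]
    sigma = float(params.get("sigma", 0.6))

    X, Y = np.meshgrid(centers_1d, centers_1d, indexing="ij")
    F = np.full((bins, bins), 6.0)
    for (cx, cy), depth in zip(centers, depths):
        F -= depth * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sigma**2))
    F += rng.normal(0.0, 0.01, size=F.shape)  # mild roughness
    F -= F.min()

    fes = FESLandscape(
        bins=(bins, bins),
        lo=(lo, lo),
        hi=(hi, hi),
        periodic=(False, False),
        F=F,
        visited=np.ones((bins, bins), dtype=bool),
    )
    fes.to_tsv(out / "fes.tsv")
    return {
        "files": ["fes.tsv"],
        "n_minima": n_minima,
        "minima_centers": [[float(c) for c in row] for row in centers],
        "minima_depths": [float(d) for d in depths],
    }
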