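"""Tunnel geometry: sphere profiles, descriptors, and an internal finder.

A tunnel is an ordered chain of inscribed spheres (center + radius) along a
centerline, sphere 0 at the buried end (near the catalytic site).  Profiles
can be read from Caver-style per-sphere CSV files or computed internally on
simple structures with a deterministic grid-based widest-path search.

Descriptors follow the conventions Caver reports: length is the centerline
arc length, curvature the arc/chord ratio (>= 1), the bottleneck the sphere
of minimal radius, and the bend angle the angle between the mean entry and
exit directions of the centerline.
"""

from __future__ import annotations

import heapq
import io
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ParseError, TunnelprofError
from .structio import Atom, StructureEnsemble

__all__ = [
    "TunnelSphere",
    "Tunnel",
    "TunnelSearchConfig",
    "read_caver_profiles",
    "write_caver_profiles",
    "tunnel_to_pdb",
    "arc_length",
    "curvature",
    "bend_angle",
    "bottleneck",
    "lining_residues",
    "find_tunnels",
]

# vdW radii used for clearance computations (scoring-class radii)
_VDW = {"C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0, "P": 2.1,
        "F": 1.5, "Cl": 1.8, "Br": 2.0, "I": 2.2, "H": 1.2, "D": 1.2}


@dataclass(frozen=True)
class TunnelSphere:
    center: np.ndarray
    radius: float
    arc_position: float = 0.0

    def __post_init__(self):
        c = np.asarray(self.center, float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("sphere center must be a finite 3-vector")
        if self.radius < 0:
            raise ValueError("sphere radius must be >= 0")
        object.__setattr__(self, "center", c)


@dataclass
class Tunnel:
    """Ordered sphere chain for one tunnel in one snapshot."""

    snapshot_id: int
    tunnel_id: int
    spheres: list[TunnelSphere]

    def __post_init__(self):
        if not self.spheres:
            raise ValueError("a tunnel needs at least one sphere")

    @property
    def centers(self) -> np.ndarray:
        return np.array([s.center for s in self.spheres])

    @property
    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.spheres])

    def __len__(self) -> int:
        return len(self.spheres)


@dataclass
class TunnelSearchConfig:
    """Parameters of the internal grid-based tunnel search."""

    start_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    grid_spacing: float = 0.5
    min_probe_radius: float = 0.9
    surface_depth: float = 3.5

    def __post_init__(self):
        self.start_point = np.asarray(self.start_point, float)
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.surface_depth <= 0:
            raise ValueError("surface_depth must be positive")


def _with_arc_positions(spheres: Sequence[TunnelSphere]) -> list[TunnelSphere]:
    out = []
    arc = 0.0
    prev = None
    for s in spheres:
        if prev is not None:
            arc += float(np.linalg.norm(s.center - prev))
        out.append(replace(s, arc_position=arc))
        prev = s.center
    return out


# ---------------------------------------------------------------------------
# Caver-style profile I/O
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {"snapshot": "Snapshot", "tunnel": "Tunnel",
                   "x": "X", "y": "Y", "z": "Z", "radius": "R"}


def read_caver_profiles(file, columns: dict | None = None) -> list[Tunnel]:
    """Read a per-sphere tunnel-profile CSV into a list of tunnels.

    One row per sphere with snapshot id, tunnel id, x, y, z, radius; the
    column map is configurable for other dialects.  One Tunnel per
    (snapshot, tunnel id), spheres in file order, arc positions computed
    cumulatively.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(file)
    df.columns = [c.strip() for c in df.columns]
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ParseError(f"profile file lacks required column(s): {missing}")
    if len(df) and (df[cols["radius"]] < 0).any():
        bad = df.index[df[cols["radius"]] < 0][0]
        raise ValueError(f"negative sphere radius at data row {bad}")
    tunnels = []
    if len(df) == 0:
        return tunnels
    for (snap, tid), grp in df.groupby([cols["snapshot"], cols["tunnel"]],
                                       sort=True):
        spheres = [TunnelSphere(center=np.array([r[cols["x"]], r[cols["y"]],
                                                 r[cols["z"]]], float),
                                radius=float(r[cols["radius"]]))
                   for _, r in grp.iterrows()]
        tunnels.append(Tunnel(snapshot_id=int(snap), tunnel_id=int(tid),
                              spheres=_with_arc_positions(spheres)))
    return tunnels


def write_caver_profiles(tunnels: Sequence[Tunnel], file=None) -> str:
    """Write tunnels in the per-sphere CSV dialect read by read_caver_profiles."""
    rows = []
    for t in tunnels:
        for s in t.spheres:
            rows.append({"Snapshot": t.snapshot_id, "Tunnel": t.tunnel_id,
                         "X": s.center[0], "Y": s.center[1], "Z": s.center[2],
                         "R": s.radius})
    df = pd.DataFrame(rows, columns=["Snapshot", "Tunnel", "X", "Y", "Z", "R"])
    if file is None:
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()
    df.to_csv(file, index=False)
    return ""


def tunnel_to_pdb(t: Tunnel) -> str:
    """Tunnel spheres as HETATM pseudo-atoms, radius in the B-factor column."""
    lines = []
    for i, s in enumerate(t.spheres):
        x, y, z = s.center
        lines.append(
            f"HETATM{i + 1:>5}  SPH TUN T{t.tunnel_id % 10000:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{s.radius:6.2f}          "
            f"{'C':>2}")
    return "\n".join(lines) + "\nEND\n"


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

def arc_length(t: Tunnel) -> float:
    """Centerline arc length: sum of consecutive center distances (A)."""
    c = t.centers
    if len(c) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum())


def curvature(t: Tunnel) -> float:
    """Arc/chord ratio; 1 for a straight tunnel, > 1 otherwise."""
    if len(t) < 2:
        raise TunnelprofError("curvature needs at least two spheres")
    chord = float(np.linalg.norm(t.spheres[-1].center - t.spheres[0].center))
    if chord < 1e-12:
        raise TunnelprofError("curvature undefined: coincident tunnel endpoints")
    return arc_length(t) / chord


def bend_angle(t: Tunnel, window: int = 5) -> float:
    """Angle (degrees) between the mean entry and exit directions.

    The entry direction averages the first ``window`` inter-sphere steps, the
    exit direction the last ``window``; a straight tunnel gives 0, a right
    angle 90.
    """
    steps = np.diff(t.centers, axis=0)
    if len(steps) < 2 * window:
        raise TunnelprofError(
            f"bend_angle needs >= {2 * window} spheres, got {len(t)}")
    v1 = steps[:window].mean(axis=0)
    v2 = steps[-window:].mean(axis=0)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def bottleneck(t: Tunnel) -> tuple[int, float]:
    """(index, radius) of the minimal-radius sphere; ties take the smaller arc position."""
    r = t.radii
    i = int(np.argmin(r))  # argmin returns the first minimum = smallest arc position
    return i, float(r[i])


def lining_residues(t: Tunnel, snapshot: Sequence[Atom],
                    cutoff: float = 3.0) -> list[tuple[tuple, float]]:
    """Residues with a heavy atom within (sphere radius + cutoff) of any sphere.

    Returns [(residue key, min surface distance)] sorted by distance; the key
    is (chain_id, residue_id, residue_name).
    """
    heavy = [a for a in snapshot if not a.is_hydrogen]
    if not heavy:
        return []
    pos = np.array([a.position for a in heavy])
    centers = t.centers
    radii = t.radii
    d = np.linalg.norm(pos[:, None, :] - centers[None, :, :], axis=2)
    surf = d - radii[None, :]
    best = surf.min(axis=1)
    per_res: dict = {}
    for a, dist in zip(heavy, best):
        if dist <= cutoff:
            key = (a.chain_id, a.residue_id, a.residue_name)
            per_res[key] = min(per_res.get(key, np.inf), float(dist))
    return sorted(per_res.items(), key=lambda kv: kv[1])


# ---------------------------------------------------------------------------
# Internal tunnel finder (grid-based widest path)
# ---------------------------------------------------------------------------

def _neighbor_offsets():
    offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)]
    return np.array(offs, int)


def _shortest_to_exit(start, exit_mask, clearance, open_mask, min_clear, offs, h):
    """Euclidean-shortest grid path from start, through nodes with clearance
    >= min_clear, ending at the first exit node reached; None if unreachable."""
    shape = clearance.shape
    ok = open_mask & (clearance >= min_clear)
    if not ok[start]:
        return None
    dist = {start: 0.0}
    prev: dict = {}
    heap = [(0.0, start)]
    step_len = np.linalg.norm(offs, axis=1) * h
    done = set()
    target = None
    while heap:
        d0, node = heapq.heappop(heap)
        if node in done:
            continue
        if exit_mask[node]:
            target = node
            break
        done.add(node)
        for off, sl in zip(offs, step_len):
            nb = (node[0] + off[0], node[1] + off[1], node[2] + off[2])
            if not (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1]
                    and 0 <= nb[2] < shape[2]):
                continue
            if not ok[nb] or nb in done:
                continue
            nd = d0 + sl
            if nd < dist.get(nb, np.inf):
                dist[nb] = nd
                prev[nb] = node
                heapq.heappush(heap, (nd, nb))
    if target is None:
        return None
    path = [target]
    while path[-1] != start:
        path.append(prev[path[-1]])
    path.reverse()
    return path


def find_tunnels(snapshot: Sequence[Atom], cfg: TunnelSearchConfig,
                 snapshot_id: int = 0, max_tunnels: int = 3) -> list[Tunnel]:
    """Deterministic grid widest-path tunnel search on one snapshot.

    Clearance at a grid node is the distance to the nearest heavy-atom vdW
    surface.  Starting from the node nearest ``start_point``, paths that
    maximize their minimum clearance are grown (Dijkstra on -bottleneck);
    nodes whose clearance reaches ``surface_depth`` count as bulk solvent.
    One tunnel per connected exit region, ranked by bottleneck radius, each a
    centerline sphere chain with radius = local clearance.

    The search is conservative: reported bottleneck radii are true lower
    bounds of the clearance along the path and converge to the analytic
    channel radius as the grid is refined.
    """
    heavy = [a for a in snapshot if not a.is_hydrogen]
    if not heavy:
        raise TunnelprofError("empty structure")
    pos = np.array([a.position for a in heavy])
    vdw = np.array([_VDW.get(a.element, 1.9) for a in heavy])

    # box margin large enough that bulk solvent (clearance >= surface_depth)
    # exists outside the structure
    margin = cfg.surface_depth + 2.0 * max(cfg.grid_spacing, 1.0) + vdw.max()
    lo = pos.min(axis=0) - margin
    hi = pos.max(axis=0) + margin
    start = cfg.start_point
    if np.any(start < lo) or np.any(start > hi):
        raise TunnelprofError("start point lies outside the structure bounds")

    h = cfg.grid_spacing
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / h)) + 1 for i in range(3))
    grid_axes = [lo[i] + h * np.arange(shape[i]) for i in range(3)]
    gx, gy, gz = np.meshgrid(*grid_axes, indexing="ij")
    nodes = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    tree = cKDTree(pos)
    # clearance = min over atoms of (center distance - vdw radius)
    kmax = min(16, len(pos))
    dist, idx = tree.query(nodes, k=kmax)
    if kmax == 1:
        dist, idx = dist[:, None], idx[:, None]
    clearance = (dist - vdw[idx]).min(axis=1).reshape(shape)

    open_mask = clearance >= cfg.min_probe_radius
    start_idx = tuple(int(np.clip(round((start[i] - lo[i]) / h), 0, shape[i] - 1))
                      for i in range(3))
    if not open_mask[start_idx]:
        raise TunnelprofError(
            "start point has insufficient clearance (not inside a cavity)")

    exit_mask = clearance >= cfg.surface_depth

    # Dijkstra variant: maximize the minimum clearance along the path
    best = np.full(shape, -np.inf)
    prev = -np.ones(shape + (3,), dtype=np.int32)
    best[start_idx] = clearance[start_idx]
    heap = [(-best[start_idx], start_idx)]
    offs = _neighbor_offsets()
    visited = np.zeros(shape, bool)
    while heap:
        negb, node = heapq.heappop(heap)
        if visited[node]:
            continue
        visited[node] = True
        b = -negb
        for off in offs:
            nb = (node[0] + off[0], node[1] + off[1], node[2] + off[2])
            if not (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1]
                    and 0 <= nb[2] < shape[2]):
                continue
            if not open_mask[nb] or visited[nb]:
                continue
            cand = min(b, clearance[nb])
            if cand > best[nb]:
                best[nb] = cand
                prev[nb] = node
                heapq.heappush(heap, (-cand, nb))

    reached_exits = visited & exit_mask
    if not reached_exits.any():
        return []

    # group exit nodes into connected components
    from scipy import ndimage

    labels, n_comp = ndimage.label(reached_exits, structure=np.ones((3, 3, 3)))
    tunnels = []
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        widest = float(best[comp_mask].max())
        # centerline = shortest path realizing the widest achievable
        # bottleneck, truncated at the first bulk node it reaches
        path = _shortest_to_exit(start_idx, comp_mask, clearance, open_mask,
                                 widest - 1e-9, offs, h)
        if path is None:  # numerical edge case; fall back to the wide tree
            comp_nodes = np.argwhere(comp_mask)
            target = tuple(comp_nodes[int(np.argmax(best[comp_mask]))])
            path = [target]
            node = target
            while tuple(prev[node]) != (-1, -1, -1) and node != start_idx:
                node = tuple(prev[node])
                path.append(node)
            path.reverse()  # start (buried end) first
        spheres = []
        for node in path:
            center = lo + h * np.array(node, float)
            r = float(clearance[node])
            if r >= cfg.surface_depth:  # stop where the path reaches bulk
                spheres.append(TunnelSphere(center=center, radius=r))
                break
            spheres.append(TunnelSphere(center=center, radius=r))
        if len(spheres) >= 2:
            tunnels.append((min(s.radius for s in spheres), spheres))
    tunnels.sort(key=lambda x: -x[0])
    out = []
    for tid, (_, spheres) in enumerate(tunnels[:max_tunnels]):
        out.append(Tunnel(snapshot_id=snapshot_id, tunnel_id=tid,
                          spheres=_with_arc_positions(spheres)))
    return out
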