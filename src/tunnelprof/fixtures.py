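"""Seeded synthetic fixtures with analytic ground truth.

Generates wall-of-atoms channels (straight, L-shaped, or semicircular) with a
configurable radius profile and optional bottleneck, alkyl / ester-headed
ligands, jittered pseudo-trajectories, and matching Caver-style profile
files.  Every generator is a pure function of its spec + seed, so reruns are
byte-identical — the ground-truth tunnel (centerline + clearance radii) is
known exactly by construction and anchors the tests of every other module.

These are geometric decoys, not physical proteins: walls are uniform carbon
atoms on a tube surface (so scoring is analytically predictable), and
"residues" are sequential blocks along the arc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structio import Atom, StructureEnsemble, TypedMolecule
from .tunnelgeom import Tunnel, TunnelSphere, write_caver_profiles

__all__ = ["ChannelSpec", "make_channel", "make_ligand", "make_trajectory",
           "make_caver_files"]

_CARBON_VDW = 1.9  # scoring-class carbon radius; wall tube radius = clearance + this


@dataclass
class ChannelSpec:
    """Specification of a synthetic wall-of-atoms channel.

    ``base_radius`` is the channel *clearance* radius (A) — the radius of the
    largest probe that passes — with an optional bottleneck pinching the
    profile down to ``bottleneck[1]`` at arc position ``bottleneck[0]``.
    """

    shape: str = "straight"  # straight | L | semicircle
    centerline_length: float = 20.0
    base_radius: float = 3.0
    bottleneck: tuple[float, float] | None = None  # (arc position A, radius A)
    bottleneck_width: float = 2.0
    wall_density: float = 1.0  # atoms per A^2 of tube surface
    arc_step: float = 1.0  # centerline sampling step, A
    polar_arc_range: tuple[float, float] | None = None  # wall O atoms in this arc span
    cap_start: bool = False  # wall off the buried end (catalytic-site side)
    seed: int = 0

    def __post_init__(self):
        if self.shape not in ("straight", "L", "semicircle"):
            raise ValueError(f"unknown channel shape {self.shape!r}")
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if self.bottleneck is not None and not (0 < self.bottleneck[1] < self.base_radius):
            raise ValueError("bottleneck radius must be in (0, base_radius)")


def _centerline(spec: ChannelSpec) -> np.ndarray:
    """Centerline points sampled every arc_step A, start at the buried end."""
    n = max(2, int(round(spec.centerline_length / spec.arc_step)) + 1)
    s = np.linspace(0.0, spec.centerline_length, n)
    if spec.shape == "straight":
        pts = np.stack([np.zeros_like(s), np.zeros_like(s), s], axis=1)
    elif spec.shape == "L":
        half = spec.centerline_length / 2.0
        pts = np.empty((n, 3))
        for i, si in enumerate(s):
            if si <= half:
                pts[i] = (0.0, 0.0, si)
            else:
                pts[i] = (si - half, 0.0, half)
    else:  # semicircle of arc length L: R = L / pi
        R = spec.centerline_length / np.pi
        theta = s / R
        pts = np.stack([R * np.sin(theta), np.zeros_like(s),
                        R * (1.0 - np.cos(theta))], axis=1)
    return pts


def clearance_profile(spec: ChannelSpec, s: np.ndarray) -> np.ndarray:
    """Channel clearance radius at arc positions ``s`` (Gaussian pinch)."""
    r = np.full_like(s, spec.base_radius, dtype=float)
    if spec.bottleneck is not None:
        s0, rb = spec.bottleneck
        w = spec.bottleneck_width
        dip = (spec.base_radius - rb) * np.exp(-((s - s0) ** 2) / (2 * w * w))
        r = r - dip
    return r


def _transport_frames(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimizing normal/binormal frames along a polyline."""
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.empty_like(tangents)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, tangents[0])) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n = ref - np.dot(ref, tangents[0]) * tangents[0]
    normals[0] = n / np.linalg.norm(n)
    for i in range(1, len(pts)):
        n = normals[i - 1] - np.dot(normals[i - 1], tangents[i]) * tangents[i]
        norm = np.linalg.norm(n)
        if norm < 1e-12:  # degenerate; restart from reference
            n = ref - np.dot(ref, tangents[i]) * tangents[i]
            norm = np.linalg.norm(n)
        normals[i] = n / norm
    binormals = np.cross(tangents, normals)
    return normals, binormals


def make_channel(spec: ChannelSpec) -> tuple[StructureEnsemble, Tunnel]:
    """Build a wall-of-atoms channel and its exact ground-truth tunnel.

    Carbon wall atoms sit on a tube of radius (clearance + carbon vdW) around
    the centerline; the ground-truth tunnel is the centerline sphere chain
    with radius = local clearance.  Residue ids advance in sequential blocks
    along the arc (one residue per ring).
    """
    pts = _centerline(spec)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    clear = clearance_profile(spec, s)
    normals, binormals = _transport_frames(pts)

    polar_lo, polar_hi = spec.polar_arc_range or (np.inf, -np.inf)

    atoms: list[Atom] = []
    serial = 1
    for i, p in enumerate(pts):
        tube_r = clear[i] + _CARBON_VDW
        n_ring = max(6, int(round(2 * np.pi * tube_r * spec.arc_step
                                  * spec.wall_density)))
        # deterministic phase offset per ring avoids aligned gaps between rings
        phase = i * np.pi / n_ring
        angles = phase + 2 * np.pi * np.arange(n_ring) / n_ring
        polar_ring = polar_lo <= s[i] <= polar_hi
        for k, ang in enumerate(angles):
            xyz = p + tube_r * (np.cos(ang) * normals[i] + np.sin(ang) * binormals[i])
            element = "O" if (polar_ring and k % 3 == 0) else "C"
            atoms.append(Atom(
                serial=serial, name=f"{element}{k % 99 + 1}", element=element,
                residue_name="WAL", residue_id=i + 1, chain_id="A",
                position=xyz, is_hetero=False))
            serial += 1

    if spec.cap_start:
        # hemispherical shell sealing the buried end: same radius as the tube
        # mouth, centered on sphere 0, so clearance at the start stays clear[0]
        tangent0 = pts[1] - pts[0]
        tangent0 /= np.linalg.norm(tangent0)
        tube_r0 = clear[0] + _CARBON_VDW
        n_cap = max(12, int(round(2 * np.pi * tube_r0**2 * spec.wall_density)))
        golden = np.pi * (3.0 - np.sqrt(5.0))
        placed = 0
        i_pt = 0
        while placed < n_cap:
            zf = 1.0 - 2.0 * (i_pt + 0.5) / (2 * n_cap)  # full-sphere sampling
            rf = np.sqrt(max(0.0, 1.0 - zf * zf))
            th = golden * i_pt
            d = (np.cos(th) * rf * normals[0] + np.sin(th) * rf * binormals[0]
                 + zf * tangent0)
            i_pt += 1
            if np.dot(d, tangent0) >= -0.05:  # keep the rear hemisphere only
                continue
            xyz = pts[0] + tube_r0 * d
            atoms.append(Atom(serial=serial, name=f"C{placed % 99 + 1}",
                              element="C", residue_name="CAP",
                              residue_id=len(pts) + 1, chain_id="A",
                              position=xyz, is_hetero=False))
            serial += 1
            placed += 1

    # union-of-tubes carve: drop wall atoms that intrude into the channel
    # interior anywhere along the centerline (e.g. at the elbow of the L,
    # where the two legs' tubes overlap)
    xyz_all = np.array([a.position for a in atoms])
    dmat = np.linalg.norm(xyz_all[:, None, :] - pts[None, :, :], axis=2)
    # tolerate shallow (<0.2 A) intrusions: rings of a narrowing section
    # legitimately shave the nominal clearance of their neighbors slightly
    keep = np.all(dmat >= (clear + _CARBON_VDW)[None, :] - 0.2, axis=1)
    atoms = [Atom(serial=k + 1, name=a.name, element=a.element,
                  residue_name=a.residue_name, residue_id=a.residue_id,
                  chain_id=a.chain_id, position=a.position,
                  is_hetero=a.is_hetero)
             for k, a in enumerate(a for a, ok in zip(atoms, keep) if ok)]

    coords = np.array([[a.position for a in atoms]])
    ensemble = StructureEnsemble(atoms, coords)

    spheres = []
    arc = 0.0
    for i, p in enumerate(pts):
        spheres.append(TunnelSphere(center=p, radius=float(clear[i]),
                                    arc_position=float(s[i])))
    truth = Tunnel(snapshot_id=0, tunnel_id=0, spheres=spheres)

    _validate_wall(ensemble, truth)
    return ensemble, truth


def _validate_wall(ensemble: StructureEnsemble, truth: Tunnel) -> None:
    """Probe the centerline: warn if the wall leaks (clearance above truth)."""
    pos = ensemble.coords[0]
    from scipy.spatial import cKDTree

    tree = cKDTree(pos)
    centers = truth.centers
    d, _ = tree.query(centers)
    measured = d - _CARBON_VDW
    if np.any(measured > truth.radii + 0.75):
        warnings.warn("wall density too low: channel wall leaks "
                      "(measured clearance exceeds ground truth)",
                      stacklevel=2)


# ---------------------------------------------------------------------------
# Ligands
# ---------------------------------------------------------------------------

_CC = 1.53
_CO_DOUBLE = 1.22
_CO_SINGLE = 1.34
_CH = 1.09
_TET = np.deg2rad(109.47)


def _zigzag(n: int, bond: float = _CC, angle: float = _TET) -> np.ndarray:
    """All-trans chain in the xz-plane, consecutive atoms ``bond`` apart."""
    dz = bond * np.sin(angle / 2.0)
    dx = bond * np.cos(angle / 2.0)
    pts = np.zeros((n, 3))
    for i in range(n):
        pts[i] = ((i % 2) * dx, 0.0, i * dz)
    return pts


def make_ligand(n_chain: int, kind: str = "alkyl",
                with_hydrogens: bool = True) -> TypedMolecule:
    """Build an all-trans alkyl chain, optionally with an ester head group.

    ``alkyl``: n_chain carbons, C-C 1.53 A.  ``ester-head``: the first chain
    carbon becomes a carbonyl carbon bearing a double-bonded O and an ester O
    with a methyl cap (two oxygens total, typed O.2 / O.3).  Hydrogens are
    attached at idealized offsets; their positions only matter for topology
    (typing / PEOE charges), never for scoring.
    """
    if n_chain < 1:
        raise ValueError("n_chain must be >= 1")
    if kind not in ("alkyl", "ester-head"):
        raise ValueError(f"unknown ligand kind {kind!r}")
    chain = _zigzag(n_chain)
    atoms: list[Atom] = []
    bonds: list[tuple[int, int, int]] = []

    def add(element, pos, name):
        atoms.append(Atom(serial=len(atoms) + 1, name=name, element=element,
                          residue_name="LIG", residue_id=1, chain_id="L",
                          position=np.asarray(pos, float), is_hetero=True))
        return len(atoms) - 1

    chain_idx = [add("C", chain[i], f"C{i + 1}") for i in range(n_chain)]
    for a, b in zip(chain_idx, chain_idx[1:]):
        bonds.append((a, b, 1))

    if kind == "ester-head":
        head = chain[0]
        o2 = add("O", head + np.array([-_CO_DOUBLE, 0.0, 0.0]), "O1")
        o3 = add("O", head + np.array([-_CO_SINGLE * 0.5, _CO_SINGLE * 0.866, 0.0]), "O2")
        cme = add("C", atoms[o3].position + np.array([0.0, 1.43, 0.0]), "CM")
        bonds.append((chain_idx[0], o2, 2))
        bonds.append((chain_idx[0], o3, 1))
        bonds.append((o3, cme, 1))

    if with_hydrogens:
        # crude tetrahedral completion; positions are topological placeholders
        h_dirs = np.array([[1.0, 1.0, -1.0], [-1.0, 1.0, 1.0], [1.0, -1.0, 1.0],
                           [-1.0, -1.0, -1.0]]) / np.sqrt(3.0)
        nbr_count = {i: 0 for i in range(len(atoms))}
        for a, b, _ in bonds:
            nbr_count[a] += 1
            nbr_count[b] += 1
        heavy_n = len(atoms)
        for i in range(heavy_n):
            if atoms[i].element != "C":
                continue
            valence = 4
            if kind == "ester-head" and i == chain_idx[0]:
                valence = 3  # carbonyl carbon is sp2
            missing = valence - nbr_count[i]
            for m in range(max(0, missing)):
                hpos = atoms[i].position + _CH * h_dirs[(m + i) % 4]
                h = add("H", hpos, f"H{i + 1}{m + 1}")
                bonds.append((i, h, 1))
    return TypedMolecule(atoms=atoms, bonds=bonds)


# ---------------------------------------------------------------------------
# Trajectories and files
# ---------------------------------------------------------------------------

def make_trajectory(base: StructureEnsemble, n_snapshots: int,
                    jitter_sigma: float, seed: int = 0) -> StructureEnsemble:
    """Jittered pseudo-trajectory: snapshot 0 is the base, the rest add i.i.d.
    Gaussian per-atom displacement of the given sigma (A) per coordinate."""
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    base_xyz = base.coords[0]
    snaps = [base_xyz]
    for _ in range(1, n_snapshots):
        snaps.append(base_xyz + rng.normal(0.0, jitter_sigma, size=base_xyz.shape))
    return StructureEnsemble(base.atoms, np.array(snaps))


def make_caver_files(tunnels, directory) -> Path:
    """Write tunnels as a Caver-style profile CSV; returns the file path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "tunnel_profiles.csv"
    with open(path, "w") as fh:
        write_caver_profiles(tunnels, fh)
    return path
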