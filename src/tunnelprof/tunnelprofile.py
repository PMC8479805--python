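"""Substrate threading along tunnel spheres and energy-vs-position profiles.

The core procedure: a substrate (a single probe atom or an acyl chain) is
placed at the centers of a tunnel's spheres, scored against the nearby
receptor atoms with the empirical pairwise function, and the resulting
score-vs-anchor profile is combined with the tunnel's geometric descriptors.
Repeating this over every snapshot of a trajectory yields per-conformation
records, a criterion to select binding-compatible conformations, and
smallest/largest-tunnel statistics across the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PlacementError, TunnelprofError
from .structio import (Atom, StructureEnsemble, TypedMolecule,
                       molecule_scoring_classes, scoring_parameters)
from .tunnelgeom import Tunnel, arc_length, bend_angle, bottleneck, curvature
from .vinascore import ScoreBreakdown, ScoreOptions, score_pose

__all__ = [
    "Placement",
    "TunnelRecord",
    "TrajectorySummary",
    "thread_substrate",
    "local_receptor",
    "energy_profile",
    "profile_trajectory",
    "select_compatible",
    "summarize",
    "records_to_frame",
    "per_residue_matrix",
]


@dataclass
class Placement:
    snapshot_id: int
    tunnel_id: int
    anchor_sphere_index: int
    ligand_positions: np.ndarray  # heavy-atom coordinates, one row per atom
    score: ScoreBreakdown | None = None


@dataclass
class TunnelRecord:
    """Geometry + energy profile of one tunnel in one snapshot."""

    snapshot_id: int
    tunnel_id: int
    length: float
    curvature: float
    bend_angle: float | None
    bottleneck_radius: float
    bottleneck_index: int
    anchors: list[int]
    profile: list[float]
    per_residue: list[dict] = field(default_factory=list)

    @property
    def min_score(self) -> float:
        return min(self.profile)

    @property
    def min_anchor(self) -> int:
        return self.anchors[int(np.argmin(self.profile))]


@dataclass
class TrajectorySummary:
    """Per-series (smallest / largest tunnel) statistics across snapshots."""

    stats: pd.DataFrame  # rows: (series, quantity); cols: mean, sd, min, max
    counts: dict  # tunnel_id -> number of snapshots carrying it
    n_snapshots: int


def _longest_chain(mol: TypedMolecule) -> list[int]:
    """Longest heavy-atom simple path (graph diameter path) through the bonds."""
    import networkx as nx

    heavy = set(mol.heavy_indices())
    g = nx.Graph()
    g.add_nodes_from(heavy)
    g.add_edges_from((i, j) for i, j, _ in mol.bonds if i in heavy and j in heavy)
    if g.number_of_nodes() == 1:
        return list(heavy)
    best: list[int] = []
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    src, dst, _ = max(((u, v, d) for u, dd in lengths.items() for v, d in dd.items()),
                      key=lambda t: t[2])
    best = nx.shortest_path(g, src, dst)
    return list(best)


def _kabsch_transform(X: np.ndarray, Y: np.ndarray):
    """Rigid transform (R, t) minimizing ||R X + t - Y||^2 (proper rotation)."""
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    return R, t


def thread_substrate(substrate: TypedMolecule, tunnel: Tunnel, mode: str,
                     anchor: int) -> Placement:
    """Place a substrate at tunnel sphere centers.

    ``probe`` mode puts a single probe heavy atom at sphere ``anchor``;
    ``chain`` mode snaps the substrate's longest heavy-atom path onto
    consecutive sphere centers starting at ``anchor`` (chain order
    preserved) and carries any remaining substituent atoms rigidly via the
    least-squares fit of the chain.
    """
    if mode not in ("probe", "chain"):
        raise ValueError(f"unknown threading mode {mode!r}")
    n_sph = len(tunnel.spheres)
    if not (0 <= anchor < n_sph):
        raise PlacementError(f"anchor {anchor} outside tunnel of {n_sph} spheres")
    heavy = substrate.heavy_indices()
    if mode == "probe":
        pos = tunnel.spheres[anchor].center[None, :]
        return Placement(tunnel.snapshot_id, tunnel.tunnel_id, anchor, pos)

    chain = _longest_chain(substrate)
    m = len(chain)
    if anchor + m > n_sph:
        raise PlacementError(
            f"chain of {m} atoms does not fit the {n_sph - anchor} spheres "
            f"remaining from anchor {anchor}")
    targets = np.array([tunnel.spheres[anchor + k].center for k in range(m)])
    all_pos = substrate.positions
    placed = np.array(all_pos[heavy])
    chain_local = {g: k for k, g in enumerate(chain)}

    others = [i for i in heavy if i not in chain_local]
    if others:
        if m >= 3:
            R, t = _kabsch_transform(all_pos[chain], targets)
        else:
            R, t = np.eye(3), targets[0] - all_pos[chain[0]]
        moved = (R @ all_pos[others].T).T + t
    # heavy-atom output order follows substrate heavy order
    out = np.empty((len(heavy), 3))
    oi = 0
    for k, i in enumerate(heavy):
        if i in chain_local:
            out[k] = targets[chain_local[i]]
        else:
            out[k] = moved[oi]
            oi += 1
    return Placement(tunnel.snapshot_id, tunnel.tunnel_id, anchor, out)


def local_receptor(snapshot: Sequence[Atom], placement: Placement,
                   cutoff: float = 8.0) -> list[Atom]:
    """Receptor heavy atoms within ``cutoff`` of any placed ligand atom.

    Order is deterministic (input order preserved).  With cutoff equal to the
    interaction cutoff, scoring against this subset equals scoring against
    the full receptor.
    """
    heavy = [a for a in snapshot if not a.is_hydrogen]
    if not heavy:
        return []
    pos = np.array([a.position for a in heavy])
    lig = np.atleast_2d(placement.ligand_positions)
    d = np.linalg.norm(pos[:, None, :] - lig[None, :, :], axis=2).min(axis=1)
    return [a for a, di in zip(heavy, d) if di <= cutoff]


_PROBE_CLASS_CACHE = None


def _probe_class():
    global _PROBE_CLASS_CACHE
    if _PROBE_CLASS_CACHE is None:
        _PROBE_CLASS_CACHE = scoring_parameters("C.3", ("C", "H"))
    return _PROBE_CLASS_CACHE


def _receptor_classes(atoms: Sequence[Atom]):
    """Scoring classes for receptor heavy atoms by element (walls/proteins)."""
    classes = []
    for a in atoms:
        t = {"C": "C.3", "N": "N.3", "O": "O.3", "S": "S.3",
             "P": "P.3"}.get(a.element, a.element)
        # receptor polarity: carbons hydrophobic, O/N acceptors (no explicit H info)
        classes.append(scoring_parameters(t, ("C",) if a.element == "C" else ("C",)))
    return classes


def _ligand_arrays(substrate: TypedMolecule, mode: str):
    if mode == "probe":
        return [0], [_probe_class()]
    heavy, classes = molecule_scoring_classes(substrate)
    return heavy, classes


def energy_profile(substrate: TypedMolecule, tunnel: Tunnel,
                   snapshot: Sequence[Atom], mode: str = "chain",
                   stride: int = 1,
                   options: ScoreOptions = ScoreOptions(),
                   keep_per_residue: bool = False) -> TunnelRecord:
    """Score the substrate at every admissible anchor of one tunnel.

    Anchors advance every ``stride`` spheres; in chain mode an anchor is
    admissible when the chain fits the remaining spheres.  Geometric
    descriptors are attached from the tunnel itself.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    heavy_idx, lig_classes = _ligand_arrays(substrate, mode)
    n_sph = len(tunnel.spheres)
    chain_len = 1 if mode == "probe" else len(_longest_chain(substrate))
    anchors = [a for a in range(0, n_sph - chain_len + 1, stride)]
    if not anchors:
        raise TunnelprofError("no admissible anchor for this substrate/tunnel")

    rec_heavy = [a for a in snapshot if not a.is_hydrogen]
    rec_pos = np.array([a.position for a in rec_heavy])
    rec_classes = _receptor_classes(rec_heavy)
    residues = [(a.chain_id, a.residue_id, a.residue_name) for a in rec_heavy]

    profile, per_res = [], []
    for a0 in anchors:
        pl = thread_substrate(substrate, tunnel, mode, a0)
        bd = score_pose(pl.ligand_positions, lig_classes, rec_pos, rec_classes,
                        options, receptor_residues=residues if keep_per_residue else None)
        profile.append(bd.total)
        if keep_per_residue:
            per_res.append(bd.per_residue)

    bi, br = bottleneck(tunnel)
    try:
        bend = bend_angle(tunnel)
    except TunnelprofError:
        bend = None
    return TunnelRecord(
        snapshot_id=tunnel.snapshot_id, tunnel_id=tunnel.tunnel_id,
        length=arc_length(tunnel),
        curvature=curvature(tunnel) if len(tunnel) > 1 else 1.0,
        bend_angle=bend, bottleneck_radius=br, bottleneck_index=bi,
        anchors=anchors, profile=profile, per_residue=per_res)


def profile_trajectory(ensemble: StructureEnsemble, tunnels: Sequence[Tunnel],
                       substrates: Sequence[TypedMolecule] | TypedMolecule,
                       mode: str = "chain", stride: int = 1,
                       options: ScoreOptions = ScoreOptions(),
                       keep_per_residue: bool = False,
                       progress: bool = False) -> list[TunnelRecord]:
    """One record per (snapshot, tunnel, substrate), deterministic order."""
    if isinstance(substrates, TypedMolecule):
        substrates = [substrates]
    known = set(ensemble.snapshot_ids)
    for t in tunnels:
        if t.snapshot_id not in known:
            raise TunnelprofError(
                f"tunnel {t.tunnel_id} references unknown snapshot {t.snapshot_id}")
    records = []
    order = sorted(tunnels, key=lambda t: (t.snapshot_id, t.tunnel_id))
    for t in order:
        snap = ensemble.snapshot(t.snapshot_id)
        for s_i, sub in enumerate(substrates):
            rec = energy_profile(sub, t, snap, mode=mode, stride=stride,
                                 options=options, keep_per_residue=keep_per_residue)
            records.append(rec)
            if progress:
                print(f"snapshot {t.snapshot_id} tunnel {t.tunnel_id} "
                      f"substrate {s_i}: min score {rec.min_score:.3f}")
    return records


def select_compatible(records: Sequence[TunnelRecord],
                      score_threshold: float | None = None) -> list[TunnelRecord]:
    """Records whose best (minimum) profile score is <= the threshold.

    Default threshold: the 25th percentile of all min-scores (scale-free).
    Stable order; idempotent; monotone in the threshold.
    """
    records = list(records)
    if not records:
        return []
    if score_threshold is None:
        score_threshold = float(np.percentile([r.min_score for r in records], 25))
    return [r for r in records if r.min_score <= score_threshold]


_QUANTITIES = ("length", "curvature", "bottleneck_radius", "min_score")


def summarize(records: Sequence[TunnelRecord],
              extreme_by: str = "bottleneck") -> TrajectorySummary:
    """Smallest/largest-tunnel statistics across snapshots.

    Per snapshot, the smallest tunnel has minimal bottleneck radius and the
    largest maximal bottleneck radius (ties broken by shorter length);
    ``extreme_by="length"`` ranks by tunnel length instead.  Statistics
    (mean, sd, min, max) of length, curvature, bottleneck radius and minimum
    profile score are aggregated across snapshots for the two series.
    """
    records = list(records)
    if not records:
        raise TunnelprofError("summarize requires at least one record")
    if extreme_by not in ("bottleneck", "length"):
        raise ValueError("extreme_by must be 'bottleneck' or 'length'")
    by_snap: dict[int, list[TunnelRecord]] = {}
    for r in records:
        by_snap.setdefault(r.snapshot_id, []).append(r)

    def keyfun(r):
        if extreme_by == "bottleneck":
            return (r.bottleneck_radius, r.length)
        return (r.length, r.bottleneck_radius)

    series = {"smallest": [], "largest": []}
    for snap in sorted(by_snap):
        recs = by_snap[snap]
        series["smallest"].append(min(recs, key=keyfun))
        series["largest"].append(max(recs, key=lambda r: (keyfun(r)[0], -keyfun(r)[1])))

    rows = []
    for name, recs in series.items():
        for q in _QUANTITIES:
            vals = np.array([getattr(r, q) if q != "min_score" else r.min_score
                             for r in recs])
            rows.append({"series": name, "quantity": q,
                         "mean": vals.mean(), "sd": vals.std(ddof=0),
                         "min": vals.min(), "max": vals.max()})
    stats = pd.DataFrame(rows).set_index(["series", "quantity"])

    counts: dict[int, int] = {}
    for r in records:
        counts[r.tunnel_id] = counts.get(r.tunnel_id, 0) + 1
    return TrajectorySummary(stats=stats, counts=counts,
                             n_snapshots=len(by_snap))


def records_to_frame(records: Sequence[TunnelRecord]) -> pd.DataFrame:
    """Flat table of records (one row per record) for CSV export."""
    return pd.DataFrame([{
        "snapshot_id": r.snapshot_id, "tunnel_id": r.tunnel_id,
        "length": r.length, "curvature": r.curvature,
        "bend_angle": r.bend_angle, "bottleneck_radius": r.bottleneck_radius,
        "bottleneck_index": r.bottleneck_index,
        "min_score": r.min_score, "min_anchor": r.min_anchor,
    } for r in records])


def per_residue_matrix(records: Sequence[TunnelRecord]) -> pd.DataFrame:
    """Residues x snapshots heatmap matrix of best-anchor per-residue scores.

    For each record the per-residue decomposition at the minimum-score anchor
    is used; records must have been profiled with ``keep_per_residue=True``.
    """
    cols = {}
    for r in records:
        if not r.per_residue:
            raise TunnelprofError("records lack per-residue data; "
                                  "profile with keep_per_residue=True")
        best = int(np.argmin(r.profile))
        col = {f"{c}:{i}:{n}": v for (c, i, n), v in r.per_residue[best].items()}
        cols[(r.snapshot_id, r.tunnel_id)] = col
    df = pd.DataFrame(cols).fillna(0.0)
    df.columns = [f"s{snap}_t{tid}" for snap, tid in df.columns]
    return df.sort_index()
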