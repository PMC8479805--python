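"""From-scratch implementation of the empirical pairwise docking score.

The score is the weighted sum, over ligand-receptor heavy-atom pairs within
an 8 A center-center cutoff, of five terms of the surface distance
d = |p1 - p2| - r1 - r2:

    gauss1      exp(-(d/0.5)^2)
    gauss2      exp(-((d-3)/2)^2)
    repulsion   d^2 for d < 0, else 0
    hydrophobic linear ramp 1 -> 0 over d in [0.5, 1.5] (both atoms hydrophobic)
    hbond       linear ramp 1 -> 0 over d in [-0.7, 0] (donor-acceptor pairs)

with the published weights.  Hydrogens never enter the score; they only set
donor flags upstream.  An optional Coulomb term over partial charges and an
optional rotor normalization are off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ScoringAtomClass",
    "PairTerms",
    "ScoreBreakdown",
    "ScoreOptions",
    "surface_distance",
    "pair_terms",
    "score_pose",
    "per_residue_decomposition",
    "CUTOFF",
    "WEIGHTS",
]

CUTOFF = 8.0  # center-center interaction cutoff, Angstrom

# term weights (see data/vina_weights.tsv for the packaged, overridable copy)
WEIGHTS = {
    "gauss1": -0.035579,
    "gauss2": -0.005156,
    "repulsion": 0.840245,
    "hydrophobic": -0.035069,
    "hbond": -0.587439,
}
ROTOR_WEIGHT = 0.05846
COULOMB_K = 332.06  # kcal*A/(mol*e^2)


@dataclass(frozen=True)
class ScoringAtomClass:
    """Per-atom scoring parameters: vdW radius plus interaction flags."""

    vdw_radius: float
    hydrophobic: bool = False
    donor: bool = False
    acceptor: bool = False
    charge: float | None = None

    def __post_init__(self):
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


@dataclass(frozen=True)
class PairTerms:
    gauss1: float
    gauss2: float
    repulsion: float
    hydrophobic: float
    hbond: float
    electrostatic: float = 0.0

    def weighted(self, weights: dict = WEIGHTS, w_elec: float = 0.0) -> float:
        return (weights["gauss1"] * self.gauss1
                + weights["gauss2"] * self.gauss2
                + weights["repulsion"] * self.repulsion
                + weights["hydrophobic"] * self.hydrophobic
                + weights["hbond"] * self.hbond
                + w_elec * self.electrostatic)


@dataclass
class ScoreBreakdown:
    """Total score with per-term and per-residue decompositions (kcal/mol scale)."""

    total: float
    per_term: dict
    per_residue: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ScoreOptions:
    """Scoring options: optional electrostatics and rotor normalization."""

    electrostatics: bool = False
    electrostatic_weight: float = 0.1406  # only used when electrostatics=True
    n_rotors: int = 0
    rotor_penalty: bool = False
    cutoff: float = CUTOFF
    weights: dict = field(default_factory=lambda: dict(WEIGHTS))


def surface_distance(p1, p2, c1: ScoringAtomClass, c2: ScoringAtomClass) -> float:
    """Center distance minus both scoring radii; negative means overlap."""
    return float(np.linalg.norm(np.asarray(p1, float) - np.asarray(p2, float))
                 - c1.vdw_radius - c2.vdw_radius)


def _ramp(d: float, lo: float, hi: float) -> float:
    """1 below lo, 0 above hi, linear in between."""
    if d <= lo:
        return 1.0
    if d >= hi:
        return 0.0
    return (hi - d) / (hi - lo)


def pair_terms(d: float, c1: ScoringAtomClass, c2: ScoringAtomClass,
               center_distance: float | None = None,
               cutoff: float = CUTOFF) -> PairTerms:
    """The five term values at surface distance ``d`` for one atom pair.

    Pairs whose center distance exceeds the cutoff contribute all-zero terms.
    """
    if center_distance is None:
        center_distance = d + c1.vdw_radius + c2.vdw_radius
    if center_distance > cutoff:
        return PairTerms(0.0, 0.0, 0.0, 0.0, 0.0)
    g1 = float(np.exp(-((d / 0.5) ** 2)))
    g2 = float(np.exp(-(((d - 3.0) / 2.0) ** 2)))
    rep = d * d if d < 0 else 0.0
    hyd = _ramp(d, 0.5, 1.5) if (c1.hydrophobic and c2.hydrophobic) else 0.0
    donor_acceptor = (c1.donor and c2.acceptor) or (c2.donor and c1.acceptor)
    hb = _ramp(d, -0.7, 0.0) if donor_acceptor else 0.0
    elec = 0.0
    if c1.charge is not None and c2.charge is not None and center_distance > 0:
        elec = c1.charge * c2.charge / center_distance
    return PairTerms(g1, g2, rep, hyd, hb, elec)


def _class_arrays(classes: Sequence[ScoringAtomClass]):
    return (np.array([c.vdw_radius for c in classes]),
            np.array([c.hydrophobic for c in classes], bool),
            np.array([c.donor for c in classes], bool),
            np.array([c.acceptor for c in classes], bool),
            np.array([c.charge if c.charge is not None else np.nan
                      for c in classes]))


def _pairwise_terms(lig_pos, lig_cls, rec_pos, rec_cls, cutoff):
    """Vectorized all-pairs term matrices, zeroed beyond the cutoff."""
    lr, lh, ld, la, lq = _class_arrays(lig_cls)
    rr, rh, rd, ra, rq = _class_arrays(rec_cls)
    diff = lig_pos[:, None, :] - rec_pos[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    within = dist <= cutoff
    d = dist - lr[:, None] - rr[None, :]

    g1 = np.exp(-((d / 0.5) ** 2)) * within
    g2 = np.exp(-(((d - 3.0) / 2.0) ** 2)) * within
    rep = np.where(d < 0, d * d, 0.0) * within
    ramp_h = np.clip((1.5 - d) / 1.0, 0.0, 1.0)
    hyd = ramp_h * (lh[:, None] & rh[None, :]) * within
    ramp_b = np.clip((0.0 - d) / 0.7, 0.0, 1.0)
    da = (ld[:, None] & ra[None, :]) | (la[:, None] & rd[None, :])
    hb = ramp_b * da * within
    with np.errstate(divide="ignore", invalid="ignore"):
        elec = np.where((dist > 0) & within, lq[:, None] * rq[None, :] / dist, 0.0)
    elec = np.nan_to_num(elec)
    return {"gauss1": g1, "gauss2": g2, "repulsion": rep,
            "hydrophobic": hyd, "hbond": hb, "electrostatic": elec}


def score_pose(ligand_positions, ligand_classes: Sequence[ScoringAtomClass],
               receptor_positions, receptor_classes: Sequence[ScoringAtomClass],
               options: ScoreOptions = ScoreOptions(),
               receptor_residues: Sequence | None = None) -> ScoreBreakdown:
    """Score a rigid ligand pose against receptor heavy atoms.

    Intermolecular pairs only; the caller passes heavy atoms.  When
    ``receptor_residues`` labels each receptor atom, the per-residue
    decomposition is filled (its values sum to the total).
    """
    lig_pos = np.atleast_2d(np.asarray(ligand_positions, float))
    rec_pos = np.atleast_2d(np.asarray(receptor_positions, float))
    if len(ligand_classes) != lig_pos.shape[0]:
        raise ValueError("one scoring class per ligand atom required")
    if len(receptor_classes) != rec_pos.shape[0]:
        raise ValueError("one scoring class per receptor atom required")
    per_term = {k: 0.0 for k in WEIGHTS}
    if rec_pos.shape[0] == 0 or lig_pos.shape[0] == 0:
        return ScoreBreakdown(total=0.0, per_term=per_term)

    mats = _pairwise_terms(lig_pos, ligand_classes, rec_pos, receptor_classes,
                           options.cutoff)
    w = dict(options.weights)
    contrib = sum(w[k] * mats[k] for k in WEIGHTS)
    if options.electrostatics:
        contrib = contrib + options.electrostatic_weight * mats["electrostatic"]
    total = float(contrib.sum())
    per_term = {k: float((w[k] * mats[k]).sum()) for k in WEIGHTS}
    if options.electrostatics:
        per_term["electrostatic"] = float(
            (options.electrostatic_weight * mats["electrostatic"]).sum())

    norm = 1.0
    if options.rotor_penalty:
        norm = 1.0 + ROTOR_WEIGHT * options.n_rotors
        total /= norm
        per_term = {k: v / norm for k, v in per_term.items()}

    per_residue: dict = {}
    if receptor_residues is not None:
        per_atom = contrib.sum(axis=0) / norm
        for res, val in zip(receptor_residues, per_atom):
            per_residue[res] = per_residue.get(res, 0.0) + float(val)
    return ScoreBreakdown(total=total, per_term=per_term, per_residue=per_residue)


def per_residue_decomposition(ligand_positions, ligand_classes,
                              receptor_positions, receptor_classes,
                              receptor_residues,
                              options: ScoreOptions = ScoreOptions()) -> dict:
    """Map residue -> summed weighted contribution (sums to the pose total)."""
    bd = score_pose(ligand_positions, ligand_classes, receptor_positions,
                    receptor_classes, options, receptor_residues=receptor_residues)
    return bd.per_residue
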