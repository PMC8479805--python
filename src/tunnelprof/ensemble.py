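"""Clustered-trajectory binding-free-energy estimate (MM/GBSA + RRHO).

The trajectory of the complex is clustered into k groups (default 10) by
pairwise least-squares-superposition RMSD with k-medoids; the medoid of each
cluster is its representative.  For every representative, receptor and
ligand are taken from the same snapshot (single-trajectory approximation)
and three contributions are computed:

* dE_MM   — intermolecular molecular-mechanics energy: Lennard-Jones with a
  generic per-element table (Lorentz-Berthelot combination) plus Coulomb over
  partial charges, no cutoff.  A simplified surrogate for a full force field.
* dG_solv — generalized-Born polar term (HCT pairwise-descreening Born
  radii) plus gamma*SASA + b nonpolar term; binding contribution is
  G(complex) - G(receptor) - G(ligand).
* TdS     — rigid-rotor/harmonic-oscillator ligand entropy: Sackur-Tetrode
  translation (1 M standard state for binding), rigid-rotor rotation from the
  principal moments of inertia, vibrations only when frequencies are
  supplied.

dG_bind = dE_MM + dG_solv - TdS per cluster and as the cluster-size-weighted
average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import constants
from scipy.spatial.transform import Rotation

from .errors import TunnelprofError
from .structio import StructureEnsemble, _load_table

__all__ = [
    "ClusterResult",
    "DecompositionResult",
    "kabsch_rmsd",
    "cluster_medoids",
    "mm_energy",
    "gbsa_solvation",
    "gb_polar_energy",
    "born_radii_hct",
    "rrho_entropy",
    "binding_free_energy",
]

log = logging.getLogger(__name__)

COULOMB_K = 332.06  # kcal*A/(mol*e^2)
EPS_IN = 1.0
EPS_OUT = 78.5
SASA_GAMMA = 0.00542  # kcal/(mol*A^2)
SASA_B = 0.92  # kcal/mol

_LJ = _load_table("lj.tsv")

# HCT descreening scaling factors per element; dielectric offset 0.09 A
_HCT_SCALE = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85, "S": 0.96, "P": 0.86}
_HCT_OFFSET = 0.09
# intrinsic (mbondi-like) radii for Born-radius integration, A
_GB_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.50, "S": 1.80,
             "P": 1.85, "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98}

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
           "P": 30.974, "F": 18.998, "Cl": 35.45, "Br": 79.904, "I": 126.904}


@dataclass
class ClusterResult:
    labels: np.ndarray  # cluster id per snapshot
    medoid_ids: list[int]  # snapshot index per cluster
    k: int

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class DecompositionResult:
    dE_MM: float
    dG_solv: float
    TdS: float
    dG_bind: float
    per_cluster: list[dict] = field(default_factory=list)
    weights: np.ndarray | None = None
    per_residue_dE_MM: dict | None = None

    @property
    def dH(self) -> float:
        """Enthalpy-like term: dE_MM + dG_solv."""
        return self.dE_MM + self.dG_solv


# ---------------------------------------------------------------------------
# RMSD and clustering
# ---------------------------------------------------------------------------

def kabsch_rmsd(A: np.ndarray, B: np.ndarray,
                subset: np.ndarray | None = None) -> float:
    """Least-squares superposition RMSD (proper rotation only), Angstrom."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if subset is not None:
        subset = np.asarray(subset)
        if subset.dtype == bool:
            subset = np.flatnonzero(subset)
        A, B = A[subset], B[subset]
    if A.shape != B.shape:
        raise TunnelprofError(f"atom count mismatch: {A.shape} vs {B.shape}")
    if A.shape[0] < 3:
        raise TunnelprofError("need >= 3 atoms for superposition")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    _, rssd = Rotation.align_vectors(Ac, Bc)
    return float(rssd / np.sqrt(A.shape[0]))


def _rmsd_matrix(ensemble: StructureEnsemble,
                 subset: np.ndarray | None) -> np.ndarray:
    n = ensemble.n_snapshots
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = kabsch_rmsd(ensemble.coords[i],
                                            ensemble.coords[j], subset)
    return M


def cluster_medoids(ensemble: StructureEnsemble, k: int = 10,
                    subset: np.ndarray | None = None,
                    seed: int = 0, max_iter: int = 100) -> ClusterResult:
    """k-medoids (PAM) on the pairwise superposition-RMSD matrix.

    Seeded initialization (k-medoids++-style greedy spread), then alternating
    assignment / medoid-update sweeps until the objective stops improving.
    Deterministic for a fixed seed.
    """
    n = ensemble.n_snapshots
    if k > n:
        raise TunnelprofError(f"k={k} exceeds number of snapshots n={n}")
    D = _rmsd_matrix(ensemble, subset)
    rng = np.random.default_rng(seed)

    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        d = D[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(d)))  # farthest-point seeding
    medoids = list(dict.fromkeys(medoids))
    while len(medoids) < k:  # pathological duplicates (all-identical snapshots)
        for c in range(n):
            if c not in medoids:
                medoids.append(c)
                break

    def assign(meds):
        return np.argmin(D[:, meds], axis=1)

    labels = assign(medoids)
    obj = D[np.arange(n), [medoids[l] for l in labels]].sum()
    for _ in range(max_iter):
        new_medoids = []
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                new_medoids.append(medoids[c])
                continue
            sub = D[np.ix_(members, members)]
            new_medoids.append(int(members[np.argmin(sub.sum(axis=1))]))
        new_labels = assign(new_medoids)
        new_obj = D[np.arange(n), [new_medoids[l] for l in new_labels]].sum()
        if new_obj >= obj - 1e-12 and new_medoids == medoids:
            break
        if new_obj > obj + 1e-9:  # PAM-style guarantee: never worsen
            break
        medoids, labels, obj = new_medoids, new_labels, new_obj
    return ClusterResult(labels=np.asarray(labels), medoid_ids=list(medoids), k=k)


# ---------------------------------------------------------------------------
# Molecular-mechanics interaction energy
# ---------------------------------------------------------------------------

def _lj_params(elements: Sequence[str]):
    eps, sig = [], []
    for e in elements:
        e = e.capitalize()
        if e not in _LJ:
            raise TunnelprofError(f"no Lennard-Jones parameters for element {e!r}")
        eps.append(_LJ[e][0])
        sig.append(_LJ[e][1])
    return np.array(eps), np.array(sig)


def mm_energy(receptor_pos, receptor_elements, ligand_pos, ligand_elements,
              receptor_charges=None, ligand_charges=None,
              receptor_residues=None) -> float | tuple[float, dict]:
    """Intermolecular LJ + Coulomb energy (kcal/mol), no cutoff.

    When ``receptor_residues`` is given, also returns the per-residue map.
    """
    rp = np.atleast_2d(np.asarray(receptor_pos, float))
    lp = np.atleast_2d(np.asarray(ligand_pos, float))
    re_eps, re_sig = _lj_params(receptor_elements)
    le_eps, le_sig = _lj_params(ligand_elements)
    d = np.linalg.norm(rp[:, None, :] - lp[None, :, :], axis=2)
    if np.any(d < 1e-6):
        raise TunnelprofError("overlapping atoms in mm_energy")
    sig = 0.5 * (re_sig[:, None] + le_sig[None, :])
    eps = np.sqrt(re_eps[:, None] * le_eps[None, :])
    sr6 = (sig / d) ** 6
    lj = 4.0 * eps * (sr6 * sr6 - sr6)
    coul = np.zeros_like(d)
    if receptor_charges is not None and ligand_charges is not None:
        qr = np.asarray(receptor_charges, float)
        ql = np.asarray(ligand_charges, float)
        coul = COULOMB_K * qr[:, None] * ql[None, :] / d
    per_atom = (lj + coul).sum(axis=1)
    total = float(per_atom.sum())
    if receptor_residues is not None:
        per_res: dict = {}
        for res, v in zip(receptor_residues, per_atom):
            per_res[res] = per_res.get(res, 0.0) + float(v)
        return total, per_res
    return total


# ---------------------------------------------------------------------------
# GBSA solvation
# ---------------------------------------------------------------------------

def born_radii_hct(pos: np.ndarray, elements: Sequence[str]) -> np.ndarray:
    """Effective Born radii from HCT pairwise descreening (A)."""
    pos = np.atleast_2d(np.asarray(pos, float))
    n = pos.shape[0]
    rho = np.array([_GB_RADII.get(e.capitalize(), 1.7) for e in elements]) - _HCT_OFFSET
    scale = np.array([_HCT_SCALE.get(e.capitalize(), 0.80) for e in elements])
    inv_a = 1.0 / rho
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j == i:
                continue
            r = float(np.linalg.norm(pos[i] - pos[j]))
            sj = scale[j] * rho[j]
            if rho[i] >= r + sj:
                continue  # atom j fully inside atom i's radius: no descreening
            U = r + sj
            L = max(rho[i], abs(r - sj))
            acc += 0.5 * (1.0 / L - 1.0 / U + 0.25 * r * (1.0 / U**2 - 1.0 / L**2)
                          + 0.5 / r * np.log(L / U)
                          + 0.25 * sj * sj / r * (1.0 / L**2 - 1.0 / U**2))
        inv_a[i] -= acc
    inv_a = np.maximum(inv_a, 1e-3)  # guard against deeply buried overflow
    return 1.0 / inv_a


def gb_polar_energy(pos: np.ndarray, charges: np.ndarray,
                    born: np.ndarray, eps_out: float = EPS_OUT) -> float:
    """Generalized-Born polar solvation energy (kcal/mol).

    E = -k/2 (1 - 1/eps_out) sum_ij q_i q_j / f_GB with
    f_GB = sqrt(r^2 + a_i a_j exp(-r^2 / (4 a_i a_j))); the i = j term reduces
    to the Born formula.
    """
    pos = np.atleast_2d(np.asarray(pos, float))
    q = np.asarray(charges, float)
    a = np.asarray(born, float)
    r2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    aa = a[:, None] * a[None, :]
    f = np.sqrt(r2 + aa * np.exp(-r2 / (4.0 * aa)))
    return float(-0.5 * COULOMB_K * (1.0 - 1.0 / eps_out)
                 * (q[:, None] * q[None, :] / f).sum())


def _sasa(pos: np.ndarray, elements: Sequence[str]) -> float:
    """Shrake-Rupley solvent-accessible surface area via biotite (A^2)."""
    import biotite.structure as struc

    pos = np.atleast_2d(np.asarray(pos, float))
    n = pos.shape[0]
    arr = struc.AtomArray(n)
    arr.coord = pos.astype(np.float32)
    arr.element = np.array([e.upper() for e in elements])
    arr.atom_name = np.array([f"{e.upper()}{i+1}"[:4] for i, e in enumerate(elements)])
    arr.res_id = np.ones(n, int)
    arr.res_name = np.array(["LIG"] * n)
    arr.chain_id = np.array(["A"] * n)
    arr.hetero = np.array([True] * n)
    vals = struc.sasa(arr, vdw_radii="Single", point_number=240)
    return float(np.nansum(vals))


def gbsa_solvation(pos, elements, charges, born: np.ndarray | None = None,
                   sasa: bool = True) -> float:
    """G_solv of one species: GB polar + (gamma*SASA + b) nonpolar, kcal/mol."""
    pos = np.atleast_2d(np.asarray(pos, float))
    if born is None:
        born = born_radii_hct(pos, elements)
    polar = gb_polar_energy(pos, charges, born)
    nonpolar = SASA_GAMMA * _sasa(pos, elements) + SASA_B if sasa else 0.0
    return polar + nonpolar


def gbsa_binding(complex_pos, complex_elements, complex_charges,
                 receptor_index, ligand_index) -> float:
    """dG_solv of binding = G(complex) - G(receptor) - G(ligand)."""
    complex_pos = np.atleast_2d(np.asarray(complex_pos, float))
    elements = list(complex_elements)
    q = np.asarray(complex_charges, float)
    ri = np.asarray(receptor_index)
    li = np.asarray(ligand_index)
    g_c = gbsa_solvation(complex_pos, elements, q)
    g_r = gbsa_solvation(complex_pos[ri], [elements[i] for i in ri], q[ri])
    g_l = gbsa_solvation(complex_pos[li], [elements[i] for i in li], q[li])
    return g_c - g_r - g_l


# ---------------------------------------------------------------------------
# RRHO entropy
# ---------------------------------------------------------------------------

R_GAS = constants.R  # J/(mol K)
KCAL = 4184.0  # J per kcal


def translational_entropy(mass_amu: float, temperature: float = 298.15,
                          standard_state: str = "1M") -> float:
    """Sackur-Tetrode translational entropy, J/(mol K).

    ``standard_state`` "1M" uses the 1 mol/L molar volume (binding
    convention); "1bar" uses the ideal-gas molar volume at 1 bar.
    """
    m = mass_amu * constants.atomic_mass
    kT = constants.k * temperature
    lam3 = (2.0 * np.pi * m * kT / constants.h**2) ** 1.5
    if standard_state == "1M":
        v = 1e-3 / constants.N_A  # m^3 per molecule at 1 mol/L
    elif standard_state == "1bar":
        v = kT / 1e5
    else:
        raise ValueError("standard_state must be '1M' or '1bar'")
    return R_GAS * (np.log(lam3 * v) + 2.5)


def rotational_entropy(masses_amu: np.ndarray, pos: np.ndarray,
                       temperature: float = 298.15,
                       sigma_sym: int = 1) -> float:
    """Rigid-rotor rotational entropy from principal moments, J/(mol K).

    Monoatomic species return 0; linear rotors use the reduced (2D) formula.
    """
    pos = np.atleast_2d(np.asarray(pos, float))
    m = np.asarray(masses_amu, float) * constants.atomic_mass
    if len(m) == 1:
        return 0.0
    x = (pos - (pos * m[:, None]).sum(axis=0) / m.sum()) * 1e-10  # m
    I = np.zeros((3, 3))
    for mi, xi in zip(m, x):
        I += mi * ((xi @ xi) * np.eye(3) - np.outer(xi, xi))
    moments = np.sort(np.linalg.eigvalsh(I))
    kT = constants.k * temperature
    hbar = constants.hbar
    if moments[0] < 1e-52:  # linear rotor
        Ib = moments[-1]
        z = 2.0 * Ib * kT / (hbar**2 * sigma_sym)
        return R_GAS * (np.log(z) + 1.0)
    z = (np.sqrt(np.pi) / sigma_sym
         * (2.0 * kT / hbar**2) ** 1.5 * np.sqrt(np.prod(moments)))
    return R_GAS * (np.log(z) + 1.5)


def vibrational_entropy(frequencies_cm1: np.ndarray,
                        temperature: float = 298.15) -> float:
    """Harmonic-oscillator vibrational entropy, J/(mol K)."""
    nu = np.asarray(frequencies_cm1, float)
    if np.any(nu < 0):
        raise TunnelprofError("negative vibrational frequency")
    if nu.size == 0:
        return 0.0
    theta = constants.h * constants.c * 100.0 * nu / constants.k  # K
    x = theta / temperature
    return float(R_GAS * (x / np.expm1(x) - np.log1p(-np.exp(-x))).sum())


def rrho_entropy(masses_amu, pos, temperature: float = 298.15,
                 vib_frequencies=None, bound_fraction: float = 1.0,
                 standard_state: str = "1M") -> float:
    """T*dS (kcal/mol) for loss of ligand trans+rot (+vib) entropy on binding.

    ``bound_fraction`` scales the assumed fraction of external entropy lost
    (1 = complete immobilization).  Without supplied frequencies the
    vibrational term is 0 (logged notice), matching a rigid ligand.
    """
    masses_amu = np.asarray(masses_amu, float)
    s_trans = translational_entropy(float(masses_amu.sum()), temperature,
                                    standard_state)
    s_rot = rotational_entropy(masses_amu, pos, temperature)
    if vib_frequencies is None:
        log.info("no vibrational frequencies supplied; vibrational entropy = 0")
        s_vib = 0.0
    else:
        s_vib = vibrational_entropy(vib_frequencies, temperature)
    s_total = bound_fraction * (s_trans + s_rot) + s_vib  # J/(mol K)
    return float(temperature * s_total / KCAL)


# ---------------------------------------------------------------------------
# Full decomposition
# ---------------------------------------------------------------------------

def binding_free_energy(ensemble: StructureEnsemble,
                        receptor_index, ligand_index,
                        charges: np.ndarray,
                        k: int = 10, seed: int = 0,
                        subset: np.ndarray | None = None,
                        temperature: float = 298.15,
                        vib_frequencies=None,
                        bound_fraction: float = 1.0,
                        size_weighted: bool = True,
                        per_residue: bool = False) -> DecompositionResult:
    """Clustered single-trajectory MM/GBSA + RRHO binding free energy.

    The complex trajectory is clustered into ``k`` groups; receptor and
    ligand coordinates of each medoid come from the same snapshot.  Results
    are reported per cluster and as the (size-weighted by default) average;
    dG_bind = dE_MM + dG_solv - TdS holds per cluster and for the average.
    """
    ri = np.asarray(receptor_index)
    li = np.asarray(ligand_index)
    if ri.dtype == bool:
        ri = np.flatnonzero(ri)
    if li.dtype == bool:
        li = np.flatnonzero(li)
    if len(ri) == 0 or len(li) == 0:
        raise TunnelprofError("empty receptor or ligand selection")
    charges = np.asarray(charges, float)
    elements = [a.element for a in ensemble.atoms]

    clu = cluster_medoids(ensemble, k=k, subset=subset, seed=seed)
    sizes = clu.sizes().astype(float)
    weights = sizes / sizes.sum() if size_weighted else np.full(clu.k, 1.0 / clu.k)

    lig_elements = [elements[i] for i in li]
    rec_elements = [elements[i] for i in ri]
    lig_masses = np.array([_MASSES.get(e.capitalize(), 12.0) for e in lig_elements])
    residues = [(ensemble.atoms[i].chain_id, ensemble.atoms[i].residue_id,
                 ensemble.atoms[i].residue_name) for i in ri]

    per_cluster = []
    res_acc: dict = {}
    for c, med in enumerate(clu.medoid_ids):
        xyz = ensemble.coords[med]
        if per_residue:
            e_mm, res_map = mm_energy(xyz[ri], rec_elements, xyz[li], lig_elements,
                                      charges[ri], charges[li],
                                      receptor_residues=residues)
            for key, v in res_map.items():
                res_acc[key] = res_acc.get(key, 0.0) + weights[c] * v
        else:
            e_mm = mm_energy(xyz[ri], rec_elements, xyz[li], lig_elements,
                             charges[ri], charges[li])
        g_solv = gbsa_binding(xyz, elements, charges, ri, li)
        tds = rrho_entropy(lig_masses, xyz[li], temperature,
                           vib_frequencies=vib_frequencies,
                           bound_fraction=bound_fraction)
        per_cluster.append({"cluster": c, "medoid_snapshot": ensemble.snapshot_ids[med],
                            "weight": float(weights[c]), "dE_MM": e_mm,
                            "dG_solv": g_solv, "TdS": tds,
                            "dG_bind": e_mm + g_solv - tds})

    dE = float(sum(w * pc["dE_MM"] for w, pc in zip(weights, per_cluster)))
    dS = float(sum(w * pc["dG_solv"] for w, pc in zip(weights, per_cluster)))
    tS = float(sum(w * pc["TdS"] for w, pc in zip(weights, per_cluster)))
    return DecompositionResult(dE_MM=dE, dG_solv=dS, TdS=tS,
                               dG_bind=dE + dS - tS,
                               per_cluster=per_cluster, weights=weights,
                               per_residue_dE_MM=res_acc if per_residue else None)
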