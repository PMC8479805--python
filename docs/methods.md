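# Methods

This note records the models implemented in `tunnelprof`, the assumptions and
defaults behind them, the numerical choices that matter, and what the
synthetic fixtures do and do not establish about real proteins.

## Tunnel representation and geometry

A tunnel is an ordered chain of inscribed spheres (center, radius) along a
centerline, sphere 0 at the buried end near the catalytic serine. Profiles
are read from per-sphere CSV files in a Caver-3-style dialect (snapshot id,
tunnel id, x, y, z, radius; column map configurable) or computed internally.

Descriptors:

- **arc length** — sum of consecutive center distances (Å); 0 for a single
  sphere.
- **curvature** — arc length divided by the straight start-to-end chord.
  Always ≥ 1; exactly 1 for collinear centers. Coincident endpoints are a
  signaled error. The straight, right-angle-L and semicircular shapes give
  the closed forms 1, √2 and π/2.
- **bend angle** — angle between the mean of the first *w* inter-sphere steps
  and the mean of the last *w* (default *w* = 5). The window stabilizes the
  direction estimate against sphere jitter, at the cost of biasing the angle
  of smoothly curved tunnels toward the chord directions; on coarsely sampled
  arcs use a smaller window or denser spheres.
- **bottleneck** — sphere of minimal radius; ties resolve to the smallest arc
  position.
- **lining residues** — residues with a heavy atom within (sphere radius +
  cutoff) of any sphere center, default cutoff 3.0 Å beyond the sphere
  surface, sorted by minimal surface distance.

### Internal tunnel finder

A deterministic grid search substitutes for Voronoi-based tunnel software on
simple structures (Caver-style profile files remain the first-class input).
Clearance at each grid node is the distance to the nearest heavy-atom vdW
surface; nodes with clearance below `min_probe_radius` (default 0.9 Å) are
closed. A Dijkstra variant maximizes the minimum clearance from the start to
bulk solvent, where "bulk" means clearance ≥ `surface_depth` (default 3.5 Å,
the maximal depth of the surface region). The reported centerline is the
shortest grid path that realizes that widest bottleneck, truncated at the
first bulk node; sphere radii are the local clearances. Default grid spacing
0.5 Å. The estimate is conservative: grid nodes sample the channel axis to
within one spacing, so reported bottleneck radii are lower bounds that
converge to the analytic channel radius as the grid is refined.

## Atom typing and PEOE charges

SYBYL types are assigned from element plus bond environment; bonds are
perceived, when absent, by the covalent-distance rule
d < r_cov(i) + r_cov(j) + 0.45 Å. Aromatic carbon requires membership in a
5/6-ring with ring bonds < 1.45 Å; carbonyl-type oxygens are recognized by
degree and C–O distance (< 1.30 Å) or an explicit bond order. Explicit
hydrogens are expected for reliable hybridization assignment of unsaturated
carbons.

Partial charges use the iterative partial-equalization-of-orbital-
electronegativities scheme: χ(q) = a + bq + cq², with the published a/b/c per
type in a packaged plain-text table; each iteration n transfers
(χ_j − χ_i)/χ⁺ · (1/2)ⁿ across every bond, where χ⁺ is the cation
electronegativity (a+b+c) of the less electronegative partner and 20.02 for
hydrogen. Six iterations (configurable) reproduce the method's convergent
schedule; total charge is conserved exactly, and the per-iteration maximum
transfer decreases strictly (recorded as `peoe_convergence_`). Methane comes
out at C ≈ −0.078 e, H ≈ +0.0195 e; an independent implementation (rdkit)
agrees within 0.01 e on small molecules. Formal charges are taken from mol2
input when present, else molecules are assumed neutral — no protonation-state
prediction is attempted.

## Scoring function

The pose score is the weighted sum over ligand–receptor heavy-atom pairs
within 8 Å (center–center) of five terms of the surface distance
d = r − R₁ − R₂: two Gaussians (widths 0.5 and 2 Å, the second offset 3 Å),
quadratic repulsion for d < 0, a hydrophobic ramp 1→0 over d ∈ [0.5, 1.5] Å
for hydrophobic–hydrophobic pairs, and an H-bond ramp 1→0 over d ∈ [−0.7, 0] Å
for donor–acceptor pairs, with weights −0.035579, −0.005156, 0.840245,
−0.035069, −0.587439. Scoring radii per element: C 1.9, N 1.8, O 1.7, S 2.0,
P 2.1, F 1.5, Cl 1.8, Br 2.0, I 2.2 Å. Carbon is hydrophobic iff bonded only
to C/H; halogens are hydrophobic; N/O donate iff bearing a polar H; O always
accepts, N accepts for lone-pair-bearing types (N.1/N.2/N.ar).

Hydrogens never enter the score; they only set donor flags. Two options are
off by default and never silently mixed in: a Coulomb term over PEOE charges
(the charge model is computed and exposed although the named scoring function
is charge-free — the electrostatic pathway is an explicit opt-in), and the
rotor normalization 1/(1 + 0.05846·N_rot), which is inappropriate for rigid
tunnel threadings. Per-term and per-residue decompositions sum to the total
by construction (each pair's weighted contribution accrues to the receptor
atom's residue).

## Threading and profiles

`probe` mode places one probe heavy atom at a sphere center. `chain` mode
snaps the substrate's longest heavy-atom bond path (the acyl tail) onto
consecutive sphere centers starting at the anchor, preserving chain order —
sphere spacing on fixtures (≈ bond length) makes this a faithful "atoms at
sphere centers" placement — and carries substituent atoms rigidly via the
least-squares (Kabsch) fit of the chain's original onto its placed
coordinates. No pose optimization is performed: the procedure is placement +
scoring, not docking. An energy profile scores every admissible anchor (every
`stride` spheres); records carry the geometry descriptors, the profile, its
minimum and the minimizing anchor.

Across a trajectory, one record per (snapshot, tunnel, substrate) is built.
"Smallest" and "largest" tunnels per snapshot are the extremes of bottleneck
radius (ties → shorter length; ranking by length available as a config
choice), and mean/sd/min/max of length, curvature, bottleneck radius and
minimum score are aggregated over snapshots for the two series.
Binding-compatible conformations are records with minimum score below a
threshold; with no threshold given, the 25th percentile of minimum scores is
used — a deliberately scale-free default, since no absolute compatibility
score is defined by the procedure.

## Clustered binding-free-energy estimate

Snapshots of the complex are clustered into k = 10 groups (default) by
k-medoids (PAM) on the pairwise Kabsch-superposition RMSD matrix (proper
rotations only; atom subset configurable, all atoms by default). Seeding is
deterministic for a given seed (greedy farthest-point after a seeded first
pick), and PAM sweeps never increase the objective. For each medoid,
receptor and ligand coordinates come from the same snapshot — the
single-trajectory approximation — and:

- **ΔE_MM**: intermolecular Lennard-Jones (generic GAFF-like per-element
  ε/σ table, Lorentz–Berthelot combination) plus Coulomb over partial charges
  with k = 332.06 kcal·Å/(mol·e²), no cutoff. This is a deliberately simple,
  fully documented surrogate for a production force field; validation is by
  closed forms and invariances, not by agreement with any specific force
  field's numbers.
- **ΔG_solv**: generalized Born with
  f_GB = √(r² + aᵢaⱼ·exp(−r²/4aᵢaⱼ)), ε_in = 1, ε_out = 78.5, Born radii from
  HCT pairwise descreening (mbondi-like intrinsic radii, offset 0.09 Å,
  per-element scaling factors), plus the nonpolar term γ·SASA + b with
  γ = 0.00542 kcal/(mol·Å²), b = 0.92 kcal/mol (Shrake–Rupley SASA via
  biotite, 240 sphere points). Binding contribution:
  G(complex) − G(receptor) − G(ligand).
- **TΔS**: rigid-rotor/harmonic-oscillator ligand entropy — Sackur–Tetrode
  translation at the 1 M binding standard state (1 bar available for gas-phase
  checks), rigid-rotor rotation from principal moments of inertia (reduced
  formula for linear rotors, zero for monoatomics), and vibrations only when
  frequencies are supplied by the user (no normal-mode engine is included; a
  logged notice marks the omission). The fraction of external entropy lost on
  binding defaults to 1 (complete immobilization) and is configurable.

ΔG_bind = ΔE_MM + ΔG_solv − TΔS holds per cluster and for the average, which
weights clusters by size by default (equal weighting by flag). ΔH is reported
as ΔE_MM + ΔG_solv.

## Synthetic fixtures

`fixtures` builds wall-of-atoms channels: carbon atoms on a tube of radius
(clearance + 1.9 Å) around a straight, L-shaped or semicircular centerline,
sampled every 1 Å of arc with ~1 atom/Å² of tube surface, residues advancing
one per ring. An optional Gaussian pinch (width 2 Å) narrows the clearance to
the requested bottleneck radius; a hemispherical cap can seal the buried end.
Where tube sections overlap (the elbow of the L), wall atoms intruding more
than 0.2 Å into the channel interior are dropped (union-of-tubes carve); a
clearance probe validates the wall and warns on leaks. Ligands are all-trans
chains (C–C 1.53 Å, tetrahedral angles), optionally with an ester head
(carbonyl O.2 + ester O.3 + methyl cap); hydrogens are topological
placeholders with idealized offsets. Pseudo-trajectories add i.i.d. per-atom
Gaussian jitter (snapshot 0 = base); every generator is a pure function of
its spec and seed.

These fixtures have analytic ground truth but are not physical proteins: no
secondary structure, no realistic packing or electrostatics, no conformational
dynamics beyond isotropic jitter. Passing tests therefore establish
correctness of the geometry, scoring, decomposition, clustering and
thermodynamic machinery — not predictive accuracy for any particular enzyme,
and not agreement with energies from production force fields or with
published per-enzyme ΔG/ΔH/TΔS values, which depend on long MD trajectories
outside this package's scope.

## Numerical choices and degenerate inputs

- Profile scoring and tunnel statistics use double precision throughout;
  decomposition conservation is exact to ~1e−14 and asserted at 1e−6.
- Ramp terms are continuous at their breakpoints; beyond the 8 Å cutoff all
  terms are exactly zero.
- Bottleneck ties take the smallest arc position; argmin order makes this
  deterministic.
- Single-sphere tunnels have arc length 0 and undefined curvature/bend
  (signaled); curvature with coincident endpoints is a signaled error.
- Born-radius inversion is floored at 1e−3 Å⁻¹ against overflow for deeply
  buried atoms; lone atoms reduce exactly to the Born formula.
- SASA is point-sampled, so the nonpolar term is rigid-invariant only to
  quadrature accuracy (~1e−2 kcal/mol at 240 points); the GB polar term is
  analytically invariant and tested at 1e−6.
- The PDB writer emits fixed-width records at 3 decimals; round-trips are
  coordinate-stable at that precision. Malformed coordinate fields are
  reported with their line number before parsing; models with inconsistent
  atom counts/ordering are topology errors.
- k-medoids with k = n yields singletons; duplicate snapshots may make medoid
  assignment between identical structures arbitrary but deterministic.

## Problem sizes used in tests and the acceptance script

Channels of 14–24 Å with ~400–900 wall atoms, trajectories of 3–20 snapshots,
ligands of 1–7 heavy atoms, 100-system random batteries for conservation
checks, and a 0.5 Å grid for the internal tunnel search — sizes chosen so the
whole battery completes in well under a minute while every check remains
analytically grounded.
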