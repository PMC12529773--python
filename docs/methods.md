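# Methods

This note records the model, the numerical choices, and the synthetic test
systems used by `ncitraj`. Every number quoted here is computed by the code in
this repository (the unit tests and `scripts/acceptance.py` recompute them);
no external data sets are used.

## Promolecular density model

The electron density of a molecular system is approximated as a sum of
spherically averaged, frozen atomic densities ("promolecular" approximation):

ρ(r) = Σ_A Σ_j c_{A,j} exp(−|r − R_A| / ζ_{A,j})

with per-element coefficients `c` (e/bohr³) and decay lengths `ζ` (bohr)
stored in `src/ncitraj/data/atomic_densities.json` (H: one exponential;
C, N, O: two). Gradients and Hessians of ρ are analytic; for a single
exponential centred at the origin they reduce to closed forms that the test
suite checks against:

* ∇ρ = −(ρ/ζ) r̂,
* Hessian eigenvalues (ρ/ζ²) along r̂ and −ρ/(ζ|r|) (doubly degenerate)
  perpendicular to it.

All analytic derivatives are additionally verified against central finite
differences at random off-nucleus points to better than 1e-5 relative error.

## NCI index

The reduced density gradient

s = |∇ρ| / (2 (3π²)^{1/3} ρ^{4/3})

is small where noncovalent interactions produce local density between
monomers. Points are classified by sign(λ₂)ρ, where λ₂ is the middle
eigenvalue of the density Hessian:

* attractive: sign(λ₂)ρ < −0.02 a.u.
* van der Waals: −0.02 ≤ sign(λ₂)ρ ≤ +0.02 a.u. (threshold ties go to vdW)
* repulsive: sign(λ₂)ρ > +0.02 a.u.

For a residue pair (A, B) the interaction region is the set of grid points
satisfying all of:

* 1e-10 < ρ < 0.05 a.u. (density band),
* s < 1.0 (reduced-gradient cut),
* min(ρ_A, ρ_B)/ρ ≥ 0.05 (both fragments contribute),
* farther than 1e-3 bohr from any nucleus.

The three per-pair integrals are Riemann sums of ρ over the attractive / vdW /
repulsive subsets of that region; by construction
attractive + vdw + repulsive = total to machine precision (asserted at 1e-12).

## Grid and subvoxel quadrature

A rectangular grid with default nominal spacing 0.1 bohr and 2.0 Å margin is
laid over each residue pair (pairs whose minimum heavy-atom distance exceeds
12 Å are prefiltered to exact zeros). Hard selection masks make plain
voxel-center sums converge only O(h) in the spacing h: the attractive basin of
a hydrogen bond is a sub-bohr blob and the s < 1.0 surface passes through its
densest part, so halving the spacing from 0.1 to 0.05 bohr still moved the
attractive integral by several percent.

`pair_integrals` therefore uses a two-phase quadrature:

1. **Scan.** Evaluate ρ and s at voxel centers at the nominal spacing and keep
   voxels passing the selection.
2. **Refine.** Dilate the passing set by one voxel (26-connectivity), then
   re-sample every retained voxel on a subgrid whose pitch is the fixed
   `refine_resolution` (default 0.025 bohr, independent of the nominal
   spacing), re-apply the full selection per subpoint, and integrate with the
   subvoxel volume element. Hessians are evaluated only at passing subpoints.

The nominal spacing then controls only *coverage* (whether a disconnected lobe
of the interaction region is found at all), while the fixed refine resolution
controls quadrature accuracy. With the default resolution the hydrogen-bond
dimer integrals computed at nominal spacings 0.2 and 0.1 bohr agree to better
than 0.1 %, and 0.1 vs 0.05 bohr agree within 2 % per channel. Integrals
change by < 1 % under rigid rotation + translation of the whole system
(grid-orientation artifact check). Setting `refine_resolution=None` reproduces
the bare voxel-center quadrature exactly. Very coarse nominal spacings
(≳ 0.3 bohr) can still miss thin lobes in the scan phase; they are intended
for the smooth screening regime (e.g. the coarse toy-model workflow), not for
converged dimer integrals.

## Hydrogen bonds, SASA, contact maps

Hydrogen bonds are detected geometrically: donors are hydrogens within 1.25 Å
of N or O; a bond requires H···acceptor ≤ 2.5 Å, donor–H···acceptor angle
> 120°, and residues either on different chains or more than 3 apart in
sequence (PDB resSeq). SASA uses the Shrake–Rupley implementation of mdtraj
(960 sphere points, 1.4 Å probe), converted to Å² per residue. Ensemble
contact maps average per-pair vdW and (attractive − repulsive) integrals,
1/d⁶ of minimum heavy-atom distances, and inverse donor–acceptor distances of
recurring hydrogen bonds.

## Folding order parameter and transition detection

The fraction of native contacts uses the soft-switch form

Q(t) = ⟨ 1 / (1 + exp[β (d_ij(t) − λ d_ij⁰)]) ⟩_{native pairs}

with β = 5 Å⁻¹, λ = 1.8, native pairs defined as heavy-atom pairs within
4.5 Å in the reference structure between residues more than 3 apart in
sequence. Basins are Q ≤ 0.1 (unfolded) and Q ≥ 0.9 (folded); a transition
runs from the last exit of one basin to the first entry into the other, which
excludes recrossings by construction. Frames for NCI analysis are sampled
uniformly inside each transition (with flanking frames), and the folded
ensemble provides the normalisation scale for pair profiles.

## Motifs and pathway clustering

Each analysed residue pair contributes a 3-channel (attractive/vdW/repulsive)
time series per transition. Series are smoothed (centred rolling mean),
time-reversed for unfolding events so that all profiles run unfolded → folded,
resampled to 100 progress points, and normalised by the folded-ensemble mean
total. Pairs are clustered into *motifs* in a single global pass — features
from all transitions are concatenated per pair, so a motif identity means the
same thing in every event. Clustering is average-linkage on correlation
distance with silhouette-selected k; weakly correlated pairs are labelled
noise, clusters with indistinguishable half-formation times are merged
(synchrony merge), and singleton remnants are set aside.

Transitions are then described by per-motif mean formation profiles and
clustered into *pathways* with the same agglomerative scheme, choosing k by
majority vote of silhouette, Calinski–Harabasz and Davies–Bouldin scores.
Fewer than 4 transitions, a non-positive best silhouette, or mutually
near-identical profiles (all pairwise correlation distances < 0.05 — the
degenerate single-pathway case) yield one pathway. Labels are renumbered
largest-cluster-first.

## Synthetic test systems

* **Hydrogen-bond dimer**: a collinear N–H···O fragment pair (N–O distance
  2.9 Å by default) with small capping groups.
* **Apolar dimer**: two methane molecules, facing H₃ triangles, C–C distance
  4.0 Å by default. At matched closest-contact distance the H-bond dimer shows
  a large attractive integral while the apolar dimer is vdW-dominated.
* **Toy folding trajectory**: 8 rigid three-atom pseudo-residues; residues
  5–8 move between an unfolded arm and docked positions 4.2 Å above residues
  1–4. Two planted pathways differ in motif order: motif A = pairs (1,5),(2,6)
  and motif B = (3,7),(4,8) form in progress windows [0.10, 0.45] and
  [0.55, 0.90] (order swapped on pathway 2), with smoothstep ramps, alternating
  folding/unfolding events (unfolding is the time reversal of the preceding
  folding schedule) and seeded 0.05 Å coordinate jitter. This gives a known
  ground truth for transition detection, motif recovery, pathway assignment
  and the planted pathway mix.

## Limitations

* The promolecular density ignores relaxation and charge transfer; integrals
  are descriptors, not interaction energies.
* Only H, C, N, O are parameterised in the bundled density table.
* The coarse-spacing screening mode trades lobe coverage for speed (see
  above); converged numbers require nominal spacing ≤ 0.2 bohr with the
  default refine resolution.
* Hydrogen-bond detection requires explicit hydrogens; hydrogen-free coarse
  models get an empty hydrogen-bond channel.
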