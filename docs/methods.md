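# Methods

`adsorbmc` predicts the orientation a rigid protein adopts when it adsorbs
onto a flat hydrophobic surface, by Metropolis Monte Carlo sampling of
rigid-body poses over a periodic graphene sheet, and verifies predicted
orientation mixtures with a calculated amide-I sum-frequency-generation
(SFG) spectrum.

## Energy model

A pose is scored as

```
E = E_vdw + E_solv
E_vdw  = Σ_pairs ε [(Rmin/r)^12 − 2 (Rmin/r)^6]        (protein–surface pairs, r < 10 Å)
E_solv = Σ_atoms σ(group) · SASA(atom)
```

* **Lennard-Jones term.** CHARMM combining rules (`ε = √(ε_i ε_j)`,
  `Rmin = Rmin_i/2 + Rmin_j/2`), plain truncation at the 10 Å cutoff (no
  switching — only pose-to-pose differences matter, and the same truncation
  applies to every pose).  A compact packaged (residue, atom-name) → CHARMM22-type
  parameter table covers protein heavy atoms; graphene carbons use the
  aromatic-carbon type.  Intramolecular terms are a rigid-body constant and
  are excluded.  Electrostatics are absent by construction: the surface is
  neutral carbon.
* **Solvation term.** Each heavy atom belongs to one solvation group —
  hydrophobic sidechain (+100), hydrophilic sidechain (−100), hydrophobic
  backbone Cα/C (+100), hydrophilic backbone O/N (−100), surface carbon
  (+100), all in kJ/(mol·Å²) — and contributes σ·SASA.  Burying hydrophobic
  area (protein hydrophobic face against the hydrophobic sheet) lowers the
  energy; burying hydrophilic area raises it.  This is the entire driving
  force for orientation selection.
* **Hydrogens.** The model is heavy-atom: Cα–H, N–H and sidechain hydrogens
  are represented by their heavy atom, which carries the group label and a
  per-element van der Waals radius (C 1.70, N 1.55, O 1.52, S 1.80 Å).
  Glycine, which has no sidechain heavy atom, contributes backbone groups
  only.

## SASA evaluation

SASA uses the Shrake–Rupley construction: test points on each solvent-expanded
sphere (radius + 1.4 Å probe), a point counting as accessible
when outside every other expanded sphere.  Details that matter:

* **Point set.** A deterministic latitude-ring point set with ring
  populations in multiples of six (default 240 points/atom, 960 for
  validation).  The six-fold azimuthal symmetry makes point-sampled areas —
  and therefore the energy — *exactly* invariant under the honeycomb
  lattice's point-group rotations (120° about an atom site, 60° about a
  hexagon center).  No randomness enters the SASA at any stage.
* **Body-fixed protein points.** The protein's point set rotates with its
  pose, so the intramolecular burial pattern is exactly constant for a rigid
  body and protein-alone SASA is exactly rotation invariant.
* **Surface patch.** SASA on an infinite sheet is regularized by evaluating
  the union of the posed protein with a disc-shaped patch of lattice atoms
  whose radius covers the protein's rotation-invariant bounding sphere plus
  the VDW cutoff and the occlusion range.  The patch is one fixed template
  translated by the lattice vector nearest the protein centroid, so the
  patch's far-field area is a pose-independent constant that cancels exactly
  in the Metropolis energy differences.  Absolute energies therefore contain
  an arbitrary patch constant; only differences are meaningful.
* **Smoothed burial for sampling.** At σ = ±100 kJ/(mol·Å²) a single test
  point flipping between buried and exposed changes the energy by
  ~0.5 Å² × 100 kJ ≈ 20 kBT, which turns the discretized landscape into
  quenched roughness that freezes any Metropolis chain.  The sampler's
  energy model therefore replaces the binary inside/outside test with a
  cubic smoothstep across a band of width `sasa_smoothing` (default 0.3 Å)
  centered on each sphere boundary.  This makes the sampled landscape
  continuous in the pose without moving its minima; setting the width to 0
  recovers the exact binary test, which is always used for *reported* SASA
  values (`adsorbmc.sasa`).

## The sampler

Plain Metropolis at 300 K (`kB = 0.0083145 kJ/(mol·K)`): a proposed
rigid-body move is accepted with probability `min(1, exp(−ΔE/kBT))`; only
accepted poses are logged, and a run ends after a target number of accepted
moves (rejected states are not re-counted, matching the accepted-moves
bookkeeping of the orientation histograms).

**Proposal kernel.** A symmetric two-class mixture:

| class | probability | translation | rotation |
|---|---|---|---|
| small | 0.85 | uniform in [−0.01, 0.01]³ Å | uniform axis, uniform angle ≤ 0.05° |
| large | 0.15 | uniform in [−3, 3]³ Å | uniform axis, uniform angle ≤ 180° |

Both classes are symmetric (the reverse increment has equal density), so the
mixture needs no Hastings correction.  The two scales reflect the two
regimes the surface-tension scale creates: adsorbed basins whose energy
varies by thousands of kJ/mol per Å (thermal widths of order 0.01 Å —
the small steps are calibrated to give roughly 30–60% acceptance there) and
orientation changes such as the amphipathic flip, which cross barriers of
hundreds of kBT and are only reachable by direct large reorientations.  At
equilibrium nearly all large moves are rejected; during the search phase
they are what carries the chain between orientations, reproducing the
characteristic flip-then-converge trajectories.

**Frame bookkeeping.**  Trajectories log accepted poses, indexed by
accepted move — the convention the orientation histograms and contact
profiles use.  Each frame also records its *multiplicity* (1 + the rejected
proposals that followed it): histograms over accepted-only frames are not
Boltzmann-distributed (a state's weight must be its persistence), so any
expectation over the sampled ensemble — e.g. the toy-system validation
against a grid partition function — uses the multiplicity-weighted stream,
the textbook Metropolis estimator.

**Escapes.**  A chain whose minimum protein–surface distance stays above
15 Å for the final 500+ accepted frames is flagged `escaped` (it left and
did not return) and excluded from pooled analyses; escapes are flagged,
never restrained, because a restraining wall would alter the sampled
ensemble.

**Determinism.**  One `numpy` Generator per chain, seeded from the run
seed; identical inputs give bit-identical trajectories.

## Analyses

* **Orientation.** Principal axes are the eigenvectors of the coordinate
  gyration tensor, ordered by descending eigenvalue, with signs fixed
  against a body-fixed reference (centroid → N-terminal Cα) so the angles
  (φ, ψ) of the two major axes against the surface normal are single-valued
  in [0°, 180°] along a trajectory.
* **Free-energy map.** (φ, ψ) histogrammed in 10° bins;
  `G = −kB·T·ln N` on populated bins (T defaults to the sampling
  temperature, 300 K), empty bins masked.  Minima are 8-neighborhood local
  minima at least 1 kBT below the populated-bin median (deepest first, ties
  lexicographic).
* **Contacts.** A residue contacts the surface in a frame when any of its
  atoms is within 6 Å of any lattice atom (minimum image on the infinite
  lattice); ratios are taken over frames where *any* protein atom is within
  the cutoff.
* **Multi-run orchestration.** Independent chains with seeds
  `seed_base + i`; escaped chains are excluded; each surviving chain is
  assigned to the free-energy minimum nearest the modal bin of its final
  10% of frames, and contact profiles are merged per basin
  (frame-weighted).

## Amide-I SFG spectra

One oscillator per peptide bond at the C=O midpoint: unit transition dipole
tilted 20° from the C=O axis toward the amide N in the O–C–N plane; site
frequency 1650 cm⁻¹; axially symmetric Raman tensor (3:1 anisotropy about
the dipole).  Couplings use the transition-dipole (Coulomb dipole–dipole)
form with prefactor 5034 cm⁻¹·Å³ for all pairs; a user-supplied function
can replace the nearest-neighbor couplings (the plug point for
dihedral-map-based couplings).  After diagonalizing the exciton
Hamiltonian, each mode's IR dipole and Raman tensor (eigenvector-weighted
sums) combine as an outer product into χ(2); lab-frame ssp and ppp
effective amplitudes use visible/IR input angles 47°/58°, an SFG angle from
the phase-matching condition at 532 nm, and unit Fresnel factors.  Each
mode contributes a complex Lorentzian (default width 10 cm⁻¹), and the
intensity is `|χ_eff + B·e^{iφ}|²` with background phases 3.5 rad (ssp) and
1.5 rad (ppp).  χ components are azimuthally averaged over 36 equally
spaced rotations about the normal; since each component is a trigonometric
polynomial of degree ≤ 3 in the azimuth, the 36-point average equals the
continuous average exactly, so spectra are exactly independent of the
molecule's in-plane placement.  Orientation mixtures average χ(2)
*coherently* (before squaring): the monolayer contains both orientations in
one coherent layer, so mixed intensities are not the average of the
component intensities.

## Synthetic fixtures and what they do (and do not) show

`build_alpha_helix` produces an ideal α-helix (φ = −57°, ψ = −47°,
standard bond geometry, idealized extended rotamers); for
leucine/lysine sequences with 3.5-residue periodicity this yields an
amphipathic helix with all leucines on one face — the benchmark peptide.
The fixture has no conformational flexibility, no termini capping and no
crystallographic sidechain rotamers; benchmark results show that the
scoring model orients an amphipathic rigid body correctly, not that it
reproduces any particular experimental adsorption free energy.  The
graphene sheet is a single frozen layer; the periodic-image machinery makes
the lattice effectively infinite regardless of the nominal cell size.

The headline benchmark (`adsorbmc.benchmark.lk_benchmark`) runs three
chains of 5000 accepted moves started lysines-down 5 Å above the sheet;
all chains flip to leucines-down, and the modal principal-axis angle over
the converged (second) half of each chain is 87–93°, i.e. the helix lies
essentially parallel to the surface.  These problem sizes keep the full
benchmark in the few-minute range on one CPU core.

## Numerical choices and degenerate inputs

* Coincident atoms are legal in SASA (they do not occlude each other) but a
  protein atom exactly coincident with a surface atom is an error (broken
  pose).
* Collinear atom sets have a degenerate gyration tensor and raise an error
  rather than returning arbitrary axes.
* ΔE = 0 is always accepted; a NaN energy is an error, never silently
  accepted or rejected.
* A chain that rejects 200 000 consecutive proposals raises a stall error
  rather than looping forever.
* Bins with zero counts are masked in free-energy maps, not set to ∞.

## Known limitations

* The surface-tension magnitude (±100 kJ/(mol·Å²), as the model defines
  it) places the adsorbed states thousands of kBT below the desorbed state,
  so converged chains fluctuate in an extremely narrow pose volume and the
  sampled "ensemble" is effectively the basin of one minimum plus the
  search dynamics that found it.  Consequences: escape events from a deeply
  adsorbed pose are impossible rather than merely rare, and free-energy
  contrasts between basins reflect visit counts of the search process more
  than converged thermodynamics.  σ is configurable for users who prefer a
  conventional (~0.02–0.1 kJ/(mol·Å²)) nonpolar surface-tension scale.
* No electrostatics, hence hydrophobic surfaces only; no protein
  flexibility; no protein–protein interactions (sub-monolayer coverage
  assumption).
* TDC is used for *all* amide couplings by default; nearest-neighbor
  couplings through the peptide bond are poorly described by dipole–dipole
  interaction, so calculated spectra are qualitative unless a dihedral-based
  nearest-neighbor map is plugged in.
* χ(2) units are arbitrary; only relative intensities within and between
  calculated spectra are meaningful.
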