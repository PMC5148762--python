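# adsorbmc

Rigid-body Metropolis Monte Carlo prediction of the orientation proteins
adopt when they adsorb onto hydrophobic surfaces, with amide-I
sum-frequency-generation (SFG) spectra for verifying predicted orientation
mixtures.

## Who this is for

Researchers studying protein immobilization on materials (biosensor
functionalization, antibody-capture layers, biomaterial coatings) who need a
fast, desk-scale answer to the question *which face of this protein touches
the surface?* — without running explicit-solvent molecular dynamics.  The
protein is treated as a rigid body over a periodic graphene sheet; sampling
its poses against a simple physics-based score predicts the preferred
adsorbed orientation(s), per-residue contact footprints, and an orientation
free-energy landscape.

## The model

A pose (rigid translation + rotation of the protein above the sheet) is
scored as

    E = E_vdw + E_solv

* `E_vdw` — Lennard-Jones 12-6 protein–surface interactions in the CHARMM
  convention, `ε[(Rmin/r)¹² − 2(Rmin/r)⁶]`, summed within a 10 Å cutoff over
  the periodic lattice.
* `E_solv = Σ σ(group)·SASA(atom)` — a nonpolar solvation term: each heavy
  atom carries a surface-tension weight (hydrophobic sidechain/backbone and
  surface carbon +100, hydrophilic sidechain/backbone −100 kJ/(mol·Å²))
  multiplying its solvent-accessible surface area (Shrake–Rupley, 1.4 Å
  probe).  Burying hydrophobic area against the hydrophobic sheet is
  rewarded; burying hydrophilic area is penalized.

Poses are sampled by plain Metropolis at 300 K (`min(1, exp(−ΔE/kBT))`),
counting accepted moves.  Analyses include principal-axis orientation angles
(φ, ψ) against the surface normal, `G = −kBT ln N` free-energy maps over 10°
orientation bins, per-residue contact ratios (6 Å cutoff), and multi-run
orchestration with escape detection and basin assignment.  The `sfg` module
builds an amide-I exciton Hamiltonian (one oscillator per peptide bond,
transition-dipole couplings), diagonalizes it, and combines IR and Raman
mode strengths into ssp/ppp χ(2) spectra with a fixed nonresonant background
phase — including coherent mixtures of two orientations in one monolayer.

See `docs/methods.md` for the full model description, parameter defaults and
limitations.

## Worked example

The package ships a fixture generator for an amphipathic leucine/lysine
α-helix (all leucines on one helical face).  Starting chains with the
*lysines* facing the sheet, the sampler must discover the flip to
leucines-down:

```python
from adsorbmc.benchmark import lk_benchmark

result = lk_benchmark(n_chains=3, accepted_moves=5000, seed=1)
for c in result.chains:
    print(f"seed {c.seed}: modal phi {c.modal_phi:.1f} deg, "
          f"Leu<6A {c.leu_fraction_final:.2f}, Lys<6A {c.lys_fraction_final:.2f}")
print(f"pooled modal phi {result.pooled_modal_phi:.1f} deg")
```

```
seed 1: modal phi 93.0 deg, Leu<6A 0.72, Lys<6A 0.00
seed 2: modal phi 93.0 deg, Leu<6A 0.72, Lys<6A 0.00
seed 3: modal phi 87.0 deg, Leu<6A 0.75, Lys<6A 0.00
pooled modal phi 93.0 deg
```

Every chain ends with ~¾ of the leucine sidechain atoms within 6 Å of the
sheet and no lysine sidechain atoms near it — the helix flipped — and the
modal angle between the helix's long principal axis and the surface normal
is ~87–93°: the helix lies essentially flat on the surface with its
hydrophobic face down, consistent with SFG measurements of such peptides
(~80°) on hydrophobic surfaces.

The same machinery runs from the shell:

```bash
adsorbmc make-peptide LKKLLKLLKKLLKL --out helix.pdb
adsorbmc build-surface --nx 10 --ny 10 --out graphene.pdb
adsorbmc run-mc --pdb helix.pdb --seed 1 --out-prefix run1 --start-face-down LYS
adsorbmc analyze --traj run1.tsv --pdb helix.pdb --out-prefix ana
adsorbmc sfg-calc --pdb helix.pdb --polarization ssp --out spectrum.csv
```

`run1.tsv` logs every accepted move (pose, energy components, minimum
surface distance, φ/ψ); `ana.femap.tsv` and `ana.minima.json` hold the
orientation free-energy map and its minima; `ana.contacts.tsv` the
per-residue contact ratios.

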