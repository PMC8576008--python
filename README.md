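# cellufacet

Tools for studying how the **exposed crystal facet** of a cellulose II
nanocrystal shapes its surface chemistry: hydroxymethyl rotamer
populations at chain ends, the hydrogen-bond network between terminal
anhydroglucoses, and the relative stability of the chain-sheet families.

Cellulose II packs antiparallel beta-1,4 glucan chains on a monoclinic
lattice (fiber axis *c*).  Cutting the crystal at different Miller planes
exposes different chain-end geometries; this package builds such models,
analyses trajectories of them, and book-keeps the energetics:

* **`crystal`** — atomistic nanocrystal builders.  An `i x i` bundle of
  chains, each of a chosen degree of polymerization (DP), with chain ends
  staggered in whole residues so that they tile a requested facet:
  O = (0 0 1) flat, A = (-1 1 2) inclined, B = (-2 2 1) steeply inclined
  (model names `iLj`, e.g. `6A12`).  The per-chain stagger is
  `n = round(2 (m - h u - k v) / l)` for chain axis `(u, v)` and plane
  offset `m`.
* **`conformers`** — the hydroxymethyl dihedral omega = O5-C5-C6-O6 per
  residue per frame, binned into gt / gg / tg rotamers (+60 / -60 /
  180 deg; windows [0,120), [-120,0), rest), stratified by residue class
  (chain-end outward = omega1, chain-end inward = omega2, internal =
  omega3).
* **`hbonds`** — directed hydrogen-bond typing (`O2H..O6` etc.; donors
  O2/O3/O6, acceptors O2/O3/O4/O5/O6) with geometric criteria
  (O...O <= 3.5 A, D-H...A >= 140 deg), and per-frame fraction
  statistics: F_j^i = x_j^i / N_i, its maximum F_max over samples, the
  N_i-weighted mean F-bar, and a strict >60 % persistence filter.
* **`energetics`** — hydrogen-bond strengths from bond-critical-point
  electron densities, E_HB = -223.08 rho + 0.7423 (kcal/mol, rho in
  a.u.), with weak/medium/strong banding; and the sheet-stability ledger
  dE_bind = E_total - E_i, dE_sheet = E_i + dE_bind (re-referenced,
  BSSE-correctable) with vacuum-vs-water solvent shifts.
* **`synth`** — seed-deterministic synthetic trajectories with planted
  rotamer mixtures and planted donor-acceptor contacts, plus synthetic
  energy tables, so every analysis has a ground-truth recovery test
  without running MD or DFT.
* **`pipeline` / CLI** — end-to-end orchestration with CSV reports and a
  reproducibility manifest.

The package never runs molecular dynamics or electronic-structure
calculations; published quantum-chemistry tables for the six reference
models (6A6, 6A12, 6A19, 10A12, 6B12, 6O12) ship as CSV inputs.

## Worked example

```sh
$ cellufacet build --size 6 --dp 12 --facet A --out 6A12.pdb
6A12: 36 chains, 432 residues; facet anchors coplanar to 1.547 A (normal off by 0.64 deg)
```

36 chains of DP 12 tile the inclined (-1 1 2) facet; the chain-end anchor
atoms lie on the requested Miller plane to within the whole-residue
quantization (the residue rise is c/2 = 5.16 A, so 1.5 A is sub-residue
flatness) and the fitted facet normal is within a degree of the ideal.

```python
>>> from cellufacet import (load_reference_sheet_energies, bind_family_sums,
...                         solvent_shift, hb_energy_from_density)
>>> ledger = load_reference_sheet_energies()
>>> bind_family_sums(ledger, "vacuum").round(3)
model
6A12   -7.660
6B12   -6.330
6O12   -9.647
>>> solvent_shift(ledger)[1]
{'de_sheet_shift_min': -0.4, 'de_sheet_shift_max': -1.3,
 'de_bind_shift_min': -0.9, 'de_bind_shift_max': -2.3}
>>> round(hb_energy_from_density(0.038), 3)
-7.735
```

The flat-facet model 6O12 has the most negative summed binding energy
(-9.647 kcal/mol per residue over its two sheet families): the flat facet
is the most stable, and stability falls as the facet inclines.  On
solvation both dE_sheet and dE_bind relax toward zero by 0.4-2.3 kcal/mol
per residue.  A bond-critical-point density of 0.038 a.u. corresponds to
a medium-strength hydrogen bond of -7.7 kcal/mol.

A full synthetic run (build, 50-frame trajectory, conformer and
hydrogen-bond reports, energy reports, manifest):

```sh
cellufacet run --out report/ --seed 42
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline quantities from
scratch — the density-to-energy map at reference densities, the
sheet-ledger sums and solvent-shift extrema from the bundled reference
table, the 10A12 builder chain count — and runs a 500-frame
6 x 6 x 12 synthetic-trajectory recovery pass as a sanity gate:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
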