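# nlsgeom

Geometric analysis of nuclear localization signal (NLS) binding at the two
peptide-binding sites of importin α.

## The problem

Importin α recognizes NLS peptides through two grooves on the concave face
of its armadillo-repeat domain: the **major site** (Arm2–Arm4) and the
**minor site** (Arm7–Arm8).  Each site is organized around conserved
tryptophan pockets, and peptide residues are indexed relative to those
pockets: at the minor site the pocket between W399 and W357 (mouse
numbering) defines the **P2′** position, with P1′ upstream and P3′, P4′, …
downstream; at the major site the pocket between W231 and W184 defines
**P3**.  A small class of NLSs carrying the signature motif
**KRx(W/F/Y)xxAF** ("Class 3") binds selectively at the minor site, with
the KR pair in the P1′/P2′ pockets.

`nlsgeom` implements the geometric machinery needed to study this kind of
recognition quantitatively:

- **Conservation statistics.**  Superimpose an ensemble of crystal
  structures onto a common receptor frame (Kabsch least-squares fit over
  mutually sequence-aligned Cα atoms) and summarize, for any monitored
  atom, the distances of its copies to their centroid as mean ± sd — the
  *positional dispersion*.  For isotropic per-coordinate Gaussian noise σ
  the expected mean is `2√(2/π)·σ·√(1−1/n) ≈ 1.5958·σ·√(1−1/n)` (a scaled
  χ₃ distribution), which the package uses for parameter recovery.
- **Pocket nomenclature.**  Detect the anchor residue of a bound peptide
  (the residue sandwiched between the pocket tryptophans), assign P/P′
  labels, and classify minor-site KR occupancy.  A transcribed survey of
  42 peptide–importin α PDB entries is packaged for the census: of the
  entries with minor-site density, KR occupies P1′–P2′ in 7/9 two-copy
  entries, 12/17 bipartite entries and 5/7 minor-only entries (24 KR
  entries in total).
- **Docking-model triage.**  Filter candidate peptide poses by the
  distance of monitored atoms (P1′/P2′ Cα and sidechain tips, pocket Trp
  Cζ3) from crystallographic centroids — published cutoffs: 1.5 Å for the
  peptide atoms, 2.0 Å for W399/W357 Cζ3 at the minor site; 1.5 Å for
  P1–P5 Cα and 1.4/1.2/2.2 Å for W231/W184/W142 Cζ3 at the major site —
  then cluster survivors by peptide Cα RMSD (greedy neighbor-count rule)
  and pick a representative.
- **Interaction geometry.**  Heavy-atom detectors for hydrogen bonds,
  cation-π contacts, π-stacking class (sandwich / parallel-displaced /
  T-shaped), and the **d_W-W** metric — the sum of the six-membered-ring
  and five-membered-ring centroid separations of a tryptophan host pair,
  measuring both spacing and parallelism.
- **Motif scanning** for KRx(W/F/Y)xxAF (and arbitrary bracket-syntax
  patterns) over FASTA files.
- **Model evaluation** against a reference complex: superpose on the Cα
  atoms of receptor residues within 5 Å of the reference peptide, then
  report grouped peptide RMSDs (P1′–P2′, P4′, P7′–P8′ backbone and
  sidechain groups).
- **Synthetic data.**  Every stage can be exercised without downloads:
  toy complexes with known anchors, noisy superposable ensembles, decoy
  sets with constructed pass fractions, indole pairs with prescribed
  geometry, and sequence sets with an exact number of motif carriers.

## Worked example

Scan the five packaged Class-3 study peptides for the signature motif:

```
$ nlsgeom motif
  id  start  end substring aromatic
NLS1      7   14  KRTWRDAF        W
NLS2      7   14  KRKFSDAF        F
NLS3      7   14  KRKWSEAF        W
NLS4      6   13  KRGYSVAF        Y
NLS5      6   13  KRSFSKAF        F
records with >=1 match: 5
```

Each peptide carries exactly one motif window; the `start`/`end` columns
are 1-based residue coordinates and `aromatic` is the residue identity at
the W/F/Y position (the future P4′ residue).  Census of the packaged
crystal-structure survey:

```
$ nlsgeom table1
  category  n_total  n_kr  n_indeterminate
major_only        9     0                0
two_copies        9     7                0
 bipartite       17    12                1
minor_only        7     5                0
```

`n_kr` counts entries whose minor-site peptide has K at P1′ and R at P2′.
Build a tryptophan pair with prescribed ring geometry and measure it:

```
$ nlsgeom simulate indoles --out pair.pdb --distance 3.8 --offset 1.0
$ nlsgeom stack A:399 A:357 --pdb pair.pdb
A:399 A:357    sandwich    angle=0.0deg    d=3.80A    offset=1.00A
$ nlsgeom dww A:399 A:357 --pdb pair.pdb
d6=3.80A    d5=3.80A    d_W-W=7.60A
```

The rings are parallel (interplanar angle 0°), 3.8 Å apart with a 1.0 Å
lateral offset — sandwich stacking — and the d_W-W spacing metric is the
sum of the two centroid separations.  Other subcommands: `conserve`
(ensemble dispersion), `filter`/`cluster` (model triage), `hbond`,
`evaluate`, `simulate` (fixture generators) and `fetch` (the only
networked command, to cache the surveyed PDB entries locally).

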