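# Methods

This note records the models, conventions and numerical choices behind
`nlsgeom`, and what the synthetic fixtures do and do not establish about
real crystallographic data.

## Structure model and conventions

PDB files are parsed with gemmi and converted into a flat residue/atom
model.  Alternate locations are resolved per atom name by keeping the
highest-occupancy conformer; ties break to the lexicographically first
altloc identifier, making parsing deterministic (re-writing a re-read file
is byte-stable).  Occupancies outside [0, 1] are clamped with a warning.
Hydrogens are retained but flagged and excluded from all distance
criteria, since crystal structures at typical resolution do not resolve
them.  Deposited residue numbering is preserved throughout (the mouse
importin α numbering — W399, W357, W231, W184, W142, N361, E396, D325 —
is the reference vocabulary; other species are reached through sequence
correspondence, never by renumbering).  Modified residues (e.g.
phosphoserine, parsed from HETATM records) keep their coordinates and
map to `X` in extracted sequences.

Chain roles default to: longest chain = receptor; remaining chains of
≤ 30 residues = peptide.  The armadillo-repeat domain (~430 residues)
versus NLS peptides (≤ 15 residues) makes this unambiguous in practice;
roles can always be supplied explicitly, which is also the escape hatch
for entries with several complexes per asymmetric unit.

## Superposition

Optimal proper-rigid superposition uses the Kabsch algorithm: SVD of the
covariance of the centered paired point sets, with the sign of the
smallest singular direction flipped when needed so a reflection is never
returned.  Inputs of fewer than three points, or (nearly) collinear
points — second singular value below 10⁻⁸ of the first — are rejected as
degenerate rather than silently returning one of the infinitely many
optima.  `rmsd` never fits; fitting functions report the fitted RMSD
separately so the two notions cannot be confused.

"Within 5 Å" shells (binding-site selection, evaluation fit sets) use the
minimum heavy-atom–heavy-atom distance, inclusive at the boundary.  An
all-atom versus Cα-only choice here is genuinely open for historical
datasets; heavy-atom minimum is the stricter and more common convention
and is what the package implements (the cutoff itself is a parameter).

## Pocket nomenclature and anchor detection

Minor site: the pocket between W399 and W357 is P2′; the occupying
peptide residue is the P2′ residue, residue i−1 is P1′ and residues i+k
are P(k+2)′.  Major site: the pocket between W231 and W184 is P3, with
P1, P2 upstream and P4…P6 downstream.  Label spans are P0′–P8′ and
P1–P6; labels falling outside the chain are omitted with a report, so an
anchor at a terminus truncates the assignment rather than failing.

Anchoring is geometric: the anchor is the peptide residue minimizing the
sum over the two pocket tryptophans of the minimum distance from its
sidechain heavy atoms (Cα for glycine) to the indole ring atoms, gated at
6 Å from *both* rings.  The 6 Å gate is a design choice — "occupying the
pocket" has no canonical numeric definition — chosen generously enough
that any residue genuinely between the rings passes while residues one
position along the chain produce strictly larger sums; if no residue
passes, the site is reported unoccupied rather than guessing.

The packaged survey table transcribes the printed minor-site strings
left-aligned at P1′ (first letter = P1′).  With that registration the
KR-at-P1′P2′ census reproduces 7/9, 12/17 and 5/7 per category;
unresolved positions (`?`) make a row indeterminate and count as
negative, with the indeterminate count reported separately.  For the two
four-letter rows the alternative registration (at P2′) exists; the
left-aligned reading is the one consistent with the census and is what
the table encodes.

## Conservation statistics

Entries are expressed in the frame of one reference entry by a single fit
(no iterative mean-structure refinement — the simplest defensible
reading of "superimpose the ensemble"; an iterative mode would be a
straightforward extension).  The fit set is the Cα atoms of receptor
residues aligned across *all* entries, from pairwise global alignments of
each receptor sequence to the reference (BLOSUM62, gap open −11 / extend
−1, free terminal gaps, via Biopython's PairwiseAligner).  Alignment
coverage below 50 % of identical aligned positions warns; below 20 % it
is an error — at that point the sequences are effectively unrelated and
any mapping would be noise.

For a monitored atom the dispersion statistic is: centroid of the n
superposed copies, per-entry Euclidean distance to that centroid, and the
mean and **sample** standard deviation (n−1 denominator; the source
material does not state a convention and the sample estimator is the
unbiased default).  Useful identities, both tested: mean² +
sd²·(n−1)/n equals the mean squared distance; and for iid isotropic
per-coordinate Gaussian noise σ the distances follow a scaled χ₃
distribution with mean 2√(2/π)·σ·√(1−1/n), so a measured dispersion mean
converts to an equivalent coordinate noise σ̂.

`pairwise_max_rmsd` re-fits every pair optimally (it answers "how far
apart are the two most different receptors", which a common-frame matrix
would overstate), while the superposition report's RMSD matrix is
computed in the common frame (it answers "how coherent is the ensemble
around the reference").

The exact atom set used historically for whole-ensemble superposition is
not recorded in the source material; the package defaults to
whole-domain mutually aligned Cα and exposes the fit-atom set as a
parameter, which is why reproduction tolerances on dispersion means are
set at ±0.15 Å rather than printed precision.

## Model filtering and clustering

A filter criterion is (target, atom, centroid, cutoff), with targets
either peptide position labels (resolved through a position assignment
shared by all models) or receptor residues by number.  A model passes
when every monitored atom lies within its cutoff of the reference
centroid, **inclusive** at the boundary ("maximal distance" is read as
≤).  A missing monitored atom fails the model with an explicit reason
instead of being skipped.  The built-in presets carry the published
cutoffs: minor site 1.5 Å for P1′ K and P2′ R Cα and sidechain Cε/Cζ,
2.0 Å for W399/W357 Cζ3; major site 1.5 Å for P1–P5 Cα and 1.4 / 1.2 /
2.2 Å for W231 / W184 / W142 Cζ3.  Centroids come from the conservation
analysis or from any user-supplied table.  Models are assumed
pre-superposed on the receptor; passing a reference re-fits each model on
the receptor Cα trace first.

The published protocol clusters surviving models by peptide Cα RMSD but
does not name an algorithm; the package uses the greedy neighbor-count
rule standard in docking: the model with the most neighbors within the
cutoff (ties to the lowest input index) seeds a cluster consisting of
itself and those neighbors, the cluster is removed, and the rule repeats.
The seed is the cluster representative.  Default cutoff 2.0 Å,
configurable.  The rule is deterministic, is verified against a
brute-force re-implementation on all small ensembles, and partitions the
input exactly.

The published "about 1 %" pass rate is not a reproduction target: the
underlying refinement ensembles (thousands of models per peptide) were
never deposited.  Decoy sets with *constructed* pass fractions stand in:
the generator places every monitored atom strictly inside its cutoff for
⌊f·n⌋ models and pushes at least one strictly outside for the rest, so
the filter's recovered fraction has a known truth.

## Interaction detectors

All detectors are heavy-atom-only and rigid-motion invariant.

- **Rings.**  Centroid = mean of ring atoms; normal = smallest right
  singular vector of the centered coordinates (sign arbitrary — every
  consumer folds angles into [0°, 90°]).  Planarity residual (rms
  out-of-plane distance) above 0.3 Å rejects a ring as broken.
- **π-stacking.**  Contact gate 7.0 Å on centroid separation; interplanar
  angle ≤ 30° is parallel — sandwich if the lateral offset ≤ 1.5 Å,
  otherwise parallel-displaced — and ≥ 60° is T-shaped; 30–60° is
  reported as intermediate without a class.  The offset is the in-plane
  component of the centroid–centroid vector averaged over the two ring
  planes, which makes the call exactly symmetric in its arguments.
  These thresholds follow common structural-analysis practice (they are
  not published constants of the study system) and are all parameters.
- **Cation-π.**  Charge center = Lys Nζ or the mean of Arg Cζ/Nη1/Nη2/Nε;
  detected when the center is within 6.0 Å of the ring centroid and
  within 45° of the ring normal.  Same caveat and configurability as the
  stacking thresholds.
- **Hydrogen bonds.**  Donor/acceptor typing from a fixed chemistry table
  (backbone amide N donates except proline, backbone carbonyl O accepts,
  sidechain atoms per residue chemistry; His N atoms are both), criterion
  = donor–acceptor heavy-atom distance ≤ 3.5 Å.  No angle term: without
  hydrogens an angle criterion would be guesswork on built positions.
- **d_W-W.**  d6 and d5 are the centroid separations of the two
  six-membered and two five-membered rings respectively, and d_W-W is
  their sum by definition, so d_W-W = d6 + d5 holds exactly.  Whether
  the historical measurement used centroids or closest atoms is not
  recorded; centroids are the symmetric, orientation-aware choice.  The
  published minimized host-guest values (14.5 / 15.4 Å) required
  force-field minimization, which is out of scope — only the metric
  itself is implemented, and the fixtures reproduce sums at that scale
  by construction.

## Motif scanning

Patterns are ordered per-position constraints; the Class-3 default is
K, R, wildcard, {W,F,Y}, wildcard, wildcard, A, F.  Wildcards match only
the 20 standard letters — `X`, `B`, `Z` and `*` never match, so ambiguous
or translated-stop positions cannot smuggle a motif in.  Overlapping
windows are all reported (completeness over parsimony), coordinates are
1-based, and scanning is case-insensitive.  The scanner is verified
against an independent regex-lookahead oracle on random sequences.

## Evaluation protocol

A model is compared to a reference by fitting on the Cα atoms of
reference receptor residues within 5 Å of the reference peptide — the
shell is computed once on the reference so every model shares the same
fit set — then reporting grouped RMSDs: minor site P1′–P2′ Cα, P1′–P2′
sidechain, P4′ Cα, P4′ sidechain, P7′–P8′ Cα; major site P2–P6 Cα, P2
sidechain, P5 sidechain.  Sidechain = heavy atoms excluding N, Cα, C, O
(Cβ included, a membership the source material leaves undefined); no
additional per-residue fit is applied.  Groups with missing atoms are
flagged, never silently dropped.  The published per-peptide RMSD values
are not reproduction targets — the models they scored are not deposited —
so the protocol is validated on identity and constructed-displacement
fixtures where the correct answer is known exactly.

## Synthetic data: what it emulates and what it does not

The generators emulate the *geometric* structure of the real analyses:
superposable receptor ensembles whose monitored atoms carry known
isotropic Gaussian noise plus arbitrary rigid offsets; decoy ensembles
with exact pass fractions; indole pairs realizing requested centroid
distance / interplanar angle / lateral offset to 10⁻³ Å and 0.1°; and
sequence sets with an exact carrier count (non-carriers are re-drawn
until a brute-force check confirms they are motif-free).  Everything is
deterministic per seed, down to output bytes.

They deliberately do not emulate: anisotropic or position-correlated
coordinate error (real crystallographic uncertainty), alternative
sidechain rotamers, stereochemically refined geometry, lattice contacts,
or sequence composition biases.  Consequently, passing the closed-loop
tests establishes that the *estimators and detectors are correct* — not
that real ensembles satisfy the isotropic-noise model.  On real data the
dispersion statistic remains a descriptive summary whose Gaussian
interpretation is approximate.

## Problem sizes and numerical tolerances

Test and acceptance runs use: 24-entry ensembles with 200 replicates for
the χ₃ parameter-recovery checks (mean within 3 standard errors; σ
recovered within 5 %); 100 random rigid transforms for Kabsch recovery at
10⁻⁶ Å; 1000 random sequences for scanner–oracle equivalence; 50 random
ensembles of ≤ 8 models for clustering–oracle equivalence; decoy sets of
40–100 models.  These sizes give comfortable statistical power for the
3-SE bands while keeping the whole suite fast.  Orthonormality of
rotations is enforced at 10⁻⁸; PDB round-trips are exact to the format's
10⁻³ Å coordinate precision.

## Known limitations

- The accession-based conservation numbers require the surveyed PDB
  entries on disk (`nlsgeom fetch`); the package ships only the
  transcribed survey table, not coordinates.
- Entries with multiple complexes per asymmetric unit rely on chain-role
  configuration; there is no automatic biological-assembly selection.
- No mmCIF input (PDB format only), no flexible or sequence-order-
  independent alignment, no energetics anywhere — every detector is
  purely geometric.
- `build_correspondence` assumes one receptor chain per entry; hetero-
  oligomeric receptors would need explicit roles.
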