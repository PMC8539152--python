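# Methods

## Model

The package implements an atom-group additivity model for the standard heat
of combustion ΔH°c (kJ/mol, 298.15 K, combustion negative) and, via Hess's
law, the standard heat of formation ΔH°f. The additive unit is the
*backbone atom*: any atom bound to at least two other atoms, hydrogens
counted. Each backbone atom maps to exactly one atom group written as an
`atom type | neighbors` pair; single-neighbor atoms (carbonyl oxygens,
halogens, hydrogens) appear only inside neighbor descriptors. Non-additive
3D effects are absorbed by special groups: intramolecular H bridges (acidic
H on O/N/S within 1.75 Å of a non-bonded O/N/F), H···H contacts (< 2.0 Å
and 2.0–2.3 Å bins, geminal and vicinal pairs excluded, both partners in
the same covalent component), and ring-strain angle classes (< 74°,
74–98°, 98–106° at each ring atom; wider angles contribute nothing).

The model assumes strict additivity: no temperature dependence, no
phase-change corrections, no stereochemistry. Supported elements are H, B,
C, N, O, P, S, Si and the halogens; anything else is rejected at parse
time.

## Structural conventions

The group grammar is defined against specific structural conventions, which
the molecule model enforces rather than inheriting a toolkit's defaults:

* **Aromaticity.** Only six-membered rings carry aromatic bonds.
  Five-membered heteroaromatics are stored in Kekulé form, so a pyrrole
  nitrogen types as `N sp3 | HC2(2pi)` and a thiophene α-carbon as
  `C sp2 | H=CS`. This is forced by the contribution table itself, whose
  `:`-marked rows are exercised only by six-ring systems. In fused systems
  (indole) the benzo ring keeps its six aromatic bonds while the hetero
  ring is Kekulé.
* **Delocalized cations.** The positive charge of amidinium, guanidinium
  and imidazolium fragments is placed on the carbon between the nitrogens
  and the C–N bonds of the fragment are typed aromatic (`C(+) aromatic |
  H:N2` for the imidazolium C2, `N aromatic | C2:C(+)` for its
  nitrogens). `normalize_conventions` performs this rewrite; pyridinium-type
  six-ring cations are left as perceived.
* **Zwitterions.** Under the `auto` policy a carboxylic-acid proton moves to
  a primary aliphatic amine or to a guanidine in the same component — the
  two cases the training data treat as zwitterionic. Anilines, amides and
  all other acid/base pairs are left as drawn (`as_drawn` is the default,
  so both prototropic forms of an amino acid remain computable).
* **Hybridization** is derived from the bond pattern (a triple bond or two
  cumulated doubles → sp; one double → sp2; aromatic flag → aromatic;
  otherwise sp3), because that is what the atom-type tokens encode. S and P
  carry a valence class instead (S2/S4, P3/P4). Explicit hydrogens are
  materialized at parse time.

## Neighbor-descriptor grammar

Neighbor descriptors are rendered canonically: hydrogen count first;
heavy-atom tokens grouped by (bond marker, element) with multiplicity
digits, elements ordered H, B, C, N, O, S, P, Si, F, Cl, Br, J (iodine is
spelled `J` in the table; the molecule model uses standard `I` and the
encoder translates at rendering time) and markers ordered plain, `=`, `#`,
`:` within an element. Neighbor formal charges appear as at most one
trailing `(+)` and one `(-)` regardless of multiplicity — the convention
the packaged table uses for nitrate (`O2=O(-)`) and for sulfate and
hydrogensulfate, which share `O2=O2(-)`.

For the central types `N sp3`, `O` and `S2` the π membership of neighbors
is counted collectively as a trailing `(pi)`/`(2pi)`/`(3pi)` instead of
per-neighbor markers. A neighbor counts as π when it is aromatic or is a
C/N carrying a double or triple bond; higher-valent S and P do **not**
count (the table spells sulfonic-acid hydroxyls `O | HS` and
phosphate-ester oxygens `O | CP`, while nitrate esters are
`O | CN(+)(pi)`). This collective π-count is the single riskiest
reverse-engineered convention and is guarded by a fixture suite (phenol,
esters, diketene, nitrate esters, pyrrole) plus a totality test that
re-renders all 390 packaged spellings through the canonical ordering.

## Packaged data

`data/table4_contributions.tsv` is a verbatim transcription of the
published 390-entry contribution set (value, occurrences, supporting
molecule count per group), audited at load time by entry count and SHA-256
checksum, and by a six-term sum test that must reproduce the diketene total
to the printed 0.01 kJ/mol. A group is *valid* when supported by ≥ 3
independent molecules (274 rows). The table's own count of
prediction-usable groups — 267 — counts ordinary atom groups only (the
geometric special groups are exempt from the validity rule) and excludes
placeholder rows whose printed contribution is exactly 0: a least-squares
estimate of exactly 0.00 kJ/mol is not a fitted value, and all four such
rows have one to three supporting molecules. Strict predictions refuse
unknown, invalid and placeholder groups and report them as blockers.

`data/element_combustion.yaml` holds per-atom element combustion
enthalpies for ΔH°f (products CO2(g), H2O(l), N2, SO2(g), ¼P4O10,
SiO2(quartz), ½B2O3; CODATA-consistent). Halogens are flagged unsupported
by default because the aqueous HX product convention is source-dependent;
a user table can override any constant.

`data/ionic_liquids.tsv` is the 28-compound ionic-liquid benchmark (name,
structure, experimental ΔH°c) used by the acceptance suite.

## Fitting machinery

Re-deriving contributions from a training table proceeds exactly as the
prediction model implies: the M×N occurrence matrix X and response y form
the normal equations (XᵀX)a = Xᵀy ("normalization into an Ax = B system"),
solved by Gauss–Seidel sweeps in fixed column order from a zero start until
the largest coordinate update falls below `tol` (default 10⁻⁶ kJ/mol,
`max_iter` 10 000). XᵀX is symmetric positive semi-definite, for which
Gauss–Seidel converges; exactly rank-deficient systems (perfectly collinear
group columns) are refused with `NonIdentifiableError` rather than
returning one of infinitely many solutions. A direct least-squares solve
serves as the independent oracle in the tests. Note one genuine source of
collinearity in chemical designs: every C–O single bond is counted once
from the carbon group and once from the oxygen group, so closed
alcohol/ether vocabularies obey an exact linear identity; carbonyl and
anionic (terminal) oxygens break it.

Cross-validation uses a seeded shuffled split into k folds (default 10) as
equal as possible; every compound is tested exactly once. Test compounds
containing a group absent from their training folds are unevaluable and
excluded from the CV statistics, mirroring the shrinking compound counts of
the reference bookkeeping. The outlier loop alternates solve → CV → discard
|residual| > k·S (default k = 3, S the cross-validated standard error) until
a fixed point, with a safety bound of 25 rounds and an optional single-pass
mode (the reference text does not state which was used; the fixed point is
the default). S is floored at 0.01 kJ/mol so that solver round-off on
noise-free data is never treated as an outlier. Statistics: R²/Q² are
squared Pearson correlations; σ uses an n−p denominator for the
resubstitution fit and the plain-n residual RMS for CV (the reference does
not state its convention; both are emitted as `sigma` and `sigma_n`);
average deviation is the mean absolute residual; the percentage deviation
is mean |residual/experiment|·100. Reported values round half-to-even at
0.1 kJ/mol, which reproduces the printed values at the observed half-way
cases.

## Synthetic data

`SyntheticDesignSpec`/`gen_design` emulate the *algebraic* structure of the
training problem — sparse non-negative count matrices (truncated-Poisson
group counts with zipf-decaying group popularity), contributions of a few
hundred to two thousand kJ/mol, Gaussian noise with σ = 18 kJ/mol (the
magnitude of the published residual scatter) and optional gross outliers at
10σ in a 5 % fraction. They deliberately bypass chemistry so solver and
rejection properties are tested independently of perception; passing those
tests therefore says nothing about group perception on real molecules,
which is covered separately by the worked-example fixtures. Synthetic
designs are byte-reproducible under their seed.

`fixture_molecules` provides the worked examples (diketene, amino-acid
prototropic pairs, keto/enol pairs, salts) plus constructed geometries: an
idealized planar diketene (square ring, exactly 90° angles) and H-bridge /
H···H pairs built directly at chosen distances to probe the thresholds.

## Approximate conformers

The geometric special groups depend on the stored conformation; the
reference database keeps geometry-optimized 3D structures that are not
distributed. `hcomb.conformers.embed_3d` is a documented approximate
substitute: seeded ETKDG distance-geometry embedding, MMFF94 minimization
of an ensemble scaled with the rotatable-bond count, lowest-energy
conformer kept. Contact counts near the 2.0/2.3 Å thresholds can differ
from any particular curated geometry, which is the main reason the
ionic-liquid benchmark is reproduced to its printed 0.23 % mean deviation
only as a whole, not compound by compound. Users with curated 3D structures
should supply them as MOL/SDF input, which takes precedence.

## Problem sizes

The acceptance suite runs at desk scale: single molecules for the worked
examples; 28 ionic liquids with conformer ensembles (≈ 1 min); 100 random
systems of 10–60 compounds × 3–15 groups for the solver oracle; 20
replicates of 120 × 10 designs for the outlier-recovery property. The
global training statistics of the reference (σ = 18.12 kJ/mol over 4886
compounds) require its 5000-compound experimental compilation, which is not
redistributable; solver correctness, CV structure and outlier recovery are
therefore certified on synthetic designs with known truth instead.

## Known limitations

* Topology-only angle assignment covers 3- and 4-rings; 5-ring strain is
  geometry-dependent (the reference's cyclopentanone arithmetic implies
  partial 98–106° occupancy) and requires coordinates.
* The collective π-count is not defined by the source for S4/P4 centers;
  no such suffixed rows exist and none are emitted.
* H···H counting excludes geminal and vicinal pairs; 1,3 pairs are counted
  when within threshold. The reference does not state its exclusion rule.
* Ring perception uses the smallest set of smallest rings; fused-system
  angle groups are assigned per ring membership, at most one per ring an
  atom closes.
* Multi-protic or amphoteric molecules beyond the two named zwitterion
  cases are kept as drawn.
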