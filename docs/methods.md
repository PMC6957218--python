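# Methods

## The motif model

The minimal Rossmann-like motif (RLM) is defined on secondary-structure
elements (SSEs), not on sequence: five elements I–V in chain order, where I
(β1), III (β2) and V (β3) are strands of at least 3 residues forming a
parallel sheet with β1 central (spatial order β2–β1–β3), II (α1) is the
first helix after β1 and packs against the sheet on one face, and IV is the
crossover element — an α-helix on the opposite face, a β-strand, or a bare
loop — between β2 and β3. Extra SSEs between III and IV or between IV and V
are insertions and are tolerated; this is how large Rossmann domains that
extend the sheet (the classic six-strand 321456 topology) still match. Two
loops are part of the motif: the catalytic loop (β1→α1) and the crossover
loop (N-terminal of element IV).

Matching operates on an interaction matrix over the structure's SSEs:

- `P`/`A` between strand pairs linked by ≥ 2 backbone N···O hydrogen bonds
  (< 3.5 Å), parallel or antiparallel by the sign of the axis dot product.
  For CA-only input a ladder fallback applies: runs of consecutive residue
  pairs with CA–CA distance in [4.0, 6.0] Å.
- `C`/`T` for packing pairs involving a helix, split by crossing angle:
  `T` ("tilted") for angles in [30°, 150°], `C` otherwise. The contact
  criterion is minimum heavy-atom distance < 6.5 Å.
- Helix face signs are evaluated against the least-squares plane through
  the CA atoms of the three strands of each candidate motif (not a global
  sheet), so multi-sheet structures are judged locally.

The matcher enumerates strand triples satisfying the two `P` constraints,
then all admissible IV elements, and deduplicates frames that differ only in
IV, preferring helix-IV > strand-IV > loop-IV. When a domain retains several
matches, the one with the smallest element-I start is flagged canonical;
all are reported. A brute-force clause-by-clause enumerator (in the test
suite, independent of the matcher) reproduces its output on every fixture.

Secondary structure comes from backbone dihedral windows — helix
φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°]; strand φ ∈ [−180°, −45°],
ψ ∈ [45°, 225° mod 360°] — with single-residue gaps bridged, runs split at
chain breaks (C–N > 2.5 Å), and minimum lengths of 3 (strand) and 4
(helix). At chain termini where only one dihedral exists, that dihedral
decides. An externally computed per-chain SSE string (e.g. from DSSP) can
be supplied instead. Dihedral windows were chosen over an H-bond-pattern
assignment because they are deterministic, fast, and exact on both ideal
and regular native geometry; the windows and every cutoff above live in
`SSEParams` and are config-exposed.

Domain anchoring follows a full-containment rule: a match is kept only if
every residue of every element and loop lies inside exactly one domain's
range, so no motif spans two domains.

## Conservation

The per-column conservation index is the negative Shannon entropy of the
gap-excluded amino-acid frequencies, z-normalized across scored columns
(mean 0, sd 1). The centered form is deliberate: it makes "less conserved
than the domain average" a negative number, which is what the
inside-vs-outside comparison needs. Columns with > 50% gaps are unscored.
Optional per-sequence weights and window smoothing exist but default off.

Element binning treats an element's per-residue trace of length L as a
piecewise-constant function on [0, L) and evaluates it at bin centers
(i + 0.5)·L/B — exact identity at L = B, a strided subsample when
partitioning (L > B), and value repetition when stretching (L < B).
Default bin counts are the rounded mean element lengths over the input set,
user-overridable. Aggregation over representatives reports per-bin means
and standard errors (SE = 0 for a single profile, by convention).

The inside/outside comparison partitions residue-mapped values into motif
residues (elements plus both loops) versus the rest of the domain and uses
the two-sample Kolmogorov–Smirnov statistic with the asymptotic p-value
from the Kolmogorov distribution, Q(D·√(nm/(n+m))). The D statistic comes
from `scipy.stats.ks_2samp`; the tail is evaluated with
`scipy.special.kolmogorov` directly because scipy's `asymp` mode now applies
a finite-sample approximation rather than the limiting distribution. Exact
small-sample p-values are out of scope.

## Enrichment and family categories

Families are keyed by the sorted tuple of family-group identifiers present
on a structure (multi-domain combinations are distinct keys) and classified
into four exhaustive reaction categories: null (no EC), homogeneous (one
EC), heterogeneous-substrate (several ECs sharing the first three digits),
heterogeneous-reaction (otherwise). Dashed ECs still count as assignments
for this classification; dash filtering applies only to pathway mapping,
where unresolved fields make an EC unmappable.

Pathway over/under-representation is the ratio of observed (motif ECs in a
class / motif ECs in the major group) to expected (all ECs in the class /
all ECs in the group), with a two-sided Fisher exact test on the 2×2 table
of (motif, non-motif) × (in class, not in class). The two-sided p follows
the point-probability criterion (sum of hypergeometric probabilities ≤ the
observed table's); mid-p is not used. Raw p-values are reported at
α = 0.05; Benjamini–Hochberg adjustment is available but off by default,
matching the per-class significance-marking convention of this kind of
report. Printed percentages round half-up.

Cofactor summaries join an EC→cofactor table to family records, with hybrid
iron–sulfur cluster variants merged into two canonical types ([Fe-O-S] and
[Ni-Fe-S]) regardless of composition, and per-EC-class percentage
breakdowns.

## Ligand contacts and binding-mode pooling

A contact is any hetero residue (waters and a configurable blocklist of
crystallization additives excluded) with a heavy atom within 4.0 Å of a
domain heavy atom; hydrogens are rarely deposited, so the heavy-atom
interpretation is used. Each contact lists every motif region with a
residue within the cutoff of that ligand, or `outside-RLM`. Compounds map
to taxonomy superclasses by exact-id lookup with two total-function
fallbacks: a manual override list (CTP and derivatives → the nucleotides
superclass: C00063, C00705, C05673, C05674, C05822) that beats the table,
and a catch-all "Generic compounds" superclass that catches everything
unmapped. A contact is biologically significant when its compound appears
among the substrates, products or cofactors of any EC assigned to the
structure; unmapped ligands are uncertain.

Binding modes are pooled by superposing each motif onto a reference motif:
CA correspondences are built element-by-element (I, II, III, V always; IV
only when both are helices), symmetric-trimmed about element centers to the
shorter length, and fitted with the closed-form Kabsch SVD solution
(reflections excluded via the determinant sign). Fewer than 9 corresponding
atoms is treated as under-determined and refused. Members that cannot be
superposed are skipped with a logged warning; a per-member motif-only RMSD
table is emitted as quality control. Externally supplied transforms can be
substituted wherever a `Superposition` is accepted.

## Synthetic data

Structures are assembled from rigid ideal-geometry segments (NeRF chain
building at strand φ/ψ = −120°/+120°, helix −57°/−47°, ω = 180°) placed on
the sandwich template. Adjacent sheet strands are offset 3.8 Å across the
sheet, 0.6 Å along the axis and 0.4 Å out of plane — the registration at
which two ideal rigid strands form 8 N···O hydrogen bonds under the 3.5 Å
criterion (minimum N···O 2.89 Å); real pleated sheets relax to slightly
wider spacings, which rigid ideal strands cannot reach while H-bonding.
Helices sit at |z| = 6.2 Å on opposite faces. Loops are quadratic Bezier
paths whose N/C offsets corkscrew around the path direction (golden-angle
step per residue), deliberately scrambling consecutive dihedrals so loop
residues never form a 3-run inside a helix or strand window and cannot
extend a flanking element — loops are geometric connectors, not
Ramachandran-realistic conformations. Decoys perturb exactly one clause:
antiparallel β3, 2-residue β2, sequential (crossover-free) sheet order, or
both helices on one face.

Alignments draw each column i.i.d. from a dominant-residue mixture — the
column's dominant amino acid with probability p (default 0.9 inside motif
columns, 0.3 outside), otherwise uniform over the other 19. Annotation
tables spread 2000 ECs uniformly over 8 pathway classes and flag motif
membership with probability `rlm_fraction × fold(class)`. Defaults (50
sequences × 200 columns; 2000 ECs; fraction 0.25) are sized so the planted
effects are decisively detectable while null calibration is measurable in
seconds: at these sizes the KS null rejection rate sits inside [0.02, 0.09]
at α = 0.05 and planted-contrast power exceeds 99%. All generators are
seed-deterministic to the byte.

What passing tests on these fixtures do *not* show: robustness to
irregular native geometry (bent strands, β-bulges, 3₁₀/π helices,
deteriorated elements), to alignment columns with phylogenetic correlation
rather than i.i.d. sampling, or to annotation noise. The generators emulate
the geometry and statistics of the analysis, not the messiness of deposited
structures.

## Numerical choices and degenerate inputs

- Residue identity is (chain, author number, insertion code); coordinates
  in Å; first model only; waters dropped; altlocs resolved to highest
  occupancy.
- Axis fitting is SVD-based with N→C orientation; the sheet-plane normal's
  global sign is arbitrary but consistent within a structure (only sign
  *differences* between helices matter).
- A chain with < 4 polymer residues yields no SSEs (not an error); an
  all-gap alignment, a constant conservation profile (sd = 0), an empty
  inside/outside partition, zero-count enrichment groups and negative
  contingency cells all raise informative errors.
- Fisher p via `scipy.stats.fisher_exact`; verified in the test suite
  against exhaustive hypergeometric enumeration over all 2×2 tables with
  margins ≤ 30.
- Kabsch never returns a reflection; superposition of a structure onto
  itself is the identity to machine precision.
- The pipeline is fail-soft per structure and byte-deterministic given the
  same inputs and configuration; strict mode aborts on first error.

## Problem sizes

The test suite and the acceptance script run on generated fixtures: single
domains of ~60–80 residues, alignments of 50 × 200, annotation tables of
2000 ECs, 100–200 replicate simulations for power and calibration. These
sizes make every stochastic assertion stable under its stated threshold
while keeping a full run in well under a minute of compute.

## Known limitations

- The dihedral-window SSE assignment has no β-bulge or helix-subtype
  handling and will fragment strongly distorted elements; a corpus-scale
  census of deposited structures would need the external-SSE hook or a
  vector-based assigner for the hardest cases.
- Loop-IV acceptance requires an SSE-free III→V gap with a ≥ 2-residue
  loop; motifs whose crossover region contains unrecognized fragments are
  missed (tunable via `SSEParams`).
- Compound mapping is exact-id; no chemical-similarity search, so renamed
  or derivative ligands fall into "Generic compounds" unless listed.
- Conservation assumes a reasonable MSA; no weighting by phylogeny by
  default, and the KS p-value is asymptotic.
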