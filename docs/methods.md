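# Methods

## The prediction problem

Two-chain-group protein complexes are labelled *obligate* (subunits
unstable alone; the positive class) or *non-obligate* (subunits stable
alone, reversible association). The hypothesis the package operationalises
is that the energetics of the interface — its size and the charge
complementarity of the facing surfaces — carry enough signal to separate
the two classes, and that electrostatic energies, being long-range, remain
informative at larger distance cutoffs (9–12 Å) than contact-potential
desolvation terms (5–7 Å).

## Interface definition

Given a complex partitioned into ligand chains and receptor chains (the
partition is always supplied explicitly, e.g. `AB:C`; it is never
inferred), the interface at cutoff *c* is the exhaustive set of
cross-partition atom pairs with Euclidean distance `r < c` (strict; a pair
at exactly the cutoff is excluded, matching the step gate below). A
KD-tree accelerates the search but the contract is the brute-force
all-pairs set, and the test suite enforces equality against an O(n²)
oracle. Contacts are ordered by (ligand serial, receptor serial) so that
floating-point accumulation is reproducible. Hydrogens are kept by default
(PQR files carry placed hydrogens); a `heavy_only` flag drops them, since
whether distances should include hydrogens is a genuinely open choice.

## Pair energies

**Desolvation.** `ΔG_des = Σ_i Σ_j e_ij · g(r_ij)` over interface pairs,
where `e_ij` is the symmetric 18×18 atomic contact potential (ACP) between
the two atoms' classes and `g(r) = 1` iff `r < cutoff`, else 0.

**Electrostatics.** `E_ij = C · q_i q_j / (ε(r) · r)` with
`C = 332.0636 kcal·Å/(mol·e²)`, charges from the PQR file, and `ε` either
a constant (default 1) or the distance-dependent screening `ε(r) = 4r`.
This is a deliberate substitution: the reference methodology computes
per-atom electrostatic energies by solving the Poisson–Boltzmann equation
numerically, which requires a PB solver and solvent/salt parameters and is
out of scope here. The Coulombic pair energy keeps the method's structure
(per-pair energies accumulated by type pair) and its qualitative
long-range behaviour, but no equivalence with PB energetics is claimed;
absolute feature values are not comparable across the two approaches.

Pairs in which either atom is untyped (nonstandard residue, hydrogen, or
absent from the typing table) are skipped and counted, for both models, so
that the sum of any feature vector equals the total interface energy of
the retained contacts — a conservation law tested per complex for both
energy kinds and both feature kinds.

## Atom and residue typing

The 18-class atom typing and the ACP matrix are data, not code: a JSON
table maps `(residue, atom name)` to one of 18 classes and carries the
symmetric 18×18 matrix, and any table satisfying those invariants can be
substituted at runtime. The packaged default
(`typing_table_synthetic.json`) is a **synthetic stand-in**, constructed
for this package rather than copied from the ACP literature: classes are
backbone N/CA/C/O, glycine CA, CB, aliphatic C, aromatic C,
carbonyl/carboxyl C, guanidinium C, amide N, ring N, lysine NZ,
guanidinium N, carboxylate O, amide O, hydroxyl O, and S; the matrix is
`e_ij = (s_i + s_j)/2` from per-class solvation propensities `s` (apolar
negative, polar/charged positive). It has the right structure and
realistic signs but is an external modelling choice; quantitative work
against published desolvation scales should drop in the corresponding
table. Residue classes are the 20 standard amino acids in alphabetical
order. The table also carries optional default charges (charged side-chain
termini only) so plain PDB input remains usable with the electrostatic
model.

## Feature vectors

Because pair order is irrelevant, features are indexed by the canonical
unordered-pair index `s·K − s(s−1)/2 + (t−s)` with `s = min, t = max`,
giving 171 atom-type-pair (K=18) and 210 residue-type-pair (K=20)
features. Each feature is the cumulative energy of all contacts carrying
that type pair; no per-atom down-weighting is applied when one atom
participates in many contacts (the cumulative-sum definition implies
none), and raw sums are used without normalisation. Standardization, where
a classifier benefits from it, happens inside CV training folds only.

## Feature selection

IG, GR and χ² are computed from a discretized feature against the class
label; mRMR uses greedy forward selection with the MID criterion
`I(x;y) − (1/|S|) Σ_{s∈S} I(x;s)`, all mutual informations in bits from
the same discretization machinery. Workflows of this kind typically delegate these statistics to off-the-shelf
attribute evaluators whose discretization settings go unreported, so the
package uses the common defaults for each
— equal-frequency binning with 10 bins for IG/GR/χ², and a 3-state
discretization at mean ± one standard deviation for mRMR — and makes both
configurable. Score ties break by ascending feature index, making ranks
deterministic. Selection inside cross-validation is fitted on training
folds only by default; a documented `selection_mode="full"` ranks once on
the whole dataset for comparison with protocols whose leakage behaviour is
ambiguous, and results from that mode should be labelled as such.

## Classifiers

All classifiers are two-class. Class statistics use biased (1/n) sample
covariances; any covariance whose condition number exceeds 1e10 receives a
ridge `λ = 1e-6 · tr(S)/D` (the 171–210-dimensional feature spaces against
~100–300 samples make pooled covariances singular as a matter of course).

* **FDA** — rows of A are top eigenvectors of `S_W⁻¹S_B`, computed by
  whitening; for two classes and d=1 this is `S_W⁻¹(m₁−m₂)`.
* **HDA** — the Loog–Duin two-class Chernoff criterion matrix
  `W^{-1/2}[m̂m̂ᵀ − (π₁ log Ŝ₁ + π₂ log Ŝ₂)/(π₁π₂)]W^{-1/2}` in whitened
  coordinates (`W = S_W`, `m̂ = W^{-1/2}(m₁−m₂)`, `Ŝ_k = W^{-1/2}S_k
  W^{-1/2}`); the log terms vanish when `S₁ = S₂`, recovering FDA — a
  tested limit. The exact criterion matrix of the original LDR literature
  is not reproduced verbatim anywhere accessible to this package, so this
  documented formula is validated through its homoscedastic limit and
  through discrimination on equal-mean heteroscedastic data rather than by
  bit-equivalence with any reference code.
* **CDA** — direct ascent on the transformed-space Chernoff distance
  `J(A) = [β(1−β)/2](Am)ᵀ(AS̄Aᵀ)⁻¹(Am) + ½log(|AS̄Aᵀ|/(|AS₁Aᵀ|^β|AS₂Aᵀ|^{1−β}))`
  with `β` the class-1 prior and `S̄ = βS₁+(1−β)S₂`. Optimisation is
  fixed-step gradient ascent (central-difference gradient, step halved
  until J increases, rows re-orthonormalised each step — J depends only on
  the row space, so this is a no-op on the objective), initialised at the
  FDA solution, capped at 500 iterations with tolerance 1e-8. The recorded
  objective path is non-decreasing by construction and the final J
  dominates Fisher's; at d=1 in 2-D it matches a dense grid search over
  unit directions to 1e-3.

The reduced dimension d defaults to 1 (two classes); the Bayes rule in
z-space is quadratic (per-class Gaussians) or linear (pooled covariance).
When a single "LDR" number summarises the family, it is the maximum pooled
accuracy over the six variants (3 criteria × 2 rules), and is labelled as
such.

**Naive Bayes** uses per-feature univariate Gaussians with a variance
floor of 1e-9 times the largest feature variance. **k-NN** is Euclidean
majority vote with k=1 by default (the common library default when no k is
stated); a vote tie falls back to the single nearest neighbour's label.
Both are implemented in-package to pin these exact contracts, and are
cross-checked against sklearn's implementations in tests. **SVM** is a
thin adapter over sklearn's `SVC(kernel="poly")` with library defaults; it
exists as a baseline and is intentionally not re-implemented.

## Evaluation

Stratified 10-fold CV (stratification is the safe reading when class
imbalance is possible), shuffled with a recorded seed; TP/TN/FP/FN are
pooled over folds and accuracy is `(TP+TN)/N`. ROC scores are posterior
log-odds for LDR/NB and the vote fraction for k-NN; the curve sweeps
descending unique scores with ties grouped, and the trapezoidal AUC equals
the Mann–Whitney U normalisation (tested on random score sets). Sweeps
recompute contacts, features and CV per cutoff (grid 5–13 Å) or per top-n
subset (n = 2, 4, 6, 8, 10 plus a no-selection baseline).

## Synthetic data

The generators define the package's test conditions:

* **Toy complexes** place each chain's atoms on a square planar grid
  (residues cycle through the 20 standard names, all atoms named CA, unit
  charges), the two planes separated by a gap, so expected contact counts
  follow in closed form. Gaussian positional jitter and random charge
  signs add within-class variability.
* **Two-population datasets** (40 complexes per class by default) contrast
  an obligate-like population — 6×6 grid at 4.5 Å gap with fully
  complementary facing charges — against a non-obligate-like one — 4×4
  grid at 5.5 Å with random signs. This caricatures the qualitative
  contrast the method exploits (interface size and charge
  complementarity), and a correct pipeline separates the populations
  essentially perfectly; the matched no-signal control (both classes drawn
  from the same population) must stay inside the binomial null band.
* **Long-range datasets** share class-identical near geometry (receptor
  layer at 4.5 Å, random charges) and put all class signal in a second
  receptor layer at 8.5 Å (complementary vs. random charges), so a cutoff
  sweep peaks at ≥ 8 Å.
* **Gaussian feature datasets** with known moments drive the classifier
  recovery and null-band tests.

What these fixtures do *not* emulate: real protein geometry (packing,
secondary structure, rotamers), realistic partial-charge distributions,
heteroatoms, or PB-derived energetics. Passing tests therefore demonstrate
correctness of the machinery and the qualitative behaviours designed into
the generators — not predictive performance on real obligate/non-obligate
datasets, which additionally depends on the electrostatic model
substitution discussed above.

## Numerical choices and problem sizes

Distances and coordinates in Å, energies in kcal/mol, information measures
in bits. Matrix square roots/logs via symmetric eigendecomposition with
eigenvalues clipped at 1e-12. Feature accumulation order is fixed, making
runs bit-reproducible at fixed seed. Test problem sizes (e.g. 50 random
interface fixtures up to 10³ atoms per side, 5000 samples per class for
Bayes-accuracy checks, 40+40 complexes end-to-end) were chosen to make the
statistical assertions sharp at desk scale while the full suite stays
fast.

## Known limitations

* The Coulombic substitution means absolute electrostatic feature values
  are not comparable with PB-derived ones; only the method's structure and
  qualitative long-range behaviour carry over.
* The default typing table is synthetic (see above); published accuracies
  on curated obligate/non-obligate datasets are not reproducible from this
  package alone and are not claimed.
* Only two-class problems are supported; multi-class LDR extensions and
  kernelised variants are out of scope, as are SASA-based interface
  definitions and wrapper feature selection.
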