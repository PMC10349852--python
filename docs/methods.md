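# Methods

## Problem setting

Non-directed arene C–H functionalization distributes product over the
symmetry-distinct C–H positions of a substrate.  For two competing site
classes A and B with observed product fractions p_A, p_B and statistical
multiplicities m_A, m_B (the number of symmetry-equivalent positions per
class), the apparent per-site free-energy preference at temperature T is

    DDG_app(A,B) = R T ln[(p_A/m_A)/(p_B/m_B)],   R = 1.9872e-3 kcal/(mol K).

This quantity is antisymmetric under pair swap, is corrected for statistical
factors, and is the regression target throughout the package.  Targets are
kept in kcal/mol at the measurement temperature so that model errors read
directly on an energy scale; a log10-ratio convention would only rescale
them by RT·ln 10.  Working assumptions: selectivity is kinetically
controlled and well described by a single effective free-energy difference
per site class; observed fractions are renormalized over the measured
classes (unquantified minor isomers are treated as unmeasured, not as zero);
zero fractions are rejected rather than silently clamped — the caller must
choose a detection-limit epsilon explicitly.

## Site enumeration and symmetry

Bonds are perceived by a covalent-radius distance cutoff (Cordero radii,
tolerance 1.2 on the summed radii; valid range 1.0–1.5).  Aromatic sites are
carbons bearing exactly one hydrogen inside 5- or 6-membered rings whose
members are C/N/O/S and whose carbons are three-coordinate.  Symmetry
classes come from iterative neighborhood refinement (Morgan/Weisfeiler–
Lehman colors seeded with element symbols) on the bond graph — topology
only, deliberately: conformational noise in 3D coordinates can never split
a class.  The refinement partition is verified against explicit
graph-automorphism orbit enumeration on all fixture molecules in the test
suite.  Class labels are assigned a, b, c, … in order of lowest atom index,
which fixes a deterministic canonical pair order (label, then lowest atom
index); swapping a pair flips the target's sign.

## Steric descriptors

*Percent buried volume*: fraction of a probe sphere (default radius 3.5 Å)
centered on the site carbon occupied by the scaled van-der-Waals spheres of
all other atoms (Bondi radii × 1.17, the SambVca convention; hydrogens
included; the center atom itself excluded).  Integration is regular-grid
point counting at 0.05 Å pitch — deterministic for a fixed grid, and
converged to within 0.5 percentage points of a 10⁶-point Monte-Carlo
integration on every fixture geometry (asserted in tests).

*Sterimol L, B1, B5* (classic Verloop, unscaled Bondi radii): projections
measured from the base atom along the base→attached axis; B1 is minimized
by an in-plane direction scan at 1° resolution (a 0.1° brute-force scan
oracle pins the residual error below 0.01 Å).  Exact support-function
minimization was rejected in favor of the scan because the scan is simpler,
resolution-controlled, and its error is provably monotone in the step.

For a ring C–H site the substituent whose bulk matters is not the H itself
but the flanking groups.  The default site Sterimol is therefore the
*flanking-substituent* convention: for each ring neighbor of the site
carbon, the Sterimol of its exocyclic branch measured from that neighbor
(its ipso atom), truncated at graph radius 3 from the branch's first atom
to stay local in fused polycyclics, aggregated by elementwise maximum
(worst-case congestion).  Bare flanks fall back to the H Sterimol.  An
alternative `h_shell` mode (the site's own C–H axis with a configurable
ring shell) is available; both are configuration flags.

## Pair encoding

The default schema holds 13 per-site descriptors — %Vbur, Sterimol L/B1/B5,
f⁺, f⁻, f⁰, dual descriptor (f⁺−f⁻, derived when not supplied), partial
charge, C–H BDE, and three extension slots for user-supplied columns —
plus one molecule-level descriptor (computed oxidation potential) and the
reaction temperature: 13×2 + 1 + 1 = 28 features per competing pair, laid
out `[site A | site B | molecule | T]`.  Schemas are explicit objects;
width and name uniqueness are validated, as are physical bounds on ingested
electronic descriptors (|Fukui| ≤ 1 e, |charge| ≤ 3 e, BDE within
50–200 kcal/mol — unit-mixup guards, not chemistry).  Antisymmetry is
handled by canonical pair ordering at dataset construction, with optional
swapped-pair augmentation at training time; a delta encoding (A−B) was
considered and set aside because it discards within-pair context that tree
models exploit, but the augmentation route keeps the learner order-agnostic.

## Model harness

Registry (fixed, documented, no tuning): Extra-Trees and random forest at
100 trees (sized for datasets of tens to a few hundred pairs, where more
trees only add runtime), scikit-learn default gradient boosting, RBF-SVR
(C = 10, ε = 0.05) and k-NN (k = 5) behind a standardizing pipeline, and
ridge with α = 1e-6 — effectively ordinary least squares with a
conditioning guard, so exact linear ground truth is recovered to numerical
precision.  All randomness is the single integer seed recorded in every
report alongside a config hash.

Evaluation is leave-one-out; Pearson R and MAE are computed on the
concatenated held-out predictions because size-1 folds admit no per-fold
correlation.  Two split units are exposed: per-pair (the default) and
grouped per-arene, which is the honest unit for prospective use — the
grouped path asserts structurally that no training row shares an arene with
the evaluated fold, and the OOS evaluator reports its train/test arene
partition so leakage can be audited externally.  Greedy forward feature
selection maximizes LOO Pearson R with stopping tolerance 1e-3 and
lexicographic tie-breaking.  Feature importance is either normalized
impurity (tree ensembles only) or permutation importance defined as the
mean Pearson-R degradation over 10 column shuffles, clipped at zero.
Constant-target or constant-prediction cases report MAE with R flagged as
undefined (NaN) rather than erroring.

## Pairwise-to-site aggregation

Pairwise DDG predictions over the sites of one arene are reduced to
per-site potentials g by least squares on the comparison graph
(min Σ(g_a − g_b − DDG_ab)²), with the zero-sum gauge Σg = 0 — arbitrary
but deterministic; only differences are physical.  The solution is unique
on connected graphs and reproduces a consistent spanning tree exactly;
disconnected graphs are an error naming the components.  Site probabilities
follow p_i ∝ m_i·exp(g_i/RT), computed with a max-shift for overflow
safety.  The loop measurement → targets → aggregation → probabilities is an
identity to 1e-6 (tested).

## Synthetic generator

The generator defines the conditions under which the package's claims are
tested.  Geometry fixtures use ideal aromatic geometry (C–C 1.39 Å, C–H
1.09 Å, planar rings, tetrahedral sp³ caps) over a small substituent
vocabulary plus naphthalene/thiophene/furan templates — exact, deterministic
coordinates for descriptor and symmetry oracles.  Descriptor datasets draw
per-class values from loosely physical distributions (e.g. %Vbur ~ N(35, 8)
truncated to [0, 100], f⁻ ~ |N(0.05, 0.02)|, BDE ~ N(112, 3) kcal/mol,
E_ox ~ N(1.9, 0.25) V); they are plausible ranges, not fits to any dataset.
The true site score is linear in the descriptors with weights dominated by
the reacting site's f⁻ (30 kcal/mol per e) plus smaller steric and BDE
terms and an E_ox·f⁻ interaction (5 kcal/mol per V·e) reflecting the
electro-oxidative mechanism; pair targets are score differences plus
Gaussian noise σ = 0.25 kcal/mol at 333.15 K, exactly antisymmetric at
σ = 0.  A `tree_friendly` variant replaces the linear law with
piecewise-constant threshold steps to exercise ensemble-vs-linear ranking.
Arenes carry 2–4 site classes with multiplicities in {1, 2}; 150 pairs
(≈45 arenes) is the default problem size, which keeps a 20-seed LOO study
within a few CPU-minutes.

What the generator does *not* emulate: correlated descriptor blocks from a
shared electronic structure, heteroscedastic measurement error, secondary
product oxidation drifting the observed ratio over time, and any resemblance
to a specific experimental dataset's values.  Passing the recovery tests
therefore demonstrates that the pipeline is a faithful estimator under its
own stated mechanism — not that real arene selectivity is this predictable.

## Numerical choices and degenerate inputs

Grid pitch must satisfy 0 < h ≤ r_sphere/5; atoms closer than 0.5 Å are
rejected as broken structures; a Sterimol axis shorter than 1e-8 Å or longer
than 2.0 Å is a geometry error; probe spheres with no occupying atoms warn
and return 0%.  Ratio parsing accepts "17:1"-style strings and normalizes.
Least-squares aggregation uses LAPACK lstsq with an explicit gauge row and
exact re-centering.  All tie-breaks (feature selection, importance ranking,
algorithm ranking) are lexicographic and documented in the docstrings.

## Known limitations

Electronic descriptors are ingested, so descriptor quality bounds model
quality; graph-only symmetry treats topologically equivalent but
conformationally locked sites as one class; the flanking-Sterimol truncation
radius is a heuristic locality choice; and reproducing published benchmark
metrics on a specific experimental dataset requires that dataset and its
exact descriptor definitions, which this repository does not bundle.
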