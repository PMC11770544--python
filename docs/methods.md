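# Methods

This note records the models implemented in `larakit`, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer would want to know about.

## Pairwise alignment and residue equivalence

All sequence comparisons use optimal global (Needleman–Wunsch) alignment
with affine gaps, computed by `Bio.Align.PairwiseAligner`.  Defaults are
BLOSUM62 with gap open 11 and gap extend 1 (a gap of length L costs
`open + (L−1)·extend`); the scoring is configurable but nothing downstream
is sensitive to moderate changes at the identity levels involved.  `X` is
accepted and scores 0 against everything.  When several tracebacks are
co-optimal the aligner's first reported alignment is used; it is
deterministic for a given input and parameter set, which is the property the
clustering and position-mapping invariants rely on.

**Percent identity** is identical residue pairs over alignment columns
*after excluding terminal-gap columns*; internal gap columns count as
mismatches.  Tools differ here, so the choice is explicit: excluding
terminal gaps avoids penalizing fragment queries.  A consequence worth
knowing: identity is not monotone under appending shared residues once
terminal gaps are involved (trimmed columns can become internal), and the
test suite asserts monotonicity only in the ungapped regime where
(m+k)/(c+k) ≥ m/c holds.

**Residue equivalence** ("the query residue equivalent to F175 of LarA1")
is read off the alignment column of each 1-based reference coordinate; a
reference position aligned to a query gap has no equivalent and is reported
absent.  Structure superposition can disagree with sequence alignment for
remote homologs; this package is sequence-only by design.

## Repertoire reduction

Length filtering keeps sequences of 300–600 residues inclusive.  Greedy
centroid clustering processes sequences in decreasing length (ties broken
by id), assigns each to the *first* centroid, in centroid-creation order,
with identity ≥ the threshold (default 0.5), and otherwise creates a new
centroid — first-match semantics, matching the behavior documented for the
greedy clustering tools used for large superfamily reductions, not
best-match.  Identity is exact alignment identity rather than a k-mer
approximation; an optional shared-5-mer prefilter can skip hopeless
comparisons and is required (and tested) not to change the partition.

Per-taxon prevalence reports the percentage of species with ≥ 1 gene copy
and the mean copy number among carrier species (an all-species mean is
available by flag); taxa are sorted by descending prevalence.

## Family classification by diagnostic residues

| family | 175 | 176 | 358 | 359 |
|--------|-----|-----|-----|-----|
| LAR    | F   | F   | W   | E/Q |
| GntE   | E   | V   | A   | H   |
| HGR    | Y   | F   | H/Q | T   |
| MAR    | –   | –   | H/Q | K   |
| HHR    | –   | –   | F/Y | –   |

Rules are evaluated most-constrained-first: a fully matched 4-position rule
beats a fully matched 2-position rule; two fully matched rules of equal
constraint count yield `ambiguous`; no match yields `unclassified`.  The
result is independent of rule-list order (a property the suite checks
against a brute-force enumeration oracle).  Missing diagnostic positions and
the absence of a catalytic-His equivalent at 108/174 raise flags but do not
veto a call — the His positions are context, not classification criteria.

These are "usually" rules.  Characterized lactate racemases exist with T or
C at the 359-equivalent position, outside the strict {E,Q} set; an
`EXTENDED_RULES` table widens LAR-359 to {E,Q,T,C} but is deliberately not
the default, so published rule semantics are never silently widened.
MAR positions 175/176 are left unconstrained because no allowed set is
established for them.

## Michaelis–Menten kinetics

The fit is nonlinear least squares of v = V·S/(K_M+S) via
`scipy.optimize.curve_fit` with positivity bounds and tight tolerances
(1e−13), initialized at V₀ = 1.1·max(v) and K_M,0 = the concentration at
half-maximal mean velocity by linear interpolation.  Replicates are pooled
into one problem.  95% confidence intervals use the asymptotic covariance
with a Student-t quantile at n−2 degrees of freedom.  k_cat = V/[E]₀ assumes
100% active-enzyme (cofactor) loading, so k_cat and k_cat/K_M are lower
bounds when loading is incomplete; a `loading_fraction` parameter rescales
them.  Catalytic efficiency is k_cat/(K_M·10⁻³) in M⁻¹ s⁻¹ (K_M given in
mM) and is also rendered at two significant figures, the precision at which
such tables are printed.

The default objective is **unweighted**; a 1/v² weighting is available.
Under multiplicative (constant-CV) error the unweighted fit mis-specifies
the variance and its asymptotic K_M interval over-covers (≈ 0.98 at
CV = 0.05 in our calibration runs) while the k_cat interval under-covers;
with the matched 1/v² weighting both intervals are calibrated (≈ 0.95).
Calibration checks therefore pair the multiplicative-noise generator with
the 1/v² weighting; the unweighted default is kept for routine fits because
assay reports conventionally use plain least squares.  The calibration
study uses an 8-point saturation grid spanning 0.2–20 × K_M with 3
replicates at CV = 0.05 and 500 simulated datasets — a standard design
scaled for desk-side runtimes.

**Optimum range**: the set of *tested* pH or temperature conditions with
activity > 0.9 × the maximum observed activity; the reported range is the
min and max of that set, with no interpolation between grid points.  A
non-contiguous qualifying set triggers a warning.  A degenerate all-zero
profile (the predicate would exclude everything) returns the whole tested
range.

## Competition-based efficiency tables

One competition observation gives k_X/k_Y = (v_x/v_y)·([S_Y]/[S_X]); the
concentration correction is applied even though assays are typically run at
equal concentrations.  Replicates are pooled as a geometric mean with a
log-scale standard error.  v_x = 0 is treated as "no detectable activity":
the pair is excluded from the graph with a flag rather than entering as a
zero.

The panel of per-pair ratios forms a graph over substrates.  Node log
efficiencies are estimated by least squares on log k_X − log k_Y = log r
with one node fixed at zero — weights 1/se² when every edge has a
replicate-based standard error, unit weights otherwise (residual-scaled
covariance in that case).  Least squares was chosen over sequential
multiplication along paths because it handles redundant and mildly
inconsistent designs symmetrically; a spanning-tree multiplication mode
exists for comparison and agrees exactly on consistent designs.  The
solution is exponentiated and scaled so the preferred substrate is exactly
100 (ties broken by substrate name).  Disconnected designs yield one table
per connected component plus a warning, since cross-component values are
not comparable.  Cycle consistency is reported per cycle-basis cycle as the
log of the product of ratios around the cycle, flagged above a default
tolerance of 0.2.

Anchoring multiplies the relative table by one experimentally measured
k_cat/K_M; the anchor cell reproduces the measured value (and its CI)
exactly, and other cells get first-order log-scale error propagation
combining the anchor's relative error with the graph standard errors of the
two nodes (node–node covariance is not retained; the CIs are mildly
conservative).  The published tables this mirrors do not state how their
propagated CIs were derived, so the delta-method choice is this package's
own, with a seeded bootstrap left as future work.

## Synthetic data: what it emulates, what it does not

* **Sequences.**  A fixed 430-residue pseudo-random base scaffold (a package
  constant, not any real sequence) carries the invariant anchors R75, H108,
  H174, K184, H200 at LarA1-equivalent coordinates.  Each family is a fixed
  scaffold variant substituting 55% of unconstrained positions, with the
  family's diagnostic residues at 175/176/358/359; positions within ±3 of
  any active-site position are conserved across families, as catalytic
  motifs are in real proteins.  This yields within-family identity ≈ 0.95
  at mutation rate 0.05 and between-family identity ≈ 0.25–0.33, so
  0.5-identity clustering separates families while all families remain
  globally alignable to the reference for signature extraction.  Per-record
  noise: uniform substitutions at `mutation_rate` (never at constrained
  positions), and with probability `indel_rate` one 1–5 residue insertion
  or deletion placed so that no constrained position is deleted (ground
  truth must stay defined).  The generator does **not** simulate descent
  along a phylogeny, realistic substitution matrices, rate heterogeneity,
  or domain rearrangements — so passing tests show the pipeline's
  operations are correct on sequences with the assumed signal structure,
  not that the residue rules themselves hold in nature (they come from the
  literature).
* **Kinetics.**  v = k_cat·[E]₀·S/(K_M+S)·(1+ε), ε ~ N(0, CV); assay error
  scales with signal, hence multiplicative.  Default CV 0.05 (a typical
  plate-reader coupled-assay error; the underlying studies do not state
  one) with 3 replicates on an 8-point grid.
* **Competition.**  v_x/v_y = (k_x[S_x])/(k_y[S_y]) × lognormal noise
  (σ = √log(1+CV²)), keeping ratios positive; default 30 mM substrate, the
  standard assay loading.  Substrate depletion and product inhibition
  during incubation are not modeled.
* **Taxonomy.**  Per-taxon Bernoulli carriage at a specified fraction with
  a constant or user-supplied copy-number law for carriers.

All generators are deterministic given spec + seed (NumPy `default_rng`).
Noise-free settings reproduce the stated models exactly, which is what the
round-trip tests exploit.

## Degenerate inputs and tie-breaks

* Fits require ≥ 3 distinct concentrations and at least one positive
  velocity; non-convergence returns `converged=False` rather than raising.
* Clustering ties: length-sorted processing breaks ties by id; assignment
  is first-match in centroid-creation order, so cluster count is
  deterministic.
* Preferred-substrate ties in efficiency tables break by substrate name.
* Empty rule lists, unknown families, inverted length bounds, out-of-range
  thresholds and coordinates all raise `ValueError` naming the offender.

## Known limitations

* The original superfamily-scale reduction (12,441 → 1212 sequences) and
  database prevalence percentages require external retrievals and are out
  of scope; the corresponding machinery is validated on synthetic inputs
  with known ground truth.
* Sequence-rule classification near family boundaries can disagree with
  tree-based assignments; no phylogenetic placement is attempted.
* Anchored CIs ignore node–node covariance from the graph solve and are
  slightly conservative.
* The alignment layer is strictly pairwise-global; fragments are handled
  through terminal-gap-tolerant identity, not local alignment.
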