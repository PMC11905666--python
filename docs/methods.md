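# Methods

## Data model

A dataset is an ordered table of text cells with stable integer row ids.
Attributes are typed by role: quasi-identifier, sensitive, insensitive, or
(direct) identifier. Every quasi-identifier carries a *generalization
hierarchy*: a rectangular table with one row per distinct leaf value and one
column per level `0..L`, level 0 being the leaf and, by convention, a single
top `"*"`. Equal values at level j must map to equal values at level j+1
(functional consistency), which is what makes full-domain recoding at a level
well defined. Numeric attributes are handled through interval hierarchies;
cells are never parsed. The empty string is an ordinary value and must appear
in the hierarchy; there is no implicit imputation. Direct identifiers are
always masked in the output.

## Privacy models

Eleven syntactic models are supported (see README for the formulas). Two
design points deserve explanation:

* **Boundary conventions.** All thresholds are inclusive — |c| ≥ k,
  H ≥ ln ℓ, EMD ≤ t, relative gain ≤ β, ratios ≤ τ — except δ-disclosure,
  which is strict (|ln(p/q)| < δ), following each model's canonical
  statement. Inclusive comparisons carry a 1e-9 slack so that exact boundary
  cases (e.g. EMD exactly t) are not lost to floating-point rounding.
  Natural logarithms are used throughout; the entropy-ℓ threshold is
  base-independent, and the δ-disclosure log base is a single module
  constant (`p4anon.models.LOG`) should the base-2 convention be preferred.
* **Grassberger entropy.** The bias-corrected estimator uses Grassberger's
  1988 correction, H = ln N − (1/N) Σ nᵢ G(nᵢ) with
  G(n) = ψ(n) + (−1)ⁿ/(n(n+1)). The correction term lives in one function
  (`grassberger_entropy`) so a different variant can be swapped in without
  touching any caller.

**Monotonicity registry.** A model is monotonic when merging passing
equivalence classes with equal keys always yields a passing class; monotonic
models need no compliance checking after partitions merge. Registered
monotonic: k-anonymity, distinct-ℓ, entropy-ℓ (Shannon), recursive-(c,ℓ),
average risk, sample uniqueness. Registered non-monotonic: both t-closeness
variants, δ-disclosure, both β-likeness variants, and entropy-ℓ with the
Grassberger estimator. The reference-dependent models are non-monotonic
*across partitions* because each partition checks against its own local
distribution; Grassberger is flagged conservatively because the corrected
estimator's behaviour under mixing is not proven here. A conservative flag
only adds compliance checking — it can cost utility, never privacy. The
registry is property-tested by merging random passing classes (10⁴ trials).

**Reference distributions.** Per-partition anonymization uses
partition-local sensitive-value distributions — that is what "anonymized
individually with the same settings" means operationally, and it is exactly
why reference-dependent models do not survive merging. Compliance checking
and final verification use the global input distribution, computed once up
front. For ordered-distance t-closeness the value ordering comes from the
model declaration when given, otherwise from the lexicographically sorted
reference support; sensitive attributes have no hierarchy, so a hierarchy
order is not available.

## Lattice search

The search space is the lattice of level vectors (one level per
quasi-identifier, `Π(Lₐ+1)` nodes, guarded by a configurable cap of 10⁶).
At a node, classes failing any class-level model are suppressed; the node is
valid when the suppressed fraction stays within the suppression limit
(default 1.0 — suppression always allowed and penalized purely through
fidelity) and all dataset-level models hold on the surviving classes. Among
valid nodes the search maximizes fidelity, breaking ties by smaller level
sum, then lexicographically — fully deterministic. With no valid node (only
possible when the limit is below 1) the configuration is reported infeasible
rather than silently degraded.

*Predictive pruning* is applied only when every configured model is
monotonic **and** the suppression limit is 0: in that regime a valid node's
successors are valid by monotonicity and only their fidelity needs
computing. With a nonzero limit the implication fails — a coarser node can
merge a passing class with a *failing* (suppressed) one, which monotonicity
does not cover (entropy-ℓ is a concrete counterexample) — so pruning stays
off. Tests assert that pruning never changes the chosen node.

*Local recoding* runs the global search repeatedly (default 10 rounds,
stopping early at a fixpoint): records of passing classes are frozen at the
round's scheme, the suppressed residual is re-anonymized in the next round,
and whatever remains at the end is suppressed. The partition-level reference
distribution is held fixed across rounds. Dataset-level models are enforced
per round on the survivors; since both supported dataset-level statistics can
only improve under pooling of disjoint passing collections, a violation on
the combined output is treated as an internal error.

## Utility

Per-cell fidelity is `1 − (covered−1)/(D−1)` (1 when D = 1), where *covered*
counts the leaves subsumed by the cell's value: 1.0 for an untouched leaf,
0.0 for `"*"`. The verbal notion "degree to which the output covers the
input domain" admits several normalizations; this one is pinned by tests and
exposed as a swappable strategy (`p4anon.utility.CELL_FIDELITY`) so e.g.
`covered/D` could be configured instead. Record fidelity is the mean over
quasi-identifier cells (suppressed records score 0), dataset fidelity the
mean over records, and partition results aggregate by record-count-weighted
pooling — provably identical (and tested to 1e-12) to computing fidelity on
the concatenated output, which is the only self-consistent aggregation rule.
The optimizer's objective and the reported utility are the same metric.

## The four-step procedure

* **Partitioning** sorts records by quasi-identifier tuple (codepoint string
  order, stable) and cuts the sorted table into contiguous chunks whose
  sizes differ by at most one. Records with identical tuples may straddle a
  boundary; correctness is unaffected because merging is handled by
  monotonicity or compliance checking. Sorting concentrates equal tuples
  within partitions, which is what keeps the utility cost of
  parallelization low.
* **Harmonization** (global mode) combines the per-partition schemes —
  average level rounded half-up (default), minimum, or lower median — and
  re-applies the common scheme to every partition. Classes failing a
  class-level model under the forced scheme are suppressed *ignoring* the
  configured suppression limit: once the scheme is fixed, suppression is the
  only remaining lever and privacy is non-negotiable. Partitions already at
  the harmonized scheme are reused without recomputation.
* **Compliance checking** pools the non-suppressed output rows, groups them
  by generalized key, and re-evaluates every non-monotonic class-level model
  with the global reference distribution; records of failing merged classes
  are `*`-suppressed. Monotonic models cannot fail on merge, so the step is
  skipped when none of the configured models is non-monotonic.
* **Finalization** concatenates the partitions (sorted order; the carried
  row ids can restore input order), re-verifies every class-level model on
  the merged classes — a failure here raises an internal-consistency error,
  because after compliance such a failure can only be a bug — and *enforces*
  dataset-level models: forcing a harmonized scheme on a partition that
  wanted a coarser one, or removing a large merged class during compliance,
  can legitimately push the class/record ratio over its threshold, so
  smallest classes (ties broken by key) are suppressed until the
  dataset-level models hold again. Fidelity is computed by weighted pooling
  and cross-checked against the whole-output computation.

Suppressed records keep their sensitive and insensitive cells and have all
quasi-identifier cells set to `"*"`; the independent checker (and `p4
check`) excludes such rows from class formation, since a fully suppressed
tuple carries no re-identification information. Because sensitive cells are
never altered, the global reference distribution is recoverable from the
output alone, and output checking needs no access to the original input.

**Determinism.** The engine contains no randomness. Partitions are
independent pure tasks executed on a thread pool (worker count defaults to
the partition count) and collected in partition order, so results are
byte-identical for any worker count. All grouping and iteration orders are
canonical (lexicographic). Per-step timings are reported for the four
stages, with the parallel step charged the maximum per-partition duration.

## Synthetic data

The generator emulates the shape of demographic survey extracts: a few
categorical quasi-identifiers with domains of 3–20 values under balanced
fanout-2/3 interval hierarchies, a 2–4-valued sensitive attribute, and
Zipf-like frequency skew (exponent 0–1.2; 0 = uniform). It does *not*
emulate inter-attribute correlation, missingness patterns, or the long
categorical tails of real census data — so passing tests demonstrate the
engine's correctness properties (guarantee preservation, optimality,
determinism, utility accounting), not utility numbers transferable to any
particular real dataset. `extrapolate` is a seeded
sample-with-replacement stand-in for distribution-aware record
extrapolation, adequate for size scaling only.

Randomized suites draw datasets of 10²–10⁴ records across all eleven model
kinds and partition counts {1, 2, 4, 8}; the utility-vs-parallelism study
uses 50 000-record tables with three quasi-identifiers spanning 3 000
distinct tuples (k = 5, global mode, P ∈ {1, 16}), a regime where
partitioning produces a measurable but small median fidelity reduction —
the intended trade-off of the method.

## Known limitations

* Only the coverage-loss utility model is implemented (the strategy hook
  admits others); no microaggregation, masking, or on-the-fly hierarchy
  induction — transformations are full-domain generalization, local
  recoding, and suppression.
* No population-based models (k-map with estimators, δ-presence),
  profitability, hierarchical-distance t-closeness, or differential privacy.
* Single-machine only; the lattice is enumerated exhaustively (with the
  monotone pruning described above), which is intended for the moderate
  hierarchies typical of health microdata, not for dozens of
  quasi-identifiers.
* Local recoding's round structure (fix survivors, recurse on the residual)
  is one reasonable realization of per-region schemes; other local
  strategies would give different utility.
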