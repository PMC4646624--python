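# Methods

## The model

A food web is modelled as a directed binary graph: taxa as nodes, a link
from consumer to resource for every feeding relationship treated as
present.  Presence/absence is the only information carried — no abundances,
diet proportions or interaction strengths — so every statistic here is a
*topological* property.  Taxa are annotated with a trophic compartment
(lower-trophic resource, phytoplankton, zooplankton, macroinvertebrate,
amphibian, fish), a habitat tag used to extract pelagic sub-webs, a
phytoplankton growth form, and a macroinvertebrate functional feeding
group (FFG).  Lower-trophic resources (coarse organic material, fine
detritus, macrophytes, water-moss, periphyton) are aggregate nodes that may
consume nothing; a web that violates this is flagged as invalid.
Microbial decomposers are outside the model.

Sub-web extraction is purely structural: keep the taxa satisfying a
predicate and the links whose two endpoints survive.  The two canned
predicates are *fishless* (drop the fish compartment) and *pelagic* (keep
habitat ∈ {pelagic, both}); extraction never increases S or L and composes
(extracting p then q equals extracting p∧q).

## Trophic levels

Three per-taxon levels on the basal = 1 scale:

* **shortest** — 1 + the minimum number of links on a directed path down to
  a basal taxon (multi-source BFS from the basal set on the reversed
  graph);
* **prey-averaged** — the unique solution of the linear system
  `TL_i = 1 + (1/n_i)·Σ_{j∈prey(i)} TL_j`, basal `TL = 1`, solved directly
  (`numpy.linalg.solve`); cycles anchored to the basal set are handled
  exactly by the solve, with no iteration;
* **short-weighted (SWTL)** — the arithmetic mean of the two.

Self-links are excluded from prey sets in both computations: a cannibal
cannot raise its own trophic level, and exclusion keeps the linear system
nonsingular.  A web with no basal taxon, or with consumers in a cycle that
has no path down to one, has undefined levels; the affected taxa are named
in the error, and the assembled report records these metrics as missing
with the reason rather than failing.

## Conventions the literature leaves open

Four choices are explicit, config-switchable (`Conventions`), and stamped
into every output:

* **Averaging set** (default: consumers only).  `MeanSWTL` and
  `MeanShortChn` average over non-basal taxa.  For webs dominated by basal
  taxa the two candidate conventions differ grossly; published pelagic
  values for webs that are ~76 % basal (e.g. mean SWTL 2.60 against mean
  shortest chain 2.43) are only arithmetically reachable with
  consumers-only averaging, which is therefore the default.  Exact
  reproduction of published values for these two metrics is not promised —
  they remain convention-sensitive.
* **Chain units** (default: trophic-level scale, herbivore = 2).  A
  link-count variant (herbivore = 1) is available since "shortest chain to
  a basal species" is ambiguous between the two.
* **SD form** (default: population, divide-by-S).  `GenSD`/`VulSD` are SDs
  of the *normalized* counts `(S/L)·degree`; raw-count SDs would be an
  order of magnitude larger than published values at D ≈ 5–8.  Both means
  are 1 by construction, a cheap internal check.
* **Omnivory basis** (default: compartment ladder).  Prey trophic levels
  for omnivory/herbivory and for the trophic-level count come from the
  six-step compartment ladder (lower-trophic = 1 … fish = 6), mirroring
  how "six trophic levels" is counted in lake studies; a computed-level
  basis (rounded shortest level) is the alternative.

Self-links count toward `L`, `Can` and the similarity sets but are ignored
when classifying top/intermediate/basal (a taxon whose only predator is
itself is still top).  `Herb` and `Omn` are fractions of all S taxa, like
every other fraction in the report.  Trophic similarity of a pair is
(shared predators + shared prey) / (distinct predators and prey of
either); a pair of fully isolated taxa scores 0 by convention; `MaxSim`
is the global pairwise maximum.

## Synthetic webs

The lake generator encodes the assembly rules as candidate links, each
retained independently with probability `p_link`: zooplankton → unicellular
phytoplankton (never colonial/filamentous — the size-based inedibility
rule); a configurable fraction of zooplankton also preys on other
zooplankton; collectors/filterers → fine detritus, shredders → coarse
organic material, scrapers → periphyton + unicellular phytoplankton,
predatory macroinvertebrates → other macroinvertebrates (self-links if
cannibalism is enabled); amphibians → macroinvertebrates; fish →
zooplankton + macroinvertebrates + amphibians (+ fish under cannibalism).
A consumer whose sampled diet is empty gets one forced link from its
eligible set, so no consumer silently becomes basal; a compartment with an
empty eligible set (e.g. zooplankton with only colonial phytoplankton)
aborts generation with the starving group named.

Defaults (5 basal resources, 20 phytoplankton with 35 % colonial forms, 6
zooplankton of which a quarter predatory, 30 macroinvertebrates under a
collector/predator-heavy FFG mix, 3 amphibians, 1 fish, `p_link = 0.6`)
give S = 65 webs with D ≈ 4.7–5.1 and C ≈ 0.07–0.08, inside the range
observed for real alpine-lake webs of this size; `p_link` is a calibration
knob, not an estimate of any real retention probability.  What the
generator does *not* emulate: taxonomic identity, benthic–pelagic coupling
beyond the fish, diet breadth heterogeneity within compartments, and the
high omnivory of real lake webs (the rules confine most consumers to one
ladder level, so generated `Omn` ≈ 0.1 versus > 0.8 in real webs).
Passing tests on generated webs therefore validate the *machinery*
(identities, conventions, sub-web logic), not ecological realism.

The niche model places taxa at uniform niche values with contiguous
feeding ranges whose beta-distributed widths are calibrated so expected
connectance equals `C_target`; generation is retried (bounded) until a
basal taxon exists.  The random baseline links each ordered pair
independently with probability `C_target`.  Both converge to the target
connectance in the mean (checked at S = 50 over 500 seeds, tolerance
0.01).

A note on the fishless direction check: removing the fish — the broadest
generalist and a predator of many taxa — can only narrow the spread of
raw diet sizes, and rarely widens raw predator-load spread; the test
asserts this on raw-count SDs (≥ 90 % of 200 seeded replicates).  The
*normalized* `GenSD`/`VulSD` may drift slightly upward instead, because
removing a high-degree node lowers L faster than S and inflates the S/L
scale — the same slight upward drift the published fishless columns show.

## Cross-study comparison

Per-web property tables (`S, L, D, C`, one row per web, a study label per
row) are compared in three steps: (i) correlation-matrix PCA — each
variable centred and scaled by its population (divide-by-n) SD, the ADE4
convention, so eigenvalues are those of the correlation matrix and sum
exactly to 4; (ii) between-class analysis — between-class inertia (class
means weighted by class size) over total inertia, a ratio in [0, 1]
invariant to axis rotation; (iii) a Monte-Carlo permutation test — labels
permuted uniformly, add-one estimator
`P = (1 + #{permuted ≥ observed})/(1 + n_perm)`, default `n_perm = 999`
(so P as small as 0.001 is representable; ties count as exceedances,
keeping the test valid).  Eigenvector signs are arbitrary; nothing
downstream depends on them.  The implementation is cross-checked against
an SVD route, an explicit sum-of-squares decomposition, and R's `prcomp`
(whose correlation eigenvalues are divisor-independent).

## Problem sizes and numerics

The test suite runs everything at small scale: oracle equivalence on
8-taxon webs (exhaustive path enumeration, damped fixed-point iteration at
tolerance 1e-10, double-loop set similarity), calibration at 500 seeds,
null calibration of the permutation P at 1000 repetitions of `n_perm = 99`
(KS against uniform at α = 0.01), power at `n_perm = 999`.  Scoring a
100-taxon web takes well under a second.  Degenerate inputs are defined,
not guessed: an empty link set yields D = C = 0 and undefined
`GenSD`/`VulSD`; a single-taxon web has no similarity; a web with
untagged taxa runs all structural metrics and reports
compartment-dependent ones as missing with the reason.

## Limitations

Binary topology overstates the importance of rare links and is sensitive
to study-specific aggregation of basal resources; the published census
values used as inputs inherit both issues.  The generator's realism ends
at its compartment rules (above).  Published per-study property tables
from other lake studies are not bundled, so the comparison stage is
exercised on synthetic tables with known structure; the published
eigenvalues themselves are not asserted.  Convention-sensitive metrics
(`MeanSWTL`, `MeanShortChn`, `GenSD`, `VulSD`, `Omn`) reproduce published
values only insofar as the conventions above match the original,
undocumented choices.
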