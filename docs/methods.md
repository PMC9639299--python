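# Methods

This note records the models behind each estimator, the conventions the
package commits to where the literature leaves room, and what the
synthetic-data validation does and does not establish.

## Pedigree representation

A pedigree is a topologically ordered list of (id, sire, dam) records.
Referenced parents without their own record are promoted to founders;
individuals with no known parents are founders and assumed unrelated and
non-inbred. An individual with one known parent keeps it; the unknown
side contributes nothing to relationship or inbreeding, and for
gene-origin purposes it is an anonymous, unrelated pseudo-founder
specific to that slot. Generation depth is 1-based (parents = depth 1).

Depth metrics follow the standard definitions: equivalent generations
Σ (1/2)^n over all known ancestor slots; full generations the deepest n
with every slot known up to n; maximal generations the longest known
ancestral path; completeness the per-depth fraction of known slots.

**Ancestry truncation.** `truncate_to_depth(id, g)` keeps ancestors whose
*minimal* generation distance from the individual is ≤ g and strips the
parents of those exactly at g. When an ancestor is reachable at several
depths (parent–offspring matings and the like) its parents survive as
long as one occurrence is shallower than g, so ancestral paths longer
than g can persist; the alternative — expanding the ancestor tree into
per-depth slots — destroys asymmetric inbreeding loops and mis-computes
truncated F, so the minimal-depth convention is used. Consequently F3 ≤
F6 ≤ F9 ≤ F holds always, while "equivalent generations ≤ g after
truncation" holds only when no ancestor recurs at several depths.

## Deterministic coefficients

Classical F comes from the tabular relationship matrix
(A_ii = 1 + ½A_sd, rows built parents-first); it is checked against an
independent Wright path-counting oracle, Σ (1/2)^(n+n'+1)(1 + F_A) over
ancestor-disjoint path pairs, to 1e−12 on random pedigrees. The tabular
route is dense and intended for pedigrees up to a few thousand
individuals — the scale of the simulated cohorts here.

Ballou's recursion treats the sire and dam events as independent; on
pedigrees whose inbreeding loops overlap it deviates from the exact
(gene-drop) expectation. Both routes are exposed; the coefficient table
reports the recursion (fast, deterministic) and `gene_drop` the
simulation estimate, and the tests document where they agree exactly
(disjoint loops) rather than hiding the discrepancy.

## Gene dropping

Each replicate assigns every founder two uniquely labelled alleles and
samples one allele from each parent pair down the (topologically
ordered) pedigree. An individual is autozygous when its two labels
coincide. Each transmitted copy carries a counter of IBD events: when a
parent is autozygous in the replicate, every allele it transmits in that
replicate is incremented. The counter convention — an individual's own
autozygosity counts toward the copies it transmits, never toward its own
"ancestral" status — makes E[AHC] = F for an individual whose ancestors
are non-inbred, and is a convention: verbal definitions of the ancestral
history coefficient do not pin down the off-by-one.

Estimators: F̂ = P(autozygous); F̂a_Bal = P(arriving counter ≥ 1);
F̂a_Kal = P(autozygous ∧ counter ≥ 1); F̂new_Kal = P(autozygous ∧
counter = 0); AHC = E[counter + 1{autozygous}]; F̂_ij = P(autozygous with
the shared label from founder j). "Arriving allele" quantities average
the two alleles, so F̂a_Kal + F̂new_Kal = F̂ and Σ_j F̂_ij = F̂ hold
exactly on the realised replicate counts (tests assert 1e−12, the
rounding of two independent divisions). Defaults: 100,000 replicates,
seed 1234, processed in chunks of 25,000 (the chunk size is part of the
reproducibility contract; same seed + chunk ⇒ bit-identical estimates).
Exhaustive enumeration of all 2^k transmission outcomes on small
pedigrees provides the exact oracle for the Monte-Carlo path.

## Gene origin: fe and fa

Founder contributions q_k propagate reference weight (1/N per reference
individual) half to each known parent; mass crossing an unknown-parent
slot accrues to that slot's pseudo-founder, so Σq = 1 and
fe = 1/Σq². For fa, the marginal contribution of a candidate is the
expected fraction of reference gene lineages passing through it while
avoiding every previously selected ancestor — computed as (weight
received from descendants with selected ancestors absorbing flow) ×
(probability the lineage continues upward to an unexplained terminal).
Pseudo-founder slots compete in the same greedy selection; otherwise fa
and fe partition different masses and fa can spuriously exceed fe on
incomplete pedigrees. Ties break by pedigree order; iteration stops when
the best marginal contribution drops below 1e−9.

## Genomic estimators

Allele frequencies are always in-sample over non-missing calls; no MAF
or LD filtering is applied anywhere. F_HOM uses the n/(n−1)-corrected
expected heterozygosity (the method-of-moments `--het` convention);
individuals informative only at monomorphic markers are NaN with a
warning. VanRaden's G centres genotypes at 2p_j, imputes missing calls
to the mean (zero contribution), and excludes monomorphic markers from
the denominator; F_G = G_ii − 1 is negative for individuals more
heterozygous than Hardy–Weinberg expectation (an all-heterozygous panel
at p = ½ gives exactly −1). The single-step H blends
G* = (1 − α)G + αA22 (α = 0.05 by default, regularisation toward the
pedigree block) through G(τ, ω) = (τG*⁻¹ + (1 − ω)A22⁻¹)⁻¹ and the
standard projection onto non-genotyped individuals; H = A exactly when
G(τ, ω) = A22, which the tests assert at machine precision, and an
independent inverse-form identity cross-checks the general case.

## ROH calling

The rule scanner finds maximal homozygous runs per individual ×
chromosome with: ≥ 30 markers, ≥ 1 Mb, 0 heterozygotes, one missing
call allowed per 50 homozygous calls (missing calls never terminate a
run and are excluded from the marker count), maximal inter-marker gap
1 Mb; boundaries sit on the first/last homozygous marker (1-based
inclusive bp).

The hidden-state caller is a two-state model (autozygous /
non-autozygous) decoded by Viterbi, vectorised across individuals.
Transitions follow an exponential segment-length model: with d the
inter-marker distance in Morgans, the state persists with probability
e^(−Kd) (K = 12 per Morgan by default, i.e. expected segments of
1/12 Morgan) and otherwise re-draws from the prior (autozygosity weight
0.01). Emissions assume founder haplotypes in linkage equilibrium and
route both states through the same genotyping-error channel the
simulator uses (homozygote → heterozygote, heterozygote → random
homozygote, ε = 0.001 by default): P(het | auto) = ε,
P(het | non-auto) = 2p(1−p)(1−ε) + (1 − 2p(1−p))ε. Missing calls emit
uninformatively. Contiguous autozygous stretches ≥ 1 Mb are reported.
A full multi-class segment-age mixture would refine segment dating, but
the downstream statistics consume only segment positions and lengths;
fidelity is instead validated directly against the simulator's tracked
truth (boundary recovery within 5 markers in ≥ 95/100 planted 20-Mb
segments at ε = 0.001 on common-variant markers; r ≥ 0.95 — observed
≈ 0.9998 — between F_ROH and the true autozygous fraction).

A known behaviour of maximum-likelihood decoding: a called segment
extends into the flanking run of chance homozygotes up to the first
heterozygous marker, so boundary precision is set by marker
informativeness (the waiting time to a heterozygote), not by the model.
The boundary-recovery experiment therefore uses a common-variant
spectrum (frequencies uniform on 0.35–0.65), where that waiting time is
short; on rare-variant-heavy panels boundary error is inherently larger.

F_ROH divides the summed segment length by the mapped genome length —
the sum over chromosomes of (last − first marker bp); the denominator is
a convention, stated because analyses differ on it. The generational
partition keeps segments of genetic length ≥ 1/(2g) Morgans for
g = 2..20 ("at least", so a segment exactly at the threshold is
retained); comparisons are done in Morgans so they are exact regardless
of the cM/Mb rate. The printed Mb thresholds truncate to one decimal
(16.6, 8.3, 5.5 for g = 3, 6, 9 at 1 cM/Mb). Physical↔genetic
conversion defaults to a constant 1 cM/Mb; a marker map with true cM
positions overrides it.

## Correlation analysis and the discard rule

Correlations are pairwise-complete Pearson (genomic columns exist only
for genotyped individuals); constant columns yield NaN with a warning.
For every trio the three first-order partials and the tolerance
ε = ⅓(Σ partial/direct) are computed; trios with a zero or undefined
ordinary correlation are excluded and logged. A pair is discarded when
|r_xy| ≤ |ε r_xz| and |r_xy| ≤ |ε r_yz| for at least one admissible
third variable ("any", the default) or for all of them ("all",
`--discard-rule`); the prose definitions of the extension across third
variables support either reading, so both are implemented and the choice
is explicit in the output. With fewer than three usable variables every
pair is reported significant, with a warning. Significance is a boolean
flag matrix, not stars.

## Synthetic data

The simulator exists to give every estimator a known truth, emulating
the statistical structure of a closed studbook population with a deep
pedigree rather than any particular breed:

- pedigrees under mating policies whose trajectories are textbook
  results (repeated full-sib lines follow F_t = (1 + 2F_{t−1} +
  F_{t−2})/4; close-kin mating with probability per generation, or a
  per-generation schedule to decouple historical from recent
  inbreeding); generations map to 10-year birth intervals so cohort
  summaries bin naturally;
- founder haplotypes in linkage equilibrium with allele frequencies from
  a configurable spectrum (uniform 0.05–0.95 by default — a genotyping-
  array-like common-variant spectrum; LD arises only from pedigree
  structure, which is sufficient for ROH semantics but understates
  background LD of real genomes);
- Haldane recombination (Poisson crossover counts, uniform placement, no
  interference), chosen for analytic checkability;
- physical positions derived from genetic positions at the configured
  cM/Mb so simulation and analysis thresholds align by construction;
- genotyping error as a symmetric state flip at rate 0.001 by default,
  then missingness at a flat rate;
- per-individual truth: the intervals where the two haplotypes descend
  from the same founder haplotype copy, and their genetic-length
  fraction of the mapped genome. E[true fraction] equals pedigree F,
  which the tests verify over replicates.

Because founders are in linkage equilibrium and mutation, selection and
interference are absent, passing tests show the estimators recover
pedigree-generated autozygosity; they do not certify behaviour under
strong background LD, array ascertainment bias, or selection.

Default study-like conditions: 31 chromosomes of 100 cM (the simulated
default genome), 1 cM/Mb, genotyping error 0.001. Tests and examples
scale chromosome and cohort counts down (2–10 chromosomes, hundreds of
individuals, 2,000–10,000 markers per chromosome) — sizes at which every
targeted effect is already resolvable, as the fixed-seed suites
demonstrate.

The correlation-decay demonstration (recent-horizon F3 versus the
length-restricted F_ROH series) uses a 12-generation pedigree with heavy
close-kin mating for nine generations and mild mating control for the
last three, genotyping the final two cohorts: the decay of r(F3,
F_ROH(gG)) beyond small g requires ancient autozygosity to dominate the
short-segment mass, which is a property of deep, historically inbred
populations, not of uniformly inbred ones — an 8-generation pedigree
with constant close-kin probability saturates instead of decaying.

## Pipeline

`inbredkit run` executes simulate → pedigree coefficients → genomic
coefficients → correlations/summaries from one YAML config, deriving
stage seeds from the single top-level seed (base, base+1, base+2), and
writes a manifest with SHA-256 checksums of every output; identical
configs and seeds reproduce identical checksums. Per-interval summaries
report cohort size, mean F, contributing founders, fe, fa, fe/fa, mean
common-ancestor count and the mean positive founder-partial coefficient
per 10-year interval.

## Known limitations

- Dense relationship matrices bound practical pedigree size (~10³–10⁴).
- The two-state ROH caller does not age segments into generation
  classes; the Fisher partition does that downstream by length only.
- The pedigree F3/F6/F9 truncation convention above can keep long paths
  alive through multi-depth ancestors.
- Simulator genomes lack background LD, mutation and selection.
- The discard rule's "any"/"all" extension is a genuine ambiguity in the
  procedure's verbal definition; results report which was used.
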