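# Methods

This note documents the models, parameters, and numerical choices behind
`lcnet`, and what the synthetic-data validation does and does not show
about real EHR data.

## Cohort model

A patient is indexed by the earliest qualifying code date inside the closed
calendar window `[window_start, window_end]` (defaults 2021-10-01 and
2022-05-26 for U09.9).  Codes before the window never index: a new code can
be applied retroactively (e.g. as a problem-list onset date), so early
dates do not reflect the date of diagnosis.  Exclusions are (1) deceased
patients and (2) patients whose index falls inside any inpatient visit
interval, because in-hospital records mix the target condition's context
with the admission's primary cause.  All interval comparisons in the
package are inclusive on both ends; in particular the analysis window is
the closed interval `[index, index + 60 days]`.  The 60-day endpoint's
inclusivity is a design choice (the convention is not externally fixed) and
is pinned by unit tests.

Events before index are never used to *exclude* a condition from the
window: a pre-existing condition recorded again after index stays in the
analysis, since chronic conditions can be exacerbated by, or recur with,
the indexed disease.  Consequently the clusters describe co-occurrence,
not causation.

Age is computed at the index date from birth date using a 365.25-day year
and binned `[0,21) [21,46) [46,66) [66,∞)`.  The bin edges follow the
analysis strata printed as `<21 / 21–45 / 46–65 / 66+`; the 365.25-day
convention can mislabel ages within a day of a bin edge, which is
irrelevant at cohort scale and acknowledged in the property test.

Percentages are rounded half-up to one decimal (`round_pct`), the
convention consistent with the headline worked examples
(9.7 = 3266/33782, 2.3 and 24.2 for 791 severe, etc.).  A zero denominator
yields an absent percentage, never 0.

Site gates: lab coverage ≥ 0.25 and valid-end-date fraction ≥ 0.75
(inclusive lower bounds), date shift ≤ 30 days (inclusive upper bound),
plus nonzero use of the index code.  Boundary inclusivity is pinned by
tests.

## Co-occurrence network and community detection

Nodes are the top-K (default 30) conditions by unique-patient count inside
the analysis window, identified by SNOMED-style display name after
collapsing ICD-10-CM synonyms through the bundled crosswalk; the index
code itself is never a node.  Ties in the ranking break lexicographically
so the node list is invariant to event order.  The edge weight
`w(i,j)` is the number of distinct patients whose window contains both
conditions — patient counts, not event-pair counts, which is the stricter
reading of "patients with both conditions".  Zero-weight edges are absent
from the graph; they carry no modularity contribution.

Weighted Newman–Girvan modularity with resolution γ:

    Q = (1/2m) Σ_ij [A_ij − γ k_i k_j / 2m] δ(c_i, c_j)

γ = 1 for all headline runs and is exposed as configuration.

* **Louvain** — two-phase greedy maximization: local single-node moves to
  the neighboring community with the largest ΔQ (ties go to the
  lowest-index community), then aggregation of communities into
  supernodes, repeated until no move improves Q.  Node visitation order is
  shuffled by the seed, making runs deterministic given the seed.  On every
  ≤ 6-node fixture in the test suite, the greedy result equals the global
  optimum found by enumerating all set partitions.
* **Girvan–Newman** — iterative removal of the maximum-edge-betweenness
  edge; betweenness uses exact weighted Brandes with edge length
  1/weight (heavier co-occurrence = closer), tie-breaking on the
  lexicographically smallest edge.  The returned partition is the
  component structure along the dendrogram with maximum modularity on the
  original graph.  On dense weighted graphs (the top-30 network is
  essentially complete) shortest-path traffic concentrates on heavy
  *within*-block hub edges, so divisive removal tends to peel singletons
  and the method often cannot beat the trivial partition — a known
  limitation of betweenness-based division on dense graphs, and one reason
  Louvain is the headline algorithm.  On sparse graphs (the bundled
  fixtures, planted sparse blocks) it recovers structure exactly.
* **Walktrap** — t-step random-walk profiles P^t (default t = 4, the
  original algorithm's default), agglomerative merging of *adjacent*
  communities by the minimum Ward-style increase
  Δσ = (1/n)·|C₁||C₂|/(|C₁|+|C₂|)·r²(C₁,C₂) with
  r²(C₁,C₂) = Σ_k (P_{C₁k} − P_{C₂k})²/d_k, cutting the merge tree at
  maximum modularity.  Isolated nodes have no walk distribution and remain
  singleton communities.

Partition agreement and stability use the adjusted Rand index
(scikit-learn's implementation; 1 = identical up to relabelling).
**Stability** is a patient bootstrap: resample patients with replacement,
rebuild the network over the same node set, re-run the algorithm, and
score ARI against the full-data reference partition.  This bootstrap/ARI
design is this package's instantiation of network-stability assessment;
the per-replicate detection seed varies so the assessment covers algorithm
seed sensitivity as well as sampling noise.

Age-stratified analysis runs top-K → network → detection independently per
stratum, so the condition lists may differ between strata; strata with
fewer than two conditions or no co-occurrence are skipped with a warning.

## Disparity analysis and disclosure control

SDoH variables are banded at the 33.3rd/66.7th linear-interpolation
percentiles of the **full reference table** (all ZIPs, not just cohort
ZIPs): low < P33.3, medium in the closed interval, high > P66.7.  The
percentile pair is configurable because the exact external convention
behind published cutpoints (e.g. 7.92/15.30 for poverty) is not stated;
tertiles are consistent with them.  Banding is scale-invariant.  Patients
map to bands by ZIP; unmatched ZIPs are "missing".

The g-test of independence is G = 2 Σ O ln(O/E) over cells with O > 0
(the x·ln x → 0 limit handles zero cells), E from the product of margins,
df = (r−1)(c−1), p from the χ² upper tail.  No continuity or Williams
correction is applied.  Post hoc per-category 2×2 comparisons are
Bonferroni-adjusted across the categories actually tested (the adjustment
scheme is a package choice).  G and Pearson's X² are asymptotically
equivalent *under independence*; the property suite verifies ≤ 2%
relative disagreement on independence-sampled tables with all cells
≥ 100.  Under strong association the two statistics legitimately diverge,
so no closeness is claimed there.  Tests are computed on raw counts;
perturbed counts exist only for display.

Disclosure control: counts in [1, 19] display as "<20"; zero cells display
as 0 (a zero discloses no individual).  When exactly one cell in a
(variable × age-group) column is suppressed, it would be derivable from
the public stratum total, so every displayed nonzero complement is shifted
by a nonzero amount in ±{1..5}, drawn once per table under the policy
seed and restricted to keep the shifted display outside [1, 19] (a
displayed 20 can only shift upward — otherwise the two policy invariants
cannot hold simultaneously).  If the only complements are zeros — which
cannot be shifted out of the banned band — the zeros are complementarily
suppressed instead.  `recoverable_cells` audits every released table by
interval arithmetic over what a policy-aware reader could deduce; the
suite requires the audit to come back empty.  Stratum totals and
one-category variables (which *are* their own margin) are treated as
public.  Displayed percentages are computed from the shifted counts.

## Procedure, medication and uptake summaries

Procedures drop encounter-only E&M codes (bundled editable list; the
canonical example is CPT 99212) and roll up to ~15 high-level categories
via a bundled code→category fixture; the published category mapping is not
public, so the fixture is a documented stand-in.  Counts are unique
patients per category per stratum; a cell is suppressed when it covers
fewer than 20 patients **or** less than 1.0% of its stratum.

New medications keep (patient, ingredient) pairs with at least one record
in the analysis window and none at any time before index (full lookback —
anti-monotone: more history can only remove drugs).  Ingredient is the
identity unit for the prior-record rule (products/doses of one ingredient
are not "new").  ATC level 3 is the 4-character prefix of the 7-character
WHO code (J01CA04 → J01C).

Uptake counts unique patients per calendar month per tracked code (U09.9
and B94.8 by default) over the full lookback range from January 2018,
zero-filled over a contiguous month range.  Patients rather than raw
events per month is a fixed, documented choice.

## Synthetic generator

The generator emulates the statistical structure the pipeline needs, with
one global seed feeding named sub-streams (persons, index, conditions,
procedures, drugs, visits, tests, sites, sdoh) so adding a table never
perturbs earlier draws; identical config + seed is byte-identical output.

* **Latent subtypes.** Each patient draws an age group (default weights
  0.07/0.34/0.41/0.18, resembling a large multi-site long-COVID cohort),
  then one latent symptom subtype from the age group's mixture.  Default
  profiles plant four subtypes on the bundled condition blocks
  (cardiopulmonary, neurological, gastrointestinal, comorbid) with
  emission probability 0.55 per own-block condition, plus a 0.03
  background rate on every condition.  Conditions are emitted
  conditionally independently given the subtype — the simplest model under
  which community detection provably recovers the blocks.  The true
  dependence structure among real long-COVID symptoms is unknown; this is
  a modeling choice, not an empirical claim.
* **Exact-count classes.** Inpatient-index, hospitalized-acute, severe and
  missing-COVID-index fractions are realized as exact rounded counts by
  seeded sampling (inpatient-index among all indexed patients; the others
  within the expected post-exclusion base cohort, matching how those
  proportions are reported).  Defaults: 8.4% inpatient index, 9.7%
  hospitalized, 24.2% of those severe, 37.2% missing COVID index.
* **Coding switch.** A configurable fraction of patients (default 25%)
  carries B94.8 placeholder events dated before the switch date (default
  2021-10-01); U09.9 index dates are uniform over the index window, so the
  monthly series shows B94.8 dominant before the switch and U09.9
  overtaking within two months after.
* **SDoH.** ZIP-level percentage variables are Gaussian with configurable
  mean/sd, clipped to [0, 100] (defaults: poverty 11±6, college 15±8,
  public insurance 18±8, unemployment 4.5±2 — plausible ACS-like
  magnitudes).  An optional skew oversamples low-poverty ZIPs for the
  cohort to plant a disparity gradient.

What passing tests show: every operation behaves correctly on data whose
ground truth is known by construction, at the documented study sizes.
What they do not show: recovery of real-data figure values (the source
records are access-restricted), realistic visit-level utilization,
within-subtype symptom correlation beyond the shared subtype, coding
variation across sites, or clinically plausible code sequences.

## Problem sizes and determinism

Default validation sizes — 36,880 patients for the attrition worked
example, 3,000 for end-to-end stratified recovery, 20 seeds for planted
2-block graphs, B = 50 bootstrap replicates, 1,000 tables for the
disclosure audit — keep the full suite and the acceptance script in the
seconds-to-minutes range on one CPU.  No stage reads wall-clock time into
results; every random draw descends from an explicit seed, and the
end-to-end driver writes per-stage manifests with config hashes and file
checksums so reruns are verifiably identical.

## Known limitations

* One known discrepancy in the reference worked examples: 12,550 of
  33,782 equals 37.147%, which rounds half-up to 37.1, while the quoted
  share is 37.2%; the package reproduces the count exactly and reports the
  arithmetically correct percentage.
* Girvan–Newman is unreliable on dense weighted networks (see above).
* The disclosure audit models a reader using column totals and bounded
  shifts; it does not model cross-variable or cross-release linkage.
* The ICD→SNOMED crosswalk, procedure categories, E&M exclusion list and
  ATC map are small editable fixtures, not terminology services.
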