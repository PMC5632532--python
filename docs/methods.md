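# Methods

`clonepop` analyses diploid multilocus microsatellite genotypes from
partially clonal organisms. This note documents the statistical model
behind every stage, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions.

## Data model

A `GenotypeTable` is an individuals × loci matrix of unordered diploid
allele pairs (integer fragment sizes in bp; a homozygote repeats the
value), with a population label per individual. A missing call is the
pair (0, 0). Half-missing calls — one allele scored, one not — carry no
usable genotype and are conservatively normalised to fully missing at
construction. GenAlEx-style CSV (two columns per locus, numeric header
row) and a tidy long format are supported; `read ∘ write` is the identity
on valid tables.

## Clone discrimination

**MLG assignment.** Two ramets share a multilocus genotype (MLG) iff
their unordered allele pairs are identical at every locus. A missing
call matches nothing, including another missing call, so any individual
with missing data is a singleton MLG. This "missing values are different
alleles" rule slightly overestimates genotype numbers, which is why the
pipeline keeps only individuals missing at most one locus (configurable,
default 1) and follows MLG assignment with lineage collapsing.

**Allele distance.** Between two genotypes, each locus contributes
`2 − |multiset intersection|` of the two pairs (0, 1 or 2). Missing vs
non-missing contributes 2; missing vs missing contributes 0, so a pair of
genotypes identical except for a shared failed locus can still merge into
one lineage even though the MLG rule kept them apart. Allele identity is
exact integer equality — no ±1 bp stutter binning, which belongs to
fragment scoring upstream of this package.

**MLL collapsing.** MLGs at allele distance ≤ 1 (configurable) are merged
into multilocus lineages (MLLs) — the working estimate of genets, built to
absorb single scoring errors and somatic mutations. Merging is
single-linkage: MLLs are connected components of the threshold graph, so
transitive chains collapse (logged when they occur). Labels are assigned
deterministically by smallest member MLG id.

**P_sex.** For an MLG observed `n` times among `N` samples, `P_sex` is the
probability that its repeats arose from independent sexual events. The
genotype probability is
`p_gen = Π_l P(genotype at l)`, with
`P(aa) = f_a² + f_a(1−f_a)F_IS` and `P(ab) = 2 f_a f_b (1−F_IS)`
(Hardy–Weinberg when `F_IS = 0`). Under the default Parks–Werth
convention, `P_sex = Σ_{i≥n−1} C(N−1, i) p_gen^i (1−p_gen)^{N−1−i}`: the
focal sample is fixed and at least `n−1` of the remaining `N−1` draws must
reproduce the genotype. The alternative `binomial-n` convention counts at
least `n` successes among all `N` draws; both are exposed because the
literature uses both. Repeats with `P_sex < 0.001` (default) are treated
as ramets of one genet.

Allele frequencies for `p_gen` use one copy per MLG by default
(`per_genet`), so a dominant clone cannot inflate its own alleles'
frequencies and make its repeats look sexually plausible. A `round_robin`
scheme (frequencies at locus *l* from genotypes unique over all loci
except *l*) and a naive `per_ramet` scheme are available. The `F_IS` fed
into `p_gen` defaults to the population's multilocus `1 − Ho/Hs` over
unique MLGs, floored at 0: clonal populations typically show heterozygote
excess (negative F_IS), and a negative correction would push homozygote
genotype probabilities below their Hardy–Weinberg value, making P_sex
anti-conservative.

## Clonal structure indices

* **Richness** `R = (G−1)/(N−1)`, with `G` the number of MLLs: 0 when the
  sample is one clone, 1 when every ramet is a distinct genet.
* **Simpson's complement** `D = 1 − Σ n_i(n_i−1)/(N(N−1))`: the
  probability that two distinct sampled ramets belong to different genets
  (it equals the exhaustive pair-enumeration value, which the tests check
  for every clone-size partition up to N = 12).
* **Evenness** `V = (D − D_min)/(D_max − D_min)`, where
  `D_max = N(G−1)/(G(N−1))` (equal clone sizes) and
  `D_min = 1 − (N−G+1)(N−G)/(N(N−1))` (one dominant clone, all others
  singletons). `V` is undefined (NaN) for `G = 1`. When `D` equals a bound
  to within 1e−12 the value is reported as exact 0 or 1: evaluating the
  ratio directly at the dominant-clone configuration produces float noise
  of order 1e−16 (as published tables sometimes show), which is
  scientifically 0.
* **Pareto slope.** The clone-size distribution's power-law slope `β` is
  the negated OLS slope of `log N_{≥x}` on `log x`, evaluated at every
  observed clone size (a Zipf plot, ties repeated). Evaluating once per
  distinct size instead gives the sparse extreme tail as much weight as
  the body and biases the slope badly for heavy-tailed samples (mean
  error ≈ 0.5 at β = 1.5, n = 500); the rank-based fit recovers β = 1.5
  with SD ≈ 0.09 under the same conditions. At least 3 distinct sizes are
  required, otherwise NaN.

## Diversity on unique lineages

All diversity and differentiation statistics consume one representative
per MLL (the member with fewest missing loci, ties broken by input
order): clonal replication otherwise pseudo-replicates genotypes.

* `Na`: distinct alleles; `Ho`: fraction heterozygous among scored
  genets.
* `He`: unbiased expected heterozygosity (Nei 1978),
  `(2n/(2n−1))(1 − Σ f_i²)`.
* `F_IS`: primary definition `1 − Ho/Hs` with the *plug-in* gene
  diversity `Hs = 1 − Σ f_i²`. An all-heterozygote two-allele locus gives
  exactly −1.00 under this definition (matching how such loci are
  conventionally reported) but −(n−1)/n under the unbiased `He`; both
  conventions circulate, so the Weir–Cockerham small-sample `f` is
  reported alongside. `F_IS` is NaN at monomorphic loci.
* `AR`: allelic richness rarefied to `m` gene copies by the
  hypergeometric expectation `Σ_i [1 − C(2n−c_i, m)/C(2n, m)]`; the
  default `m` is the smallest number of scored gene copies over all
  (population, locus) cells, so every cell is rarefiable. AR is monotone
  in `m` and equals `Na` at the full sample.
* `Ap`: alleles absent from every other population at that locus.
* Multilocus values are unweighted means over retained loci (and `A`,
  `Ap` totals).

## Locus quality control

* **Hardy–Weinberg.** Permutation test in the allele-shuffling style:
  the population's scored gene copies at the locus are pooled and
  randomly re-paired; the two-sided statistic is `|F_IS|` (allele counts
  are permutation-invariant, so only `Ho` varies). p-values use the
  add-one smoothing `(1 + hits)/(n_perm + 1)`.
* **Linkage disequilibrium.** The statistic is the G log-likelihood of
  the two-locus genotype contingency table; the null permutes one locus's
  genotypes among individuals. Both members must be genotypically
  polymorphic.
* **Null alleles.** Brookfield estimator 1, `r = (He − Ho)/(1 + He)`,
  flagged when `r > 0.1` *and* a one-sided binomial test of the observed
  homozygote count against its Hardy–Weinberg expectation is significant
  at 0.05. A polymorphic locus scored only as homozygotes is always
  flagged. Note the estimator's known downward bias under homozygote
  masking: as diversity grows it plateaus at `q/(1+q)` for true null
  frequency `q`, so recovery to ±0.1 holds for high-diversity loci but
  the point estimate under-reports strong nulls (≈ 0.22 recovered at
  q = 0.3).
* In the pipeline, QC tests run per population on unique MLGs; null
  drops are applied first and linkage is then assessed among survivors
  (both loci of a significant pair are dropped, matching how linked pairs
  are usually removed when neither member can be blamed). Linkage p-values
  are Bonferroni-corrected within the family of tested pairs ×
  populations. The missing-data filter runs after locus QC and before
  clone discrimination, so a dropped locus cannot cost an individual its
  place in the sample.

## Differentiation

* **F_ST** is estimated as Weir & Cockerham's (1984) θ — the
  variance-components estimator most population-genetics software
  computes under the name F_ST — per allele and locus, with
  `θ = Σa / Σ(a+b+c)`. Demes with fewer than two scored genets at a locus
  contribute nothing for that locus.
* **G_ST family** uses Nei & Chesser (1983) small-sample corrections for
  `H_S` and `H_T` (harmonic-mean sample size), then
  `G_ST = (H_T − H_S)/H_T`, Hedrick's
  `G'_ST = G_ST (k−1+H_S)/((k−1)(1−H_S))`, and Meirmans & Hedrick's
  `G''_ST = k(H_T − H_S)/((k·H_T − H_S)(1−H_S))`. `G''_ST` equals 1
  exactly when populations share no alleles — its design property for
  polymorphic microsatellites — and the parametric ordering
  `G''_ST ≥ G'_ST ≥ G_ST ≥ 0` holds for any valid frequency configuration
  (exposed via `gst_from_frequencies`). The sample-corrected estimators
  carry an O(1/n) residual around 0 that the `1/(1−H_S)` rescaling
  amplifies, so "≈ 0 for identical populations" is asserted at n = 200.
* **Permutation p-values** shuffle genets (never ramets) between the two
  populations with sizes preserved; one-sided, add-one smoothed.

## Synthetic data generator

Per population, allele frequencies diverge from ancestral frequencies
under the Balding–Nichols model, `p_pop ~ Dirichlet(p_anc (1−F)/F)`;
genet genotypes are drawn with inbreeding `f_is_sim` (probability of an
autozygous locus); genets are replicated into ramets by a clone-size law
(`fixed_counts`, `dominant`, `pareto`, `uniform`); and observation noise
is applied in order: null-allele masking at the genet level (a carrier
renders as an apparent homozygote of its visible allele, a null
homozygote as a missing call — the Micro-Checker model), a per-ramet
scoring error that shifts one random allele by one repeat unit (creating
the one-allele MLG pairs lineage collapsing must absorb), then random
missing calls. Allele indices map to plausible fragment sizes
(`100 + 24·locus + 3·(index+1)`), so emitted files look like
fragment-analysis exports with one contiguous size range per locus.
Everything is deterministic under the config seed and recorded in a
`TruthRecord`.

`make_paper_like_fixture` emits the four study-shaped populations this
package's validation is built around: 23 ramets/13 genets (dominant clone
of 4), 24/6 (dominant 19), 24/5 (dominant 14) and 24/3 (dominant 22),
two species × two sites, with sites of a species sharing loci and
ancestral frequencies (divergence F = 0.10 — a realistic within-species,
between-site value that yields the weak, marginally non-significant
structure such surveys report). Genets are redrawn until pairwise allele
distances are ≥ 3, which makes clone discrimination identifiable: an
injected one-allele slip stays closer to its own genet than to any other.
The second species' tables carry exactly the deterministic slips (2 and
3) that split its lineages into 7 MLG/5 MLL and 6 MLG/3 MLL.

What the generator does **not** emulate: coalescent ancestry and linkage,
stepwise-mutation dynamics over generations, spatial clonal architecture,
allele-size homoplasy, and genotyping artefacts beyond single-repeat
slips. Tests passing on this generator therefore validate the estimators
and the pipeline's bookkeeping under the stated sampling model — they do
not certify behaviour on data violating it (e.g. strong stutter, severe
dropout).

## Validation problem sizes

The test suite's distribution-level checks use sizes chosen to make the
checks informative at desk scale: type-I error of the HWE, linkage and
differentiation permutation tests over 400 null replicates (n = 500
genets × 8 alleles; 200 × 4; and 2 × 25 × 5 respectively; 199
permutations each, rejection at p ≤ 0.05, giving an exactly attainable
5% level); P_sex against a 10⁶-draw binomial simulation; θ recovery as
the mean over 200 Balding–Nichols replicates (F = 0.10, 10 loci, 100
genets per population); Simpson's D exhaustively for all clone-size
partitions with N ≤ 12.

## Known limitations

* P_sex treats loci as independent (no linkage) and uses point estimates
  of allele frequencies; with few polymorphic loci it is approximate.
* Brookfield-1's downward bias (above) means the null-allele *point
  estimate* should not be read as the null frequency when diversity is
  modest; the flag is the reliable output.
* The G-statistic LD test uses genotype (not gametic-phase) association,
  appropriate for diploid data of unknown phase but less powerful than
  likelihood methods using phase.
* With only two populations, θ estimates deme-pair divergence with wide
  sampling variance across loci; permutation p-values, not the point
  estimate, carry the inference.
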