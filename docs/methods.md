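# Methods

## Problem and model

`satclone` analyses clonal diversity in diploid hybrid parthenogens scored
at microsatellite loci. The motivating system is the Caucasian rock lizard
*Darevskia unisexualis*, an all-female species formed by hybridization of
female *D. raddei nairensis* with male *D. valentini*: every individual
carries, at each locus, one allele inherited from each parental species,
and daughters are their mother's clones apart from new mutation.

An allele is modelled as (i) the lengths of its variable repeat tracts and
(ii) a profile of flanking single-nucleotide / indel sites, with the gap
treated as an ordinary fifth state. Allele identity is structural:
catalog labels never influence any computation. Two kinds of flanking
sites matter:

* **diagnostic sites** — states observed in the maternal catalog are
  disjoint from those in the paternal catalog. Because point mutations at
  these sites are far rarer than repeat slippage, they are treated as
  stable markers of parental origin.
* **other polymorphic sites** — indel/SNP variation that, together with
  repeat counts, distinguishes alleles within a species.

## Pipeline

1. **Phasing** (`phasing.assign_allele`, `phase_cohort`). Each allele is
   assigned a parental side by majority vote over diagnostic sites; ties
   or uninformative profiles are left unassigned. Repeat lengths are
   deliberately excluded from the side call — repeats mutate, flanking
   diagnostic sites do not. Genotypes that do not split into one maternal
   plus one paternal allele are reported as phase failures and excluded
   from clone calling but retained in allele counts (conservative: a
   failure removes an individual from the clone census without discarding
   its observed alleles). Alleles absent from both catalogs but
   side-assignable are kept and flagged `repeat_mismatch` /
   `snp_mismatch` / `both_mismatch` against the nearest same-side catalog
   allele (ranked by SNP Hamming distance plus repeat L1 distance).
2. **Single-origin test** (`single_origin_test`). Individuals are grouped
   by the tuple, over loci and sides, of their diagnostic-site states.
   One class is consistent with a single founding hybridization; *k*
   classes require at least *k* origins. This is a combinatorial
   classification, not a likelihood test: it cannot reject a shared origin
   for individuals with identical combinations.
3. **Clone calling** (`clones.call_clones`). Clones are equivalence
   classes under exact equality of the phased multilocus genotype.
   Canonical names C1, C2, … follow descending total count; ties break by
   lexicographic composition order (locus order fixed; maternal then
   paternal tract vectors then SNP profiles). Published label sets can be
   restored via a composition → name mapping; unmatched clones get a
   distinct `*` suffix. Clonal diversity per population is 100·k/n.
4. **Diversity statistics** (`popstats`). Allelic richness is
   standardized by hypergeometric rarefaction
   R_S(g) = Σᵢ [1 − C(2N−Nᵢ, g)/C(2N, g)], computed in exact rational
   arithmetic; `g` defaults per locus to the smallest 2N among the
   populations compared (g = 6 for the bundled cohort, set by the
   three-individual Sevan sample). Gene diversity uses Nei's unbiased
   estimator He = (2n/(2n−1))(1 − Σpᵢ²); the plain 1 − Σpᵢ² is also
   exposed. Group comparisons of richness use a two-sided
   label-permutation test, p = (1 + #{|Δ*| ≥ |Δ|})/(B + 1), because
   sample sizes per population are tiny and the null of exchangeable
   labels is the only defensible one.
5. **Clone network** (`network`). Clones are coded into a character
   matrix (one column per locus/side/tract, one per flanking site;
   constant columns dropped by default — distances are unaffected).
   Distances count repeat differences: `event` mode counts tracts that
   changed (one contiguous length change = one mutational event, the
   default), `unit` mode sums absolute repeat-count differences.
   Flanking-site differences are *excluded* from distances by default:
   in these data every site difference is linked to an allele exchange
   already visible in the repeat columns, and the published network for
   this system was computed from repeat differences only; `include_sites=True`
   restores a literal fifth-state treatment. The network is a
   tie-retaining minimum spanning network: pairs are processed in
   non-decreasing distance and every edge joining two different components
   at a distance level is added before the components merge — equivalently
   the union of all minimum spanning trees, which the tests verify by
   exhaustive enumeration. An optional connection limit truncates long
   edges, leaving subnetworks; the full 95% parsimony-probability limit
   computation of classic statistical-parsimony software is not
   re-derived. The network is unrooted; `ancestral_candidate` only ranks
   clones by (populations occupied, total count, degree) and reports ties.

## Synthetic-data generator

`simulate` produces cohorts with exactly the structure the analysis
assumes, plus ground truth for recovery tests:

* Parental catalogs with uniform tract lengths on `tract_length_range`
  (default 5–15 repeats, the typical range of tetranucleotide alleles) and
  diagnostic states drawn from disjoint per-species alphabets (maternal
  {A, C}, paternal {G, T}); allele *j*'s diagnostic combination is the
  binary expansion of *j*, so low-index alleles are pairwise
  distinguishable. Panels are diploid Hardy–Weinberg draws seeded with
  one copy of every catalog allele, so a panel always spans its catalog.
* `n_origins` founders each pair one maternal and one paternal catalog
  allele per locus; with `origin_distinguishing` founder *i* carries
  maternal allele *i* everywhere, making origins separable by diagnostic
  combination.
* Apomictic Wright–Fisher propagation within demes: each daughter copies
  her mother; a locus mutates with probability μ per generation under a
  symmetric single-step model (±1 repeat on one uniformly chosen side and
  tract, reflecting at length 1). μ defaults to 10⁻³, a mid-range
  microsatellite slippage rate. Migration is an island model: marked
  individuals are shuffled uniformly across demes, conserving deme sizes.
  Founders seed demes round-robin, so with `n_demes == n_origins` each
  deme starts as a pure founder lineage and no origin can be lost to
  drift — the configuration used for origin-recovery tests.
* Defaults (7 demes of 100, 50 generations, 15 sampled per deme) echo the
  scale of the motivating field survey; generation counts are free
  parameters, since the founding events cannot be dated from these data.

What the simulator does **not** emulate: triploidy, backcrossing,
recombination, genotyping error, multi-step repeat mutations, indel
mutation in flanking regions, or real geography. Passing recovery tests
therefore show the pipeline is correct *under its own assumptions* — they
do not validate those assumptions against real populations.

## Bundled reference dataset

`datasets.load_unisexualis_dataset()` reconstructs the 109-individual,
seven-population *D. unisexualis* survey (12 clones, four loci) together
with parental panels. The published material gives clone compositions,
per-population counts and the repeat-tract coding matrix; it does not
print the flanking-site alphabet. The dataset therefore assigns:

* one diagnostic site per locus with two arbitrary distinct states (C
  maternal / T paternal), constant across all 109 individuals — only the
  identity of combinations matters downstream;
* the six polymorphic indel sites attributed to alleles in the unique way
  consistent with the published per-clone coding: site 1 → Du215 paternal
  allele 2; sites 2–4 → Du281 maternal alleles 1–3; site 5 → Du281
  paternal alleles 4/5; site 6 → Du47G paternal allele 2. Under this
  attribution Du281 maternal alleles 4 and 5 (and paternal 4 and 5) are
  structurally identical — exactly then the locus shows six distinct
  alleles and the panel 14 in total, matching the published counts, so the
  labels are read as population-of-origin bookkeeping rather than distinct
  sequences.
* invariant alleles take the published constant tract lengths; they never
  influence distances or clone identity.

One reproduction note: the published frequency of the three-individual
clone C6 is a truncation (3/109 = 0.0275); this package rounds half-up and
prints 0.028, while all other clone frequencies match the published
three-decimal values.

## Numerical and degenerate-input conventions

* Percentages half-up to 1 d.p., frequencies to 3 d.p.; exact `Fraction`
  values retained alongside every rounded figure.
* Rarefaction and He are exact rationals until final float conversion.
* Permutation p-values are seeded and reproducible; B ≥ 999 enforced.
* Empty populations, g outside [1, 2N], unknown loci, duplicate
  (individual, locus) rows, and mixed-species tables raise typed errors;
  phase failures and individuals missing a locus are reported data.
* Distance level ties in the network are retained as parallel
  equal-length connections; nothing is broken arbitrarily.

## Problem sizes used in the test suite

Simulation-based tests use 2–4 loci, demes of 15–40 individuals, 4–15
generations and 50–200 replicate seeds; the random-walk oracle uses one
locus with 400 individuals over 40 generations and 25 replicates; the
exhaustive spanning-tree oracle covers all networks of up to 7 clones over
200 random matrices. These sizes give stable verdicts for every property
tested while keeping the whole suite fast on a single CPU.

## Known limitations

* Side assignment is a deterministic vote, not probabilistic ancestry
  inference; it cannot express uncertainty for conflicting profiles.
* The single-origin test is blind to independent origins that happen to
  combine identical diagnostic haplotypes.
* Clone calling tolerates no genotyping error: one miscalled repeat makes
  a new clone.
* `event`-mode distances treat a 2-repeat jump as one event; `unit` mode
  as two. Both are provided because the underlying mutation process
  cannot be identified from end-point data.
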