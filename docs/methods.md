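# Methods

This note documents the models and procedures implemented in `kindisperse`,
the defaults they use, and the choices made where the design was genuinely
open.

## Relatedness estimation

Dyadic relatedness is estimated with moment estimators computed as ratios
of locus-wise sums, over the loci typed in both members of a dyad:

* **Queller–Goodnight** (default): for reference genotype (a, b) and
  proband (c, d) at one locus, the numerator is
  ½(S<sub>ac</sub>+S<sub>ad</sub>+S<sub>bc</sub>+S<sub>bd</sub>) − p<sub>a</sub> − p<sub>b</sub>
  and the denominator 1 + S<sub>ab</sub> − p<sub>a</sub> − p<sub>b</sub>
  (S = allele-identity indicator, p = population frequency); numerators and
  denominators are summed over loci and over both orderings of the dyad
  before dividing. This symmetric ratio-of-sums form is the standard
  multilocus estimator.
* **Lynch–Ritland** as the pluggable alternative, with the published
  locus information weights and the arithmetic mean of the two directed
  estimates. Both estimators were chosen because they are deterministic,
  auditable closed forms; the package deliberately contains no
  likelihood/MCMC relatedness machinery.

Reference allele frequencies are counted from all genotyped individuals,
kin included, with no iterative kin correction — the bias this introduces
is small at population scale and is exercised by the recovery tests (mean
estimates for unrelated / half-sib / parent–offspring / full-sib dyads fall
within ±0.05 of 0 / 0.25 / 0.5 / 0.5 at 20 loci).

Dyads sharing fewer than `min_shared_loci` (default 10) typed loci carry no
estimate. Sampling noise at 20 microsatellite loci is substantial: the
per-dyad standard deviation is ≈ 0.1, which matters for threshold
calibration (below).

## Close-kin threshold

`calibrate_threshold` implements the rule "the threshold is the lowest R
among known parent–offspring and full-sibling dyads", and reports the
maximum known non-kin R and an `overlap` flag when the two calibration sets
cannot be separated. Ties are strict: a dyad with R exactly at the
threshold is **not** a genetic tie.

With moment estimators at 20 loci, the minimum over ~55 known-kin dyads is
an extreme order statistic of a noisy distribution and lands anywhere
between about 0.2 and 0.35 depending on the draw; thresholds that low admit
second-degree kin (expected R = 0.25) wholesale and degrade the network
classifier. The pipeline therefore defaults to a **fixed** threshold of
0.43 — the value at which close kin separate cleanly from non-kin in
well-calibrated field panels — while keeping calibration available
(`threshold_source: calibrated`) and always reporting the calibrated value
and its overlap flag alongside.

## Dispersal-status classification

For each focal animal passing the per-individual loci filter (default ≥ 10
typed loci), close kin are counted per group of residence, excluding the
focal's co-residing offspring from the current-group count (a parent may
have immigrated before the offspring was born, so co-residing offspring
carry no information about the parent's own natal status; offspring
residing elsewhere still count toward their group, a documented asymmetry
of the published rule set).

* current-group count strictly below some other group ⇒ `likely_immigrant`;
* strictly above every other group ⇒ `likely_natal`;
* equal counts are resolved by the status of the tied kin: all
  current-group kin natal and all tied-group kin immigrant ⇒ natal, the
  mirror image ⇒ immigrant. "Status" means known status where available,
  otherwise the classifier's own output, swept to a fixed point.
  Assignments are never revised once made, so the fixed point is
  order-independent (tested with randomized sweep orders). Ties among three
  or more groups, and cycles that make no progress, end `unknown`
  (`unresolved`).

Known-status animals are never reassigned in normal operation; for accuracy
evaluation the classifier is run over them with their own status hidden
(`reassign_known=True`), and the confusion summary reports correct /
incorrect / unassigned percentages over the known-status set, optionally
restricted to animals with at least one genetic tie.

Known limitation: an animal whose only close kin are its own offspring
(e.g. a founding female) is systematically pushed toward
`likely_immigrant` once any offspring disperses, because its co-residing
offspring are excluded while the dispersed ones count elsewhere. This is a
property of the published rules, preserved deliberately.

## Proximity

The score of dyad (A, B) is the arithmetic mean of the two directed
proportions of each member's retained scans in which the other was within
one meter. Scans flagged "not all identified" are dropped first; animals
with fewer than `min_scans` (default 10 — chosen below observed per-animal
scan minima so no real animal is silently dropped, but high enough for
stable proportions) retained scans carry no scores. Scores exist only for
co-resident dyads; cross-group dyads have none, and animals present for
part of the window keep their scans without time-weighting.

## Resampling nulls

Within-group null: the observed mean of a dyad class (FF/MM/MF) in a group
is compared with means of equally many dyads drawn **without replacement,
as units** from all dyads of that group (an individual may appear in
several drawn dyads), over 10,000 iterations by default. Confidence bounds
are equal-tailed percentile intervals (2.5/97.5 and 0.5/99.5, linear
interpolation; at 10,000 iterations the difference from raw order
statistics is below reporting precision). Results carry a direction
(above/below/inside) at each level, since both directions are
scientifically meaningful (e.g. female–female above, male–female below).
Empty target classes yield no result; single-dyad groups are flagged
degenerate.

Population-level null: the observed statistic is the mean over groups of
each group's mean same-sex dyadic R; each iteration replaces every real
group with the same number of same-sex individuals drawn without
replacement from the pooled population, draws being independent across
simulated groups within an iteration (no global partition is imposed; the
alternative would change little at these pool sizes and is easy to add).

Calibration: with exchangeable synthetic scan data the FF class falls
outside the 95% interval in ≈ 5% of replicate groups (checked at 200
replicates), and on groups small enough to enumerate the Monte-Carlo null
matches exhaustive subset enumeration within Monte-Carlo error.

## Tenure statistics

Kaplan–Meier product-limit curves are fit per context (natal vs breeding
group) and sex, with right-censoring; the median is the smallest observed
time at which survival reaches 0.5 or below, undefined (None) when fewer
than half the stratum experienced the event. Censorings tied with events at
the same time are processed after the events (standard convention). The
log-rank test compares the two sexes. Sex-bias count tests use expected
frequencies equal to total events times each sex's share of the population:
the 1-df chi-square applies Yates' |O−E|−0.5 correction (capped at zero),
and Fisher's exact test evaluates the 2×2 sex-by-outcome table two-sided by
the point-probability rule. Both the corrected and uncorrected chi-square
statistics are reported, because published emigration statistics of this
kind are sometimes computed against time-varying denominators that the
printed counts alone cannot reconstruct; the package makes no attempt to
reproduce such values.

## Synthetic populations

The generator emulates a mid-sized fragmented forest population: 8 founding
groups of 7 founders each (alternating sexes), two non-overlapping breeding
generations at a 96-month interval, everyone surviving to the study end, so
the default population holds ~190 adults and subadults across ~11 groups
(fissions add groups). Age classes follow the study species' cutoffs
(males adult > 7 y, females > 5 y, subadult from 3 y); time is months
throughout.

* **Male dispersal is obligate**: every male leaves his birth group at a
  uniform age between 37 months and `male_dispersal_age_months` (default
  84), to a uniformly chosen other group; a redistribution step guarantees
  every group at least one prospective sire.
* **Female dispersal is facultative**: each female disperses with
  probability `female_dispersal_prob` (default 0.5) at a uniform age
  between 48 and 72 months; with probability `parallel_dispersal_prob`
  (default 0.5) she takes her co-resident sisters and daughters along as a
  cohort to the same destination.
* **Fission** splits a group along matrilines (each matriline wholly to one
  daughter group) with probability 0.1 per group per generation.
* **Genotypes** are Mendelian at 20 loci of 8 possible alleles, founder
  frequencies drawn once per locus from a symmetric Dirichlet
  (concentration 1.0, expected heterozygosity ≈ 0.78); missingness (default
  5% per individual × locus) is applied last, after inheritance.
* **Known status** is revealed for a random half of the animals
  (`status_known_prob`), emulating the subset whose immigration or
  philopatry was directly observed.
* Each breeding female produces two offspring with fathers drawn uniformly
  from her group's co-resident males of her own generation, giving
  paternal half-siblings within groups and full siblings in about a
  quarter of families.

What the generator does **not** model — and what passing tests therefore do
not establish for real data: mortality (censoring is purely administrative),
overlapping or continuous breeding, extra-group paternity, genotyping error
beyond missingness, spatial structure of home ranges, and observation
effort varying across groups. The generator's defaults are the package's
study conditions, not estimates of any real population's parameters; in
particular the true female dispersal rate of any field population is
unknown, and these knobs are calibration dials for validation, not
inferences.

Scan simulation is an exchangeable null plus optional class effects: every
co-group member is within one meter of the focal independently with
probability `base_rate` (default 0.03, giving realistic proximity scores of
a few percent), plus `assortment_effect` for female–female dyads (or
per-class effects), with per-dyad overrides for constructing fixtures.

## Numerical and degenerate-input choices

* All randomness flows from `numpy.random.default_rng` seeds; the pipeline
  derives per-stage sub-seeds from one master seed via `SeedSequence` and
  records them, with SHA-256 digests of every output, in a manifest —
  reruns are byte-identical.
* Estimator denominators that vanish (monomorphic or uninformative loci)
  drop out of the sums; a dyad whose total denominator is zero carries no
  estimate.
* Dyads without R estimates are "unevaluable" for tie classification and
  are reported separately rather than treated as non-kin.
* The loci filters (`min_shared_loci`, `min_loci_typed`) default to 10,
  matching the common "more than 10 of 20 loci" reporting filter; both are
  exposed.
* Group-summary labels use explicit cutoffs on the proportion of natal
  adult females (≥ 2/3 philopatric, ≤ 1/3 dispersed, facultative between),
  since verbal labels need numeric definitions to be computable; the
  kin-based and bonded flags are exactly the 95%-level significance of the
  within-group female–female relatedness and proximity nulls, with no
  recomputation in the report layer.

## Problem sizes used in validation

The test suite and the acceptance script run the full pipeline on the
default ~190-animal population, 500 dyads per relationship category for
estimator recovery, 200 replicate groups for type-I calibration, and
10,000-iteration nulls checked against exhaustive enumeration on groups
with at most 12 dyads — sizes chosen so each statistical check has
adequate resolution while the whole suite completes in well under a minute.
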