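# Methods

`orphanaudit` audits the possible origins of *orphan* transcripts — sequences
in an EST collection with no detectable homology to reference databases — by
partitioning them among four explanations: poor sequence quality, assembly
failure, lack of function, and taxonomic isolation compounded by reference
incompleteness. This note records the models, the tunable parameters, the
numerical conventions, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Sequence quality (ORF metrics)

An ORF is defined **stop-to-stop**: the longest maximal stop-free in-frame
interval over the searched frames, with start-codon presence reported
separately (an in-frame ATG anywhere inside the interval). This separates two
distinct quality signals — a short coding interval versus a truncated 5' end
that lost its start codon — which an ATG-to-stop definition would conflate.

* Default frame set: the three forward frames, because directionally cloned,
  5'-sequenced cDNA reads carry the coding strand; `frames=SIX_FRAMES`
  searches both strands.
* Ties are broken by lower frame number, then smaller start. Coordinates are
  0-based half-open on the read everywhere; 1-based conversion happens only
  at report boundaries.
* Codons containing N count as neither stop nor start. GC content is
  100·(G+C)/(A+C+G+T) with N excluded from the denominator; an all-N sequence
  has undefined GC and raises.
* Group comparisons use Welch's unequal-variance t-test with
  Welch–Satterthwaite degrees of freedom (scipy's implementation, cross-checked
  in the tests against a hand-computed closed form and a type-I-error
  calibration at α = 0.05).

## Assembly failure rate

Gene families that are single-copy in **every** reference species should
appear once in the focal assembly. With `n` matched single-copy families of
which `m` are multi-copy in the focal set, those `m` families together
holding `s` focal sequences, the failure rate is the product of two
proportions:

    failure_rate = (m / n) · (m / s)

the fraction of families affected times the fraction of the inflated
sequence set that corresponds to real genes. Applied to the unique-sequence
total `U`, the discount is `round(U · failure_rate)` with **round half away
from zero**, and the adjusted count is `U` minus the discount, so
adjusted + discounted = original exactly. Family assignment uses the best
hit per query: lowest e-value, then highest bit score, then lexicographically
smallest subject id.

The audit's headline "redundancy"/"gene discovery" summary admits two
candidate ratios (contigs/reads and unique/reads); the module reports
`discovery_rate = unique/reads` — the definition validated by the
quality-assurance sub-assembly worked example (787/796 → 99%) — and carries
both candidates in its output notes rather than asserting either.

## Homology partitioning and the completeness correction

Hits are kept when `e_value ≤ 1e-5` **and** `aligned_length ≥ 33` residues,
both boundaries inclusive. A query is annotated against a dataset when at
least one hit survives; the partition is computed over an explicit query
universe so unmatched queries appear, and the cross-dataset union counts
each query once. Best-hit semantics (same tie-break as above) are used for
e-value spectra and taxon breakdowns; presence/absence per dataset is
identical under any-hit and best-hit semantics.

A reference dataset that fails to match even its own species' transcripts at
rate `1 − p_intra` (the intraspecific matching rate, a proxy for
fragmentation/incompleteness) will also fail to match genuinely homologous
foreign queries. The correction discards that share of the non-matches from
the denominator:

    discarded = n_nomatch · (1 − p_intra)
    corrected = n_match / (n_total − discarded)

The corrected fraction is always ≥ the raw fraction, with equality only at
`p_intra = 1`. **Known limitation:** this correction is first-order only.
Under the generative model in which a fraction `f` of queries have true
homologs and the reference detects each with probability `c = p_intra`,
raw matching converges to `f·c` but the corrected estimate converges to
`f / (1 + f(1 − c))`, an underestimate with relative bias ≈ `f(1 − c)`
(about 9% relative at `f = 0.29`, `c = 0.66`). Exact recovery would require
discarding `(1 − c)` of *all* queries, not only of the non-matching ones;
the implemented form is the one whose corrected values reproduce the
published worked examples, and the residual bias is visible in the
synthetic-recovery analysis (05_homology_partition.py).

## Expression support

Arrays carry random probes with no genomic target; their per-condition
intensity distribution is the empirical null. Per condition, the threshold
is the empirical `q`-quantile (default 0.995, linear interpolation between
order statistics) of the random-probe intensities, giving each single call
an empirical per-test false-positive rate of `1 − q`. This is the literal
construction of the design's "0.5% false discovery" threshold and is a
per-test rate, not a Benjamini–Hochberg FDR; outputs label it accordingly.

A target's per-condition score is the **median** of its probes (a single
probe is its own median); it is *expressed* when the median **strictly**
exceeds the threshold (a value exactly at the threshold is not expressed —
the null construction places 0.5% of nulls strictly above), and *functional*
when expressed in ≥ `min_conditions` conditions (default 2 of 12, the
inversion of "no evidence of expression in 11 or 12 conditions").
Thresholds are computed per condition column of the supplied matrix; if
replicate arrays should have separate nulls, supply them as separate
condition columns. Fewer than 200 null values triggers a warning rather than
an error.

Note that with multiple probes per target the null distribution of the
*median* is tighter than that of a single probe, so the realized per-target
false-call rate on pure null data is far below `1 − q`; the calibration
property (call rate ≈ `1 − q`) holds for single-probe targets and for the
random probes themselves.

## Gene-family exclusivity

A family is exclusive to a focal species set when present in ≥ 1 focal
species and absent from every non-focal species. The observed count is
compared with exclusive counts of random same-size species combinations
(default 30 draws of 5): combinations are drawn uniformly without
replacement *within* a draw and may repeat across draws (`distinct=True`
forces all-different; exact enumeration is available for small matrices and
is what the resampler must reproduce when it covers all combinations). The
null summary uses the sample (n−1) SD. By default the observed focal
combination itself is excluded from the null draw; a flag includes it. A
zero null SD makes the z-score undefined (reported as such) rather than
infinite.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of a `SimConfig` (seed included): same
config, byte-identical outputs. Identifier universes are shared across
generators through dedicated seed streams, so the EST set, hit table and
probe matrix of one config are mutually consistent.

Defaults are the conditions of a normalized whole-organism Sanger EST
survey of an understudied arthropod:

| parameter | default | meaning |
|---|---|---|
| `n_ests` | 14,310 | reads in the collection |
| `orf_length_mean` / `_sd` | 339.9 / 120 nt | planted ORF length, annotated group |
| `orf_length_mean_unannotated` | 183.4 nt | planted ORF length, unannotated group |
| `gc_annotated` / `gc_unannotated` | 0.500 / 0.452 | GC weight of random draws per group |
| `frac_no_start` | 0.04 | transcripts whose planted ORF lacks ATG |
| `redundancy` | 0.12 | reads duplicating an existing transcript |
| `true_match_frac` | 0.29 | transcripts with a true reference homolog |
| `reference_completeness` | 0.662 | detection probability per true homolog |
| `decoy_fraction` | 0.10 | hit rows deliberately failing one filter |
| `n_families` / `frac_multicopy` | 1,115 / 86/415 | single-copy families; multi-copy share |
| `copy_count_weights` | 2:70, 3:12, 4:2, 5:2 | multi-copy size distribution |
| `n_species` / `presence_prob` | 14 / 0.15 | family matrix; per-cell presence |
| `n_conditions` / `probes_per_gene` | 12 / 9 | array design |
| `n_random_probes` | 11,657 | null probes per condition |
| `effect_shift` | 4.0 | intensity shift in expressing conditions |
| `frac_expressed` | 0.642 | genes with true expression |

Design choices where the emulated study is silent:

* **Null intensity distribution**: standard normal per condition on the
  normalized scale. The simplest continuous null with exact quantiles for
  oracle tests; the quantile rule only needs *a* continuous null.
* **`effect_shift` = 4**: an expressed gene should be detectable by design.
  The 9-probe median has SD ≈ 0.37, so a 4σ shift clears the 0.995
  background quantile (2.58) with probability ≈ 0.9999 per expressing
  condition — "clearly expressed", while 2σ would leave most expressed genes
  uncalled and make the truth labels meaningless.
* **`presence_prob` = 0.15**: independent Bernoulli presence at 0.15 makes
  ≈ 16% of families exclusive to a random 5-of-14 species subset, matching
  the scale of real arthropod family matrices.
* **Start-codon omission is independent of the annotation group** (a single
  global `frac_no_start`); the association between missing starts and
  non-annotation seen in real data is not modeled.
* **Duplicates are exact copies** by default (`substitution_rate = 0`),
  keeping assembly-failure truth unambiguous; per-site noise can be enabled.
* **Sequence composition is only approximately the configured GC.** To make
  the planted ORF *provably* the longest stop-free interval, flanks are
  built from random chunks separated by 11-nt "stop walls" (stops in all
  three frames at any phase) and ORF interiors carry a 4-codon cross-frame
  stop anchor after every 6 random codons; a verification pass redraws the
  rare boundary tie. Walls are AT-rich and anchors are 50% GC, so realized
  GC is compressed toward the middle while preserving the planted group
  contrast. Codon usage is not modeled at all.
* Random-probe composition modeling, chromatograms and raw array images are
  out of scope; inputs are assumed base-called, trimmed and normalized.

Consequently, passing tests demonstrate that the statistics recover planted
structure under a clean generative model — unbiased estimation where the
estimator is unbiased, calibrated false-positive rates, exact bookkeeping —
not that they are robust to real-data pathologies (chimeric reads,
cross-hybridization, paralog confusion, phylogenetic correlation among
species in the family matrix).

## Numerical conventions and degenerate inputs

* Filter boundaries inclusive on both thresholds (`e = 1e-5` and
  `length = 33` are kept).
* Rounding of count discounts: half away from zero; report percentages:
  half away from zero to whole percent.
* Empirical quantiles: numpy's default linear interpolation between order
  statistics.
* Zero e-values are binned into the most significant histogram bin
  (log10 floor −200) instead of failing the log transform.
* Degenerate inputs raise typed errors: sequences < 3 nt, all-N GC, empty
  copy-number tables or null sets, a correction that discards the whole
  denominator (`p_intra = 0` with all non-matching), groups of < 2
  observations for Welch's test. Two identical constant groups return t = 0
  rather than raising.
* Published count tables are recomputed, never trusted: fixture mode lays
  reported beside computed values and flags disagreement beyond rounding.
  Two printed figures are internally inconsistent with their own inputs
  (a remainder of 9,749 where the inputs give 9,794; a printed 41.3% that
  recomputes to 41.4%) and one dataset row sums to 14,309 rather than
  14,310; these are carried as data and flagged, not forced.

## Problem sizes

The test suite exercises distributional claims at the sizes where the
checks are sharp but fast: 50,000 single-probe targets and 50,000 random
probes for null-calling calibration, 10,000 queries × 20 seeds for the
correction's recovery behaviour, 10,000 families × 30 replicates for
failure-rate recovery, exhaustive enumeration up to length-6 sequences and
8-species matrices for the brute-force oracles. The analysis drivers run
the full 14,310-read cohort; the end-to-end ledger driver uses a 2,000-read
cohort for its synthetic arm.
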