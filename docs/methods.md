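# Methods

## The classifier and its contracts

A surname-list classifier has no fitted parameters: its entire model is a
named set of canonical surnames per target group. Classification is exact
whole-surname equality on canonical form. We deliberately exclude prefix,
substring and phonetic (Soundex/metaphone) matching: fuzzy matching would
recover sensitivity at the direct expense of PPV, and PPV is the quantity
this family of classifiers exists to maximize.

**Canonical form.** Unicode NFKD decomposition with combining marks
stripped (`é → E`), uppercase, apostrophes (`'`, `’`, `ʼ`, `` ` ``) and
periods removed, every other non-letter character treated as a separator,
whitespace runs collapsed, surrounding whitespace trimmed, hyphens kept.
This maximizes robustness to registry spelling variation (case,
diacritics, punctuation) without merging genuinely distinct names; keeping
hyphens means a compound surname matches only as the full string, which
again protects PPV. Normalization is idempotent and total on any input
containing at least one letter; letter-free input raises a typed error in
list construction but, during bulk roster assignment, falls to the
residual group with a warning counter — a registry-scale run must never
abort on one garbled name, and the residual group is by definition
"everyone not positively identified".

**Disjointness.** A name on two lists has no unique group, so assignment
refuses to run on overlapping collections unless an explicit precedence
order is declared. `check_disjoint` reports the exact overlap per list
pair; the packaged starter lists are pairwise disjoint and disjoint from
the packaged general-population fixture.

**Gold standard.** A respondent is resolved to target group G iff at
least one of the two ethnicity questions has exactly one response
(after set-collapsing repeated identical tokens) equal, case-insensitively,
to G's token. Two genuinely open points are fixed as package policy:
repeated identical answers collapse before the single-response test (a
duplicated answer is still one ethnic response), and a respondent
triggering two distinct target groups falls to the residual group with a
warning (the conservative reading protects PPV; a precedence flag is
available for the alternative). Both choices are configurable at the call
site.

**Undefined vs zero.** Every metric with an empty denominator is reported
as explicitly undefined (`None`), never 0: a stratum with no predicted
positives has no PPV, and a silent 0 would corrupt stratified tables.
Percentages are reported rounded half-up to one decimal; full-precision
proportions are retained internally.

**Bootstrap.** Confidence intervals use the percentile bootstrap with
respondent-level resampling (default B = 1000), weights carried along as
constants. The weights here represent population counts, not sampling
probabilities, and the survey's design-based replication weights are not
part of the data model, so respondent resampling is the appropriate and
honest level. If a metric is undefined in more than half the replicates
the interval is refused rather than reported from the defined minority.

## The synthetic-data generator

Registry rosters and linked survey microdata are restricted, so the
package ships a generative stand-in with exactly enough structure to
exercise every pipeline contract:

1. true group ~ categorical(prevalence);
2. immigration category, sex, age band ~ per-group composition tables;
3. list membership ~ capture (own list) / contamination (another group's
   list), both multiplied by a per-immigration-category factor;
4. surname drawn from the packaged 200-name fixture of the matched list
   (off-list members draw from the general-population fixture), with
   rank-frequency weights: the printed registrant counts for the ten most
   common names, a log-log least-squares power-law extrapolation for the
   remaining ranks;
5. self-report: honest members answer a single target token; with
   probability `misreport`, and always for non-members, a distractor
   pattern is drawn (multi-responses, "Southeast Asian", "Aboriginal",
   mixed sets containing a target token) that never resolves to a target;
6. weight ~ lognormal(5.0, 0.8) — median ≈ 150 persons represented,
   realistic skew — independent of group; cycle ~ uniform over three
   labels.

All draws are vectorized from one `numpy` generator, so output files are
byte-identical for a given seed.

### Closed-form oracle

Because weights are independent of everything else, expected weighted
metrics equal the outcome-class probabilities. Summing over groups g and
immigration categories k (π prevalence, q composition, s capture,
c contamination, m stratum multiplier, r misreport, T the target):

    A = P(test+, gold+) = Σ_k π_T q_{T,k} s m_k (1−r)
    P(test+) = Σ_{g,k} π_g q_{g,k} p_test(g,k);  P(gold+) = π_T (1−r)
    B = P(test+) − A;  C = P(gold+) − A;  D = 1 − A − B − C

with the four metrics as the usual ratios. Restricting the sums to one
immigration category (and renormalizing) gives the stratified oracle. The
test suite checks this implementation against an independent exhaustive
enumeration of all (group, stratum, membership, report) outcome classes,
and checks the full pipeline against it at n = 50,000 over an 8-point
(π, s, c) grid within 3 Monte-Carlo standard errors, using the linearized
ratio-estimator SE `sqrt(p(1−p)·Σw²)/Σw` over each metric's denominator.

### Default calibration

The defaults describe a plausible large-province study regime: minority
prevalences 5.4% and 4.0%; capture 0.504 and 0.802 (expected sensitivity
equals capture because the capture multipliers are 1); contamination
0.0028/0.0035 (South Asian list) and 0.0021/0.0064 (Chinese list) per
bearer group; misreport 0.025; per-group immigration composition tables
in which minority members are predominantly recent immigrants and the
general population predominantly native-born; contamination multipliers
1.2 / 0.2 / 0.4 / 0.5 from native-born to longest-settled immigrants.
Under the closed form these put expected PPV at 0.891 and 0.917 with the
native-born stratum far below the rest (≈0.45 and 0.63) — the
characteristic nativity gradient, produced jointly by the composition
tables (most false positives are native-born) and the raised native-born
contamination. These are generator inputs defining the simulated regime;
no test asserts them as targets.

### What the simulator does and does not emulate

It emulates: low-prevalence minorities, the purity/completeness
trade-off, strata-dependent misclassification, weight skew, cycle
pooling, realistic surname frequency skew, and conflicting/multi-response
answer patterns. It does not emulate: the survey's multi-frame weight
calibration and design-based variance machinery, correlation between
weights and ethnicity (an optional knob exists in principle but the
default is independence), name changes over time, intermarriage dynamics,
or any quantitative mechanism behind the native-born PPV deficit — the
stratum multipliers are a stylized stand-in. Passing tests therefore
demonstrate the pipeline's arithmetic and contracts, not the field
performance of any particular list on real rosters.

## Problem sizes

The test suite uses 200-respondent populations (100 random trials) for
the brute-force oracle equivalence, n = 50,000 for the parameter-grid and
stratified-gradient checks (large enough that the native-born PPV gap of
tens of points dwarfs Monte-Carlo noise at ~200–400 predicted positives
per stratum), and 40 × B = 250 replicates for bootstrap coverage. The
acceptance script uses the same sizes; everything runs in well under a
minute on one core.

## Known limitations

* The starter lists are 200-name excerpts for demonstration and fixtures;
  production lists are an order of magnitude larger, so absolute metrics
  computed with the starter lists on real data would be much less
  sensitive than the reference values.
* Exact matching cannot see transliteration variants that normalization
  does not collapse (WONG vs WANG are distinct names, correctly; but a
  registry typo WNOG is simply unmatched).
* Sex and age affect nothing in the generator beyond composition, so
  simulated sex/age-stratified metrics are flat by construction.
* The conflict rule and deduplication policy in gold-standard resolution
  are package policy (documented above), not facts about any particular
  survey's processing.
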