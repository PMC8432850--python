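# Methods

This note documents the models, conventions, and numerical choices behind
`icd2iss`, and what the synthetic generators do and do not emulate.

## Code formats and normalisation

ICD-10-GM writes at most six significant characters (letter + two digits,
then up to three digits after the dot). Two export conventions are handled
rather than rejected: a trailing `-` (incomplete-code marker) is stripped
and recorded, and a trailing `!` marks a secondary *detail* code that
carries extra clinical information (e.g. the `S06.7-!` family grading
unconsciousness duration).

ICD-10-CM is modelled as the canonical dotted eight-character string
`CCC.SSVE`: three-character category, subclassification padded to two slots
with the placeholder `X`, a subcategory-specific seventh-character value
(`0`, `1`, `2`, `X`, …), and the encounter character (`A`/`D`/`S`,
severity-neutral, default `A` = initial encounter). Dots are presentation
only; all matching uses the dotless significant characters. Parsing and
rendering are inverse on canonical codes and `normalize_cm` is idempotent
(property-tested).

The converter's default profile accepts the S00–T88 injury chapter. Codes
from other chapters pass through unmapped with a warning instead of
aborting, because routine discharge exports mix injury and non-injury
diagnoses.

## Conversion tables

Three pluggable TSV tables drive the conversion; each ships as a fixture
covering the documented examples, and larger review tables are drop-in
replacements.

- **Recode rules** (`gm_pattern → cm_target`): longest-prefix substitution
  on dotless stems, preserving any trailing characters. Prefix semantics
  subsume exact-subcategory substitution and also cover GM codes more
  specific than the rule. Patterns are unique, so ties are impossible.
- **Seventh-character policies** (`cm_subcategory, condition, value`):
  exactly one unconditional fallback per subcategory; conditional rows are
  evaluated first against the patient's detail-code annotation tags. A stem
  with no policy row gets the placeholder `X` plus a warning — unreviewed
  stems must not abort a run.
- **Detail-code interpretations** (`gm_pattern → tag`): "!"-codes are
  lifted out of the injury list and become per-patient annotation tags;
  unrecognised detail codes are tagged `unknown`. The fixture maps the
  unconsciousness family: `S06.72!` → "> 24 h with return" → seventh
  character `5`; `S06.73!` → "> 24 h without return" → `6`. The AIS fixture
  assigns severity 5 only to the `S065X6` prefix and 4 to the `S065` stem,
  so a subdural haematoma scores AIS 4 unless consciousness is lost beyond
  24 hours without return — AIS 5, exactly the documented behaviour of
  GEM-based scoring.

## AIS lookup and the ISS

Historical GEM crosswalks route ICD-10-CM through ICD-9-CM, so one
diagnosis can map to several candidate severities. That two-step structure
is collapsed here into a single prefix table whose rows carry a severity
*set*; the observable min/max choice survives as the lookup mode (GEMmax
takes the highest candidate, GEMmin the lowest). Rows keyed on full-length
prefixes beat stem rows by longest-prefix matching.

Conventions (each configurable or flagged):

- **AIS 6 cap**: any region at AIS 6 sets ISS = 75 (flag `ais6_cap`). This
  is the standard ISS convention; it is on by default and can be disabled.
- **Unknown severity**: the marker 9 never enters the score (squaring it is
  meaningless); it sets `unknown_severity_present` and is returned only
  when it is a row's sole candidate.
- **Region taxonomy**: fixed to the six ISS regions with neck folded into
  head/neck.
- **Contributing regions**: the values, not the regions, determine the sum,
  so ties are inert; for reproducible reporting the lexicographically
  smallest region subset achieving the score is reported.
- Patients whose every code misses the table get a missing ISS and the flag
  `no_mappable_injury` rather than a fabricated zero.

`compute_iss` is verified exhaustively against an independent sort-free
oracle (maximum over all three-region subsets of the sum of squares) on all
6^6 profiles.

## Agreement statistics

- **Sign convention**: diff = automatic − manual (configurable). The
  direction is a documented choice, not a claim about any external dataset.
- **Paired TOST**: two one-sided one-sample t-tests of the mean difference
  against the bounds (default −3/+3 ISS points); `p_tost` is the maximum of
  the one-sided p-values and the matching (1−2α) confidence interval (90%
  at α = 0.05) is reported. Zero-variance differences yield a flagged
  degenerate result whose verdict follows the position of the constant mean
  relative to the bounds. The t-based engine is a documented default; the
  protocol deliberately pairs a parametric TOST with a nonparametric NHST,
  and both tests are exposed separately.
- **NHST**: two-sided Wilcoxon signed-rank. Zero differences are dropped
  (Wilcoxon's original convention); the exact null is used up to 25
  remaining pairs, the continuity-corrected normal approximation above.
  All-zero differences give p = 1 by convention.
- **Verdict**: equivalent iff the TOST is significant *and* the NHST is
  not, at the same α.
- **Weighted kappa**: κ = (Po − Pe)/(1 − Pe) with linear weights
  w_ij = 1 − |i−j|/(k−1) by default (quadratic selectable). Linear weights
  are the verified default: they reproduce the published overall κ = 0.47
  on the embedded cross-tabulation, whereas quadratic weights give 0.60.
  Interpretation bands: ≤ 0.20 poor, 0.21–0.40 fair, 0.41–0.60 moderate,
  0.61–0.80 good, 0.81–1.0 excellent. A table with Pe = 1 (all mass in one
  row and one column) has undefined κ and raises.
- **Group binning**: 1: 0–8, 2: 9–15, 3: 16–24, 4: 25–40, 5: 41–49,
  6: 50–75 — a partition of 0–75 (property-tested). Where published
  row/column labels overlap ("16–25"/"25–40"), the partition definition is
  authoritative.
- **Bonferroni**: min(1, m·p), applied in `compare_report` across the
  7-test family (six groups + overall). Verdicts are reported both on raw
  per-test p-values (the printed convention) and on adjusted ones.
- **TOST power / sample size**: exact noncentral-t power at true mean
  difference 0, iterated to the smallest n reaching the target. The joint
  rejection probability is computed as
  P(T_low ≥ t_crit) + P(T_high ≤ −t_crit) − 1, exact whenever the two
  one-sided rejection regions overlap — the relevant regime near the design
  power. Self-consistency is verified by Monte Carlo: at the returned n for
  a difference SD of 8 ISS points (the scale of observed
  manual-vs-automatic ISS differences in validation cohorts of this kind),
  the simulated rejection rate is 80% ± 2% at 10⁴ replicates. At very small
  n (e.g. SD 3 with bounds ±3, where n* ≈ 11) the discreteness of n makes
  the attained power overshoot the target by several points; that is a
  property of any sample-size routine, not an implementation artefact.

## Synthetic generators

`generate_cohort` emulates the *structure* a validation study needs, not
clinical realism: each patient gets a target ISS group drawn from a
configurable mix (default: the 640-patient split 219/122/155/114/13/17
across groups 1–6, i.e. a little over half the cohort below ISS 16), a
severity template realising that group, and random distinct body regions
supporting those severities. Codes come from a curated ~30-entry catalogue
spanning all six regions and severities 1–5, including the subdural
haematoma + detail-code pair; region/severity assignments in the catalogue
are plausible but invented. Every catalogue severity set is a singleton and
the fixture tables are closed over the catalogue (tested), so the
convert→score pipeline must recover the ground-truth ISS exactly — this is
the parameter-recovery check, and it holds for any seed.

`generate_paired_scores` draws the manual ISS uniformly within the sampled
group's range and shifts the automatic score for a `shift_prob` fraction of
patients by rounded N(0, `shift_sd`) noise, clamped to [0, 75]. The
defaults (`shift_prob` = 0.9, `shift_sd` = 16) were calibrated once by
simulation so the 6×6 group cross-tabulation of 640 pairs lands near linear
κ = 0.47, and then frozen (`fixtures/paired_default.json`). What passing
tests show is therefore that the *statistical protocol* behaves correctly
on data with the published group structure and agreement level — not that
any particular hospital's coding practice is reproduced. Real data differ
in ways the model ignores: disagreement is not symmetric in practice,
depends on region mix and coding depth, and manual scores are not uniform
within groups.

Determinism: all randomness flows through `numpy.random.default_rng(seed)`
from a single seed per generator call; identical configurations give
byte-identical outputs.

## Problem sizes

The test suite runs the exhaustive 6^6 ISS oracle, 1000 random kappa
tables, a 10⁴-patient mix-convergence check, a 1000-patient end-to-end
recovery, and a 10⁴-replicate Monte-Carlo power check; the whole suite
completes in a few seconds on one CPU, and `scripts/acceptance.py` in about
two. These sizes give Monte-Carlo error comfortably below every tolerance
asserted.

## Known limitations

- Syntactic validation only: no official GM/CM catalogue is bundled, so a
  well-formed but non-existent code is accepted.
- The shipped crosswalk/AIS fixtures cover the documented worked examples
  plus the generator catalogue; production use requires full review tables
  (drop-in TSVs).
- No NISS, no AIS-2005↔2015 dictionary translation, no mortality models
  (TRISS/RTS), no reverse CM→GM mapping.
- The paired-t TOST assumes approximate normality of mean differences;
  for heavily skewed difference distributions at small n the nominal level
  is approximate.
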