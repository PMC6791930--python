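# Methods

## Design

The package implements a case/non-case disproportionality analysis of a
spontaneous-reporting database. Reports are classified as cases when at
least one reaction PT belongs to a configurable ototoxicity case list
(22 MedDRA PTs bundled as package data); counting is at the report level,
so a report with several case PTs contributes one case. All remaining
retained reports form the comparator. Event-specific screening uses PT
groups: *tinnitus*; *hypoacusis* (incl. neurosensory hypoacusis);
*deafness* (deafness, its bilateral/neurosensory/unilateral variants, and
sudden hearing loss). For a PT-specific table the case margin is the
group's case count while the non-case margin stays the full comparator;
cases outside the group are excluded from that table rather than pooled
into the comparator, keeping `a + c` equal to the group total.

### Exclusion rules

Applied in a fixed precedence so each dropped report has one recorded
reason: observation window → literature source → vaccine (suspected drug
with ATC prefix J07; a concomitant vaccine does not drop a report) →
bare vertigo. "Vertigo" alone is clinically ambiguous (often used
interchangeably with dizziness), so a report is dropped only when
"vertigo" is among its PTs *and* no PT from the case list is present; a
report with a specified vestibular diagnosis such as positional vertigo
remains a case. Whether such reports should instead stay in the
comparator is genuinely open; the switch `vertigo_policy =
drop | keep_as_noncase` documents both readings, with `drop` (the
narrowest reading of "excluded from this analysis") as default.

Duplicate detection is exact-key: reports identical on
(age, sex, sorted substances, sorted PTs) collapse to the earliest
receipt date (ties: smallest report id). Receipt date is deliberately
not part of the key, because duplicate submissions typically differ in
date. No probabilistic linkage is attempted.

## Estimation

**Crude ROR.** `ROR = ad/(bc)` with the Wald CI on the log scale. This
equals `exp` of the slope of a univariate logistic regression of case
status on exposure; the equivalence is verified (not used for
computation) against a statsmodels GLM fit to 10⁻⁶ relative error.
Exposure means the drug appears among a report's *suspected* drugs
(`include_concomitant=True` widens this); a drug listed twice counts
once. ATC class-level screening uses prefix matching via
`key_type="atc"`. Zero cells get the Haldane–Anscombe +0.5 correction,
flagged in the output; with the default min-3-report rule this only
affects exploratory output. No multiple-testing correction is applied —
deliberate and conventional for SDR screening, and a prominent
limitation: at α = 0.05 across hundreds of drugs, some null pairs will
always be flagged.

**SDR rule.** Lower 95% bound > 1 and `a ≥ 3`. The report-count floor is
what controls the null flag rate for rare exposures; the test suite
verifies on a null generator that raising the floor from 1 to 3 strictly
reduces flags.

**Adjusted ROR.** One logistic model per drug–event pair (not a shared
model): case status on exposure + age (years, continuous) + sex
(male = 1, female reference) + number of drugs (suspected + concomitant,
continuous). Backward elimination removes the covariate with the largest
Wald p-value above `alpha_stay = 0.05` and refits, ties broken by the
fixed order age → sex → n_drugs; the exposure term is never eliminated.
Wald p-values (not likelihood-ratio tests) keep the procedure
deterministic and match common practice. Missing age/sex is handled by
complete-case analysis. Perfect separation — a zero cell in the
exposure × outcome cross-table — raises an error rather than returning a
diverged estimate; no Firth correction is applied. A categorical-age
option (<18 / 18–64 / ≥65 dummies, 18–64 reference) is available but not
default; the coding the original analysis used is unknowable, and the
continuous coding is the least parameterized choice.

**Descriptives.** Pearson chi-squared (no continuity correction) for
categorical comparisons, Mann–Whitney U for continuous ones, gated by a
one-sample Kolmogorov–Smirnov test against a normal with moments
estimated from the sample (conservative; used only as a gate). The
seriousness test compares serious vs not-serious with "not available"
excluded; outcome comparisons are per-category binary tests among known
outcomes. Percentages use the full group size (including missing rows)
as denominator, which reproduces published cohort-table conventions;
display rounding is half-up to one decimal. The exact Mann–Whitney path
(total n ≤ 12) enumerates all group assignments, with ties contributing
1/2 to U; the two-sided p is twice the smaller tail of the enumerated U
distribution, capped at 1 — with ties and unequal groups that
distribution is asymmetric, so a |U − μ| tail-sum would differ. Larger
samples use the tie-corrected normal approximation with continuity
correction.

## Synthetic generator

`generate(SyntheticConfig)` emulates a national-scale SRS: age from a
truncated two-component normal mixture (defaults 0.35·N(38, 13²) +
0.65·N(70, 9²), clipped to [0, 100], matching an elderly-skewed reporting
population with median ≈ 61), sex with 56% female, drug count 1 +
Poisson(1.5). Each focal drug has an exposure logit `γ₀ + γ_age·age_z +
γ_sex·male + γ_nd·ndrugs_z` and contributes `θ` to the event logit
`β₀ + Σθ_d·exposed_d + β_age·age_z + β_sex·male + β_nd·ndrugs_z`.
Covariates are standardized inside the generator (z-scores of the
realized draws) so coefficients are scale-free and recovery tests can
target `exp(θ)` directly. Defaults keep the study-scale conditions:
β₀ = logit(0.002) (≈0.2% case prevalence), one designed association with
OR 4 confounded by age (β_age = γ_age = 0.3). An event report draws one
PT from group weights (tinnitus 0.55, hypoacusis 0.33, deafness 0.03,
other 0.09, mirroring observed case composition); a `multi_pt` mode adds
a second group's PT to exercise counted-once semantics. Literature
sources, vaccine exposures (ATC J07), bare-vertigo reports and exact
duplicates (new id, +30 days) are injected at configurable rates
(defaults 1%, 2%, 0.2%, 1%). Filler drug and PT vocabularies are
synthetic strings with ATC-like codes that never collide with J07.

What the generator does **not** model: reporting trends over time,
drug–drug co-reporting structure, notoriety/stimulated-reporting bias,
PT co-occurrence beyond the optional second group, and free-text or
causality fields. Passing recovery tests therefore show the estimators
are correct under the designed mechanism, not that real SRS biases are
overcome.

### Replicate experiment sizes

The recovery experiments use higher event prevalence (2–5%) and exposure
(~15%) than the generator's study-scale defaults: at n = 20,000–100,000
these give hundreds of exposed cases per replicate, so the experiments
measure estimator behaviour (bias, CI coverage, deconfounding) rather
than small-sample noise. The null-calibration experiment spreads 30 null
drugs over exposure rates 2·10⁻⁴–10⁻² at 1% prevalence and n = 50,000,
placing exposed-case counts around the min-report threshold where the
rule actually binds. Coverage and calibration run at 200 seeded
replicates; medians for the confounding comparison use 50.

## Reference fixture

`make_reference_fixture()` builds, deterministically and without RNG, a
325,980-report database whose classification reproduces a published
cohort's marginals exactly: 652 cases / 325,328 non-cases; case sex
337/312/3, age bands 17/359/245/31, seriousness 187/408/57 with subtypes
82/59/42/4, outcomes 203/131/128/23/0/167; PT groups tinnitus 358,
hypoacusis 213, deafness 21; and per-drug exposure counts (default
amikacin 16/119, cisplatin 34/1,731; configurable, validated against the
totals). Known-age vectors are monotone sequences anchored at the
quartile positions so median (Q1–Q3) come out exactly 60 (45–70) for
cases and 61 (44–74) for non-cases under linear-interpolation quantiles;
drug-count vectors are anchored the same way to 2 (1–3) and 2 (1–4).
Attributes are block-assigned (marginals exact, joint structure
arbitrary), except non-case drug exposures, which are spread with a
prime stride so exposure does not line up with the demographic blocks.
Every report carries one globally unique synthetic filler PT, making
exact-key deduplication a no-op by construction. The fixture validates
only marginal counts; any within-report joint distribution it implies is
synthetic.

## Numerical choices and degenerate inputs

- Wald z-quantiles from scipy; CI level α = 0.05 throughout by default.
- Logistic fits: statsmodels Logit, Newton, 100-iteration cap;
  non-convergence raises rather than returning partial estimates.
- Chi-squared requires all expected counts > 0; KS requires n ≥ 5 and
  nonzero variance; Mann–Whitney requires non-empty samples. Each
  violation raises a typed error.
- Screening output ordering is deterministic: event group, then
  descending `a`, then drug key.
- Pipeline runs assert the partition property
  (cases + non-cases + dropped = ingested) at runtime and
  schema-validate outputs before exiting 0.

## Limitations

RORs quantify reporting disproportion, not risk; no denominators exist
in an SRS. No Bayesian shrinkage (IC/EBGM) or PRR is provided — ROR
only. Expectedness labels cover only the bundled drug–PT pairs; all
other pairs report "unknown". The reference fixture reproduces marginal
counts, so statistics depending on within-report joint structure (e.g.
cross-tabulations of sex by seriousness among cases) are not meaningful
on it.
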