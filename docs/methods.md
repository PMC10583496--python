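# Methods

## Setting

Each participant completes five speech-elicitation tasks: two expository
prompts (describe an important person; describe a meaningful place —
tasks `ET1`, `ET2`) and three picture descriptions (`PDT1`–`PDT3`, in the
cookie-theft tradition). Each transcript yields 16 lexical-semantic
features. The analyses ask two questions: (1) within a task type, does a
feature measure something stable about the person (test-retest
reliability across parallel forms)? (2) across task types, how much does
a person's standardized feature value move around (intraindividual
variability)?

## Feature definitions and counting conventions

Tokens come in three kinds, encoded in the transcript dialect: lexical
words, partial words (trailing `-`), and nonword vocalizations (leading
`&`). The conventions, applied uniformly:

* **N** (word count) counts lexical words only. Fillers (*um*, *uh*, …)
  are spoken words and count toward N; partials and nonwords do not.
* **Speech rate** alone counts every token of every kind, divided by the
  elapsed duration in seconds. **Filler rate** is filler tokens per second.
* The nine **category features** (fillers, empty words, definite and
  indefinite articles, pronouns, nouns, verbs, determiners, content
  words) are proportions of N, scaled per 100 words. The scale is a
  single constant (`PROPORTION_SCALE`); a raw-proportion rendering is one
  edit away. Pronouns are Penn tags PRP/PRP$/WP/WP$; nouns NN\*; verbs
  VB\*; determiners DT/PDT/WDT; articles are matched by surface form;
  filler and empty words by lexicon membership; content words are words
  absent from the stop-word list.
* **Frequency** is the token-weighted mean of log₁₀ per-million word
  frequency, with a configurable floor for out-of-vocabulary words
  (default: the table's minimum). Any per-million table can be supplied;
  the bundled table is a small synthetic fixture for self-contained runs.
* **Type-token ratio** is V/N. The **Honoré statistic** uses its standard
  form R = 100·ln N / (1 − V₁/V); when every type is a hapax (V₁ = V) the
  statistic is undefined and a NaN sentinel is returned with a warning.
  The **Brunet index** uses the standard form W = N^(V^−0.165).

POS tagging is deliberately an injected dependency: any callable mapping
a word list to an equal-length Penn tag list. Gold tags travel with
transcripts (sidecar files) when available — the synthetic generator
always emits them — and a small rule-based tagger is the fallback, so
feature correctness is tested against gold tags rather than against any
particular tagger's behavior.

## Reliability model

Raw features live on incommensurable scales, so values are z-scored
within each (feature, task, group) stratum — sample (n−1) SD throughout —
before analysis. Since z-scoring is affine per stratum, Pearson
correlations are unchanged; this is asserted as a test property rather
than assumed.

Within a task type, the reliability of a feature is the Pearson
correlation of the feature with itself across task pairs: the single
ET1–ET2 correlation for expository tasks, and the three pairwise picture
correlations averaged on the Fisher-z scale, r̄ = tanh(mean atanh r).
Fisher averaging is variance-stabilizing and keeps the average inside
(−1, 1). Correlations are clipped to ±(1 − 1e−12) before atanh so a
degenerate perfect correlation yields a large finite z instead of
infinity.

**Resampling null.** To calibrate "how large is large", each of `reps`
(default 10,000) replicates draws one uniformly random derangement of the
participants (no one paired with themselves; bijective, so every value is
used exactly once) and re-pairs the left side of every task pair with the
deranged right side. One permutation serves all features within a
replicate, preserving cross-feature structure. All per-feature, per-pair
correlations of a replicate are Fisher-averaged into a single mean
correlation; the observed grand mean is referred to these `reps` values
with a one-sided, add-one-smoothed p-value, p = (1 + #{null ≥ obs}) /
(1 + reps) — the claim being tested is directional, and smoothing keeps
p > 0. Per-feature reliabilities are referred to the same grand-mean null
as a descriptive calibration. Note the derangement null is not exactly
mean-zero in finite samples: E[r_null] ≈ −r_obs/(n−1), a visible negative
bias in groups of ten and a negligible one at several hundred.

**Group comparison.** Whether reliability differs between the MCI and
cognitively intact groups is tested by a two-sample pooled-variance
t-test on the Fisher-z transforms of the 16 per-feature reliabilities per
group (df = 16 + 16 − 2 = 30), with the 95% CI of the mean difference
back-transformed to the r scale. The equal-variance pooling matches the
integer-df design; Welch would give fractional df.

**Intraindividual variability.** Default mode: for each participant,
the sample SD of their five z-scores for a feature, averaged over the
group's participants. A second mode (`variance_pooled`) computes the
per-task cross-participant SDs squared, summed over the five tasks and
divided by the group size; it is exposed because both renderings of
"variance of SDs" are defensible, but the per-participant form is the
default since it directly operationalizes within-person dispersion. On
properly z-scored data the pooled form degenerates toward 5/n and is
mainly useful on unstandardized input.

**Analysis strata.** Full-sample analyses use z-scores computed without
group stratification; per-group analyses use group-stratified z-scores.
A group that is present but has fewer than 4 participants is an error
(the resampling null is meaningless below that), not a silent skip.

## Cognitive-status rule

T-scores are normed to mean 50, SD 10. The default rule classifies MCI
when ≥ 2 tests score T ≤ 40 (boundary inclusive) *within one cognitive
domain*; a looser variant ignoring the domain restriction is available
via `require_same_domain=False`. Both are exposed because the two
formulations circulate in the screening literature and differ for
profiles with scattered single-domain deficits; the domain-restricted
form is the default as the more specific criterion. Lowering any T-score
can never flip MCI to intact (monotonicity; property-tested).

## Synthetic cohorts

Two generators, deliberately at different levels, so statistical claims
do not depend on NLP plumbing and vice versa.

**Feature level.** For participant i, feature f: trait
θ_if ~ Normal(μ_group,f, √ρ_f) shared across tasks; task observation
θ_if + Normal(0, √(1−ρ_f)). Total variance is 1 and the population
inter-task correlation is exactly ρ_f, so ρ is a directly controlled
estimand. Expository tasks receive an additive offset (default 0.5 z)
mimicking the higher word counts of open-ended prompts; z-scoring removes
it, which is itself a property worth testing. Defaults: 10 MCI + 29
intact participants, 16 features, ρ = 0.6 (the middle of the reliability
range such cohorts show), group shift 0.

**Transcript level.** Each participant draws one `SpeakerProfile` —
verbosity (log-normal around 240 words on picture tasks, σ_log = 0.4),
filler propensity (logit-normal around 0.03, σ = 0.8), Zipf exponent
(1.10 ± 0.05), base speech rate (log-normal around 2.3 words/s,
σ_log = 0.15) and empty-word propensity (logit-normal around 0.05) — and
keeps it across tasks; the profile is the person-stable signal that makes
extracted features reliable. Task word counts are Poisson with
multipliers {ET1: 2.6, ET2: 2.2, PDT1: 1.2, PDT2: 0.97, PDT3: 0.92},
making expository samples roughly 2.5× longer than picture samples.
Tokens are drawn from a deterministic vocabulary (default 800 entries): a
closed-class head of real function words with fixed Penn tags at the top
Zipf ranks, then noun-heavy synthetic open-class forms. Fillers are
inserted per position with the speaker's propensity; nouns are replaced
by empty words with the empty-word propensity; 1% of words are emitted as
partials and 0.5% as nonwords. Duration is token count over the
speaker's rate with 5% log-normal noise. Gold tags and a matching
frequency table (Zipf probabilities × 10⁶) are emitted alongside, and
optional T-scores are drawn consistent with each participant's group
label. The MCI profile defaults nudge filler and empty-word propensities
upward, reflecting the word-finding difficulty those features proxy.

What the generator does *not* emulate: discourse structure, syntax,
semantic content of the pictures, disfluency clustering, or any
age/sex/education effects. Tests passing on these cohorts show that the
statistical machinery recovers the structure it assumes — not that real
speech satisfies those assumptions.

## Numerical and design choices

* Sample (n−1) SD everywhere: z-scoring, ITV, null summaries.
* Every stochastic operation takes an explicit integer seed; `fit()`
  derives one child seed per task-type × group from a seed sequence, in a
  fixed order, so runs are bit-reproducible.
* Derangements are sampled by rejection from uniform permutations
  (acceptance ≈ 1/e), vectorized in batches.
* Feature-matrix CSVs round-trip exactly: floats are written with
  shortest-round-trip `repr` and read with round-trip float parsing.
* Constant strata, empty transcripts, zero-variance correlation columns,
  undersized groups and unknown feature names are hard errors naming the
  offending unit, not silent NaNs.
* Problem sizes in the test suite are chosen to make each check sharp but
  cheap: oracle equivalence on 1,000 random transcripts; null calibration
  on 500 cohorts of 29 at 500 reps; parameter recovery at n = 500;
  end-to-end pipeline checks at 50 participants.

## Known limitations

* The rule-based fallback tagger is adequate for synthetic corpora and
  smoke use only; real transcripts should inject a trained tagger.
* The bundled frequency table is a synthetic fixture; substantive use of
  the frequency feature requires a real per-million table.
* Reliability here is internal consistency across same-session parallel
  forms, not stability over weeks or months.
* The Honoré statistic is undefined for all-hapax samples (short
  transcripts); downstream correlation analyses require complete data, so
  very short transcripts can force exclusions.
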