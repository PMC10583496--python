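# speechlex

Lexical-semantic features of spontaneous speech, and how reliable they are.

Spontaneous-speech measures — lexical diversity, word frequency, filler
usage, part-of-speech composition — are promising low-burden digital
biomarkers of early cognitive decline in older adults. Before such measures
can track cognitive status over time, a psychometric question has to be
answered: does a short sample of a person's speech measure something stable
about that person, or mostly the occasion? `speechlex` is a library and
command-line tool for that question. It is aimed at researchers studying
speech biomarkers for mild cognitive impairment (MCI) and related
conditions who work from manual or automatic transcripts.

The package provides:

* **Feature extraction** — 16 lexical-semantic features per transcript:
  word count *N*; filler, empty-word, definite/indefinite-article, pronoun,
  noun, verb, determiner and content-word proportions (per 100 words);
  mean log₁₀ word frequency (per million); type-token ratio *V/N*; the
  Honoré statistic *R* = 100·ln *N* / (1 − *V₁*/*V*), where *V₁* counts
  hapax legomena; the Brunet index *W* = *N*^(*V*^−0.165); and speech and
  filler rates (tokens/second). Part-of-speech tagging is an injected
  dependency (any callable mapping words to Penn Treebank tags); gold-tag
  sidecar files are used when present.
* **Reliability analysis** — repeated tasks of the same type (2 expository
  prompts; 3 picture descriptions) are treated as parallel test forms.
  After z-scoring within each (feature, task, group) stratum, each
  feature's reliability is the Pearson correlation of the feature with
  itself across task pairs, averaged on the Fisher-z scale:
  *r̄* = tanh(mean atanh *r*). Significance comes from a resampling null
  that re-pairs participants by random derangement (10,000 reps;
  one-sided, add-one-smoothed p). Group differences in reliability are
  tested with a pooled t-test on the Fisher-z scale (16 features per
  group ⇒ df = 30).
* **Intraindividual variability (ITV)** — the SD of a participant's five
  z-scores per feature, averaged over participants: how much a person
  moves around their own typical level across different task types.
* **Cohort classification** — the T-score rule for MCI: at or below T = 40
  (1 SD below the normative mean) on ≥ 2 tests within one cognitive domain.
* **Synthetic cohorts** — a feature-level generator with exact control of
  the inter-task correlation ρ, and a transcript-level generator that
  emits token streams (Zipfian vocabulary, person-stable speaker
  profiles, gold tags) so the whole pipeline can be exercised end to end.

## Worked example

```python
import speechlex as sl

spec = sl.TranscriptCohortSpec(seed=7)   # 10 MCI + 29 intact participants
transcripts, records, lexicons = sl.generate_transcripts(spec)
matrix = sl.extract_corpus_features(transcripts, records, lexicons)
results = sl.SpeechReliabilityModel(matrix).fit(reps=10_000, seed=42)
print(results.summary())
```

```text
Speech feature reliability analysis
==================================================
resampling reps: 10000   seed: 42

Grand-mean within-feature correlations:
  expository full     r = +0.8011   null mean = -0.0184   p = 9.999e-05
  expository MCI      r = +0.7153   null mean = -0.0710   p = 9.999e-05
  expository intact   r = +0.8310   null mean = -0.0262   p = 9.999e-05
  picture    full     r = +0.6536   null mean = -0.0148   p = 9.999e-05
  picture    MCI      r = +0.6087   null mean = -0.0586   p = 9.999e-05
  picture    intact   r = +0.6762   null mean = -0.0209   p = 9.999e-05

MCI vs intact (per-feature reliabilities, Fisher z):
  expository t(30) = -1.3147, p = 0.199, 95% CI [-0.63, 0.16]
  picture    t(30) = -0.5210, p = 0.606, 95% CI [-0.51, 0.32]
```

Reading this: within each task type, a participant's feature values
correlate strongly with their values on another instance of the same task
type (grand mean *r* ≈ 0.61–0.83 across groups), while the resampling
null — what you would see pairing different people — sits near zero, so
every observed mean beats all 10,000 null draws (p = 1/10001). Reliability
does not differ detectably between the MCI and cognitively intact groups.
The ITV table (also in `results.summary()`) shows which features stay
stable across *different* task types: in this synthetic cohort word count
and speech rate move least within a person, pronouns and indefinite
articles most.

The same pipeline runs from the shell:

```bash
speechlex simulate --out corpus --seed 7
speechlex extract --corpus corpus --out features.csv
speechlex reliability --features features.csv --seed 42 --out table.md --format markdown
```

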