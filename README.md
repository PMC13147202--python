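# pragmalang

Computational analysis of pragmatic language in dialog-act-tagged language
samples, built for neurodevelopmental phenotyping studies that compare
autistic and non-autistic speakers by diagnosis and sex across two
elicitation contexts: a picture-book **narrative** and a semi-structured
**conversation**.

The package turns tagged transcripts into group-level pragmatics:

- **Transcript I/O** — a minimal SALT-inspired plain-text dialect with
  maze (false start / reformulation) markup; word counts exclude mazes but
  count filled pauses (*um*, *uh*, ...).
- **Word classification** — LIWC-style dictionary matching with wildcard
  stems and phrase entries, custom theoretically-derived categories
  (simple/complex affective states, affective and cognitive behaviors,
  causal explanations, story elements, characters) and summed composites,
  reported as a percent of participant word count.
- **Speech-act sequences** — per-tag proportions, tag diversity, and the
  a-priori adjacent-pair sequences (consecutive on-topic / off-topic /
  storytelling narration; backchannel, self-elaboration,
  expected/unexpected responses to examiner questions in conversation),
  each with an opportunity-normalized rate.
- **Markov-chain comparison** — per-group first-order chains over speech
  acts and the Kullback–Leibler divergence *rate*

  D(P‖Q) = Σᵢ π_P(i) Σⱼ P(i,j) ln [P(i,j)/Q(i,j)],

  the expected per-step log-likelihood ratio weighted by P's stationary
  distribution π_P, symmetrized over group order and tested with a
  transcript-label permutation null.
- **Latent profile analysis** — from-scratch EM for diagonal-covariance
  Gaussian mixtures over z-scored indicators, model selection over 1–6
  profiles by AIC/BIC/normalized entropy/profile sizes and the bootstrap
  likelihood-ratio test (BLRT), plus profile-membership contingency tests.
- **Stats harness** — Type-III diagnosis × sex ANCOVA with a verbal-IQ
  covariate and estimated-marginal-means contrasts, Wilks-Λ MANCOVA,
  chi-square / Fisher's exact dispatch under the 20%-expected-cell rule
  (exact r×c enumeration), Benjamini–Hochberg FDR, partial correlations,
  multiple regression, ICC(2,1) and percent agreement.
- **Synthetic cohorts** — a generator that plants group structure
  (transition matrices, lexical emission rates, covariate distributions)
  so that every stage of the pipeline is testable end to end without any
  human data.

## Worked example

Generate a small synthetic conversation cohort and compare the male
autistic vs non-autistic group chains:

```python
from pragmalang import Task, default_config, generate_cohort, permutation_test

cfg = default_config(Task.CONVERSATION, n_per_group=30, seed=1)
cohort = generate_cohort(cfg, Task.CONVERSATION)
a = [t for t in cohort if t.diagnosis == "asd" and t.sex == "male"]
b = [t for t in cohort if t.diagnosis == "non_asd" and t.sex == "male"]
res = permutation_test(a, b, n_perm=499, alpha=0.5, seed=7)
print(f"KL symmetric = {res.symmetric:.4f} nats/step, p = {res.p_value:.4f}")
```

prints

```
KL symmetric = 0.0683 nats/step, p = 0.0020
```

i.e. the two groups' speech-act chains differ by about 0.07 nats per
utterance step — driven by the planted backchannel gap (non-autistic
speakers backchannel after an examiner statement with probability 0.35 vs
0.15) — and none of the 499 label permutations reached the observed
divergence (add-one p = 1/500 = 0.002).

The full analysis is organized as numbered drivers:

```bash
python analysis/01_simulate_cohorts.py      # study-scale cohorts (73/27/40/47)
python analysis/02_word_classification.py   # category percents per transcript
python analysis/03_speech_act_sequences.py  # a-priori sequence rates
python analysis/04_markov_kl.py             # pairwise chain divergences + p
python analysis/05_latent_profiles.py       # LPA fit table and membership
python analysis/06_group_statistics.py      # ANCOVAs with BH correction
```

Each step prints its findings and writes tables under `results/`. There is
also a thin CLI (`pragmalang validate|counts|classify|sequences|markov-kl|lpa|simulate`)
for working with transcript files directly.

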