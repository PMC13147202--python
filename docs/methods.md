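# Methods

This note documents the models, conventions and design choices behind
`pragmalang`, and what the synthetic-data validation does and does not
establish about real language samples.

## Transcript model and counting rules

A transcript is an ordered list of utterances, each with a speaker
(participant or examiner), a dialog-act tag, and tokens. The plain-text
dialect is deliberately minimal (header `@` lines; one utterance per line;
mazes in parentheses); it is SALT-inspired, not SALT-complete — full SALT
or CHAT conventions, and conversion from them, are out of scope.

Tokenization is whitespace splitting with terminal punctuation stripped
and case folding; hyphenated forms stay whole. This makes every count
reproducible by hand on small inputs.

The word count includes participant tokens only, excludes maze material,
and includes filled pauses — the convention used for percent-of-word-count
normalizations throughout. One edge the convention leaves open is a filled
pause *inside* a maze; here the maze exclusion wins, on the reasoning that
mazes are wholesale-excluded spans. Narrative analyses drop examiner
utterances entirely (files may still contain them); conversation analyses
are speaker-aware.

Dialog-act tag sets are fixed per task: 7 participant categories for
narrative (statement, question, nonnarrative, character speech, sound
effect, thinking, incomplete), 8 for conversation (initiation statement,
question, reply, clarification, backchannel, check-in, character speech,
incomplete), plus examiner question/statement. Automatic tagging from raw
text is a non-goal; tags are inputs.

## Word classification

Matching follows the dominant `.dic` convention: literal entries,
trailing-`*` prefix stems, case-insensitive after normalization. Phrase
entries (e.g. "as a result") are matched greedily left-to-right within an
utterance, longest first; a phrase match counts once and consumes its
tokens (they are then unavailable for single-word matches). A token may
hit several categories and counts in each. Composites sum their
constituent counts with no deduplication, mirroring LIWC's summed
categories. Percent scores are 100 × count / word count, with the
word-count rule above applied uniformly; `count_mazes=True` flips the maze
exclusion for sensitivity analyses, since whether dictionary runs on the
original data excluded mazes is not documented. A zero word count yields
missing percents, never zero.

The shipped example lexicon contains only a handful of printable example
words per category; it exists to make the pipeline runnable and the
generator's emission rates exact. Real analyses should supply full
dictionaries as `.dic` files.

## Sequence statistics

All a-priori sequences are defined on adjacent utterance pairs; a run of
three counts as two pairs. Narrative sequences are computed after removing
examiner utterances; conversational sequences use the full, speaker-aware
turn order. How the original coding scheme normalized sequence counts is
not stated anywhere we could follow, so both raw counts and
opportunity-normalized rates are reported, with sequence-specific
opportunity sets: pairs opened by an examiner non-question (backchannel,
non-obligatory response), pairs opened by an examiner question
(expected/unexpected responses), pairs opened by a participant utterance
(self-elaboration). Rates are therefore comparable across transcripts of
very different lengths.

"Non-obligatory response to examiner speech" is under-defined in the
source coding scheme. The default here counts any non-backchannel
participant utterance following an examiner non-question;
`non_obligatory_includes_backchannel=True` widens it. This is a documented
reconstruction, not a claim about the original rule.

## Markov chains and the KL divergence rate

Each group's chain pools transition counts across its transcripts
(per-transcript-average is available via `pool="mean"`): every transcript
contributes START → first tag and its within-transcript bigrams; no
transition crosses a transcript boundary and there is no END state. Rows
are smoothed with pseudo-count α = 0.5 (a Jeffreys-style prior), chosen so
all probabilities are positive — a requirement for finite divergences when
one group visits transitions the other does not. As α → ∞ both chains
approach uniform and the divergence shrinks to zero; sensitivity to α
should be checked when chains are sparse.

Two chains are compared with the divergence rate D(P‖Q) = Σᵢ π_P(i) Σⱼ
P(i,j) ln[P(i,j)/Q(i,j)] (nats per step), where π_P is P's stationary
distribution, computed by power iteration from uniform to a 1e-10
successive-iterate tolerance. Because group order is arbitrary, the test
statistic is the symmetric mean of the two directions; both directions are
reported.

Significance uses a transcript-level label permutation: group labels are
reshuffled over the pooled transcripts with sizes preserved, both chains
re-estimated, and the symmetric divergence recomputed; the add-one p-value
is (1 + #{null ≥ observed}) / (1 + n_perm). Permuting whole transcripts
respects within-transcript dependence. Note the plug-in divergence between
two independently estimated chains is biased upward at finite samples;
the permutation null carries the same bias, so the test is calibrated
(verified at level .05 within [0.03, 0.07] over 500 null replicates) even
though the point estimate overstates the population divergence.

## Latent profile analysis

Indicators are z-scored columnwise (listwise deletion first; zero-variance
columns are an error). The mixture is Gaussian with class-specific
diagonal covariances — the common LPA default when the covariance
structure is unrestricted within the "variances free, covariances zero"
family; the source analysis did not state its structure, and a
shared-variance variant would be a small extension. EM details: k-means++-
style seeding, best of `restarts` (default 20) runs by log-likelihood,
convergence when the log-likelihood gain drops below `tol` (default 1e-6),
variances floored at 1e-4 (on z-scored data), restart on any class whose
expected membership falls below one observation. The free-parameter count
is p = (k−1) + 2kd, giving AIC = −2ℓ + 2p and BIC = −2ℓ + p ln n.
Classification entropy is the 0–1 normalized 1 − [Σ −p·ln p]/(n ln k),
missing for k = 1.

The BLRT simulates `n_boot` datasets from the fitted (k−1)-profile model,
refits both models to each, and compares the observed 2(ℓ_k − ℓ_{k−1})
against that null with an add-one p. Bootstrap refits use fewer restarts
(default 5; 2 in the large calibration runs) and a looser tolerance than
the primary fit — the LRT null distribution is insensitive to this, and it
keeps 100-bootstrap tests affordable.

Model selection reports the fit table over k = 1..6 and flags the
BIC-minimal row and any profile below 5% of the sample; the final choice
is the analyst's, weighing the BLRT and interpretability — on the
synthetic conversation features, BIC typically stops at k = 1 while the
BLRT supports k = 2, exactly the kind of disagreement the iterative
workflow is meant to adjudicate. Membership is tested per (profile, group)
cell as a 2×2 table against the rest of the sample, through the
chi-square/Fisher dispatch, BH-corrected as one family.

## Statistical harness

ANCOVA uses sum-to-zero coding and Type-III-style nested residual-sum-of-
squares comparisons (each effect tested against the full model), which is
order-invariant under the unbalanced cells this design produces; it
matches `car::Anova(type=3)`/`emmeans` and statsmodels `anova_lm(typ=3)`
to numerical precision in the tests. Effect size is partial eta squared.
Estimated marginal means evaluate the model at the covariate mean with the
other factor equally weighted. The MANCOVA omnibus uses Wilks' Λ with
Rao's F approximation (exact for single-df hypotheses); per-outcome
ANCOVAs remain the primary report, matching how such results are usually
presented.

Contingency tests dispatch on the 20% rule: Fisher's exact when ≥ 20% of
cells have expected count < 5, else Pearson chi-square without continuity
correction. Fisher's two-sided p uses the point-probability rule via full
enumeration of tables with the observed margins (r×c, not just 2×2; it
matches R's `fisher.test` and the hypergeometric closed form on 2×2).
Enumeration is exponential in principle; it is intended for the small
tables the rule selects.

Benjamini–Hochberg adjustment is the step-up definition with cumulative-
min monotonization, applied as one family per analysis block (task ×
outcome set), configurable. Partial correlations are Pearson on residuals
with t-based p on n − 2 − (number of covariates) df. ICC is the (2,1)
form — two-way random effects, absolute agreement, single measure — with
the conventional moderate/good/excellent bands at .5/.75/.9; the source
study did not name its ICC form, and (2,1) is the conservative default for
two interchangeable raters.

## Synthetic cohorts

The generator is the study-design stand-in: four groups (diagnosis × sex)
at the emulated cell sizes 73/27/40/47, two tasks. Each group has a
planted first-order chain over the task's speech-act states
(speaker-aware for conversation), Poisson utterance counts and lengths,
per-token lexical emission rates over the example categories against a
500-word deterministic background vocabulary (guaranteed not to match any
category), maze and filled-pause injection (6% / 4% per token), and
Gaussian VIQ/age.

Planted conditions, fixed once from the effect directions the design is
meant to detect: backchannel transition mass after an examiner
non-question 0.35 (non-autistic) vs 0.15 (autistic); participant-to-
participant (self-elaboration) mass 0.45 (female) vs 0.35 (male);
complex-affect emission 0.020 (female) vs 0.010 (male) per token;
narrative off-topic/thinking mass slightly higher in autistic groups;
VIQ mean 105 (autistic) vs 112 (non-autistic), SD 13, making the covariate
non-trivial. Narrative lengths (≈ 50 utterances × ≈ 8 tokens ≈ 400 words)
match the observed scale of such samples. Per-transcript seeds are spawned
from the master seed via `numpy.random.SeedSequence`, so cohorts are
bitwise reproducible.

What the generator does *not* emulate: real lexical content and syntax,
topic structure, disfluency clustering, tagger disagreement, age- or
IQ-dependent pragmatics, masking/camouflaging, or any correlation between
the lexical and sequential channels beyond group membership. Passing
tests therefore establish that the *computations* are correct and the
*inference* is calibrated and powered under known structure — not that the
measures are valid on human transcripts.

## Problem sizes used in validation

Test-suite simulations use reduced-but-stated sizes chosen as the smallest
that make the checks sharp: permutation calibration with 2 × 20
transcripts, 200 permutations, 500 replicates; LPA recovery at n = 150
with 7 indicators over 100 seeded runs; BLRT level/power at n = 100 with 4
indicators, 99 bootstraps, 100 replicates; GLM null calibration over
1,000 replicates; end-to-end power at n = 30 per group over 25 replicates.
The analysis drivers and the acceptance script run at the full emulated
study scale (187 transcripts per task).

## Known limitations

- The exact statistic and null of the original chain-comparison analysis
  are not documented; the divergence-rate + permutation design here is a
  principled reconstruction.
- Fisher enumeration is impractical for large-count r×c tables (those
  dispatch to chi-square under the 20% rule anyway).
- The LPA covariance family is diagonal-only; correlated indicators within
  a profile are absorbed into extra profiles rather than modeled.
- Mixed categorical-continuous latent class models, covariate-on-class
  regression, trigram chains and prosodic/timing features are out of
  scope.
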