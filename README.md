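# headachedx

An adaptive, rule-based headache-diagnosis engine with the full
diagnostic-accuracy statistics toolkit used to validate such an
instrument against a clinical reference standard.

## Who this is for

Researchers building or evaluating computer-administered diagnostic
questionnaires — in particular ICHD-3 headache classification — who need
(a) a rule engine that asks the *fewest* questions that still guarantee
the same diagnosis as the full questionnaire, and (b) the statistics of
a paired diagnostic-accuracy study: Cohen's κ, exact binomial confidence
intervals, likelihood ratios, prevalence-transported predictive values,
Fagan post-test probabilities, and exact-CI sample sizing.

## What is inside

**`headachedx.rulebase`** — ICHD-3 criteria as operator trees over
symptom *atoms* (questions with small finite answer domains), evaluated
in strong Kleene three-valued logic.  A criterion such as migraine
without aura is `ALL(A, B, C, D)` with `C = AT_LEAST(2, ...)` over the
four pain characteristics; probable migraine uses an
`EXACTLY_ONE_FALSE` operator over the criterion blocks.  Under a partial
answer set each rule is TRUE, FALSE, or UNKNOWN, and decided values are
final under any further answers.

**`headachedx.engine`** — the adaptive interview.  Walking once over an
ordered question bank, a question is asked only if some completion of
the current answers makes the final diagnosis depend on it; within an
enumeration budget the check is exact (completion enumeration over the
rule's undecided support cone), above budget a sound over-approximation
is used.  Skipping is therefore provably sound: the adaptive session
always returns the same labels as the exhaustive questionnaire.

**`headachedx.cohort`** — a synthetic paired-study simulator: latent
headache classes (default mixture: 67% migraine/probable migraine), a
true answer set per respondent, and an index channel that perturbs each
answer with a per-symptom discordance probability concentrated on the
symptoms that require verbal rephrasing (phonophobia, photophobia,
aggravation by activity).

**`headachedx.dxstats`** — the statistics.  Sensitivity = TP/(TP+FN)
etc. with Clopper–Pearson (exact Beta-quantile) intervals; unweighted
κ = (p_o − p_e)/(1 − p_e) with the asymptotic interval; LR+ =
sens/(1−spec) and LR− = (1−sens)/spec with log-method intervals;
PPV/NPV transported to any prevalence by Bayes' rule; Fagan updates
post-odds = pre-odds × LR; and the smallest group size m whose exact CI
at an anticipated proportion has width ≤ w, scaled to a total cohort
size N = ⌈m / group fraction⌉.

## Worked example

The validation study's 2×2 table (index test vs. reference interview,
n = 202) is 121 true positives, 2 false positives, 15 false negatives,
64 true negatives:

```sh
headachedx evaluate --counts 121 2 15 64 --prevalence 0.10
```

```
Diagnostic accuracy report — contrast: mpm_vs_nom
  2x2 table: TP=121  FP=2  FN=15  TN=64  (n=202)
  Study prevalence      67.3% (60.4%–73.7%)
  Kappa                 0.82 (0.74–0.90) — almost perfect agreement
  Accuracy              91.6% (86.9%–95.0%)
  Sensitivity           89.0% (82.5%–93.7%)
  Specificity           97.0% (89.5%–99.6%)
  PPV                   98.4% (94.2%–99.8%)
  NPV                   81.0% (70.6%–89.0%)
  LR+                   29.4 (7.49–115.1)
  LR-                   0.11 (0.07–0.18)
  Fagan 50% pretest:    positive → 97%, negative → 10%
  Fagan study pretest:  positive → 98%, negative → 19%
  Discordant records    17
  At prevalence  10%:   PPV 76.5% (45.4%–92.7%), NPV 98.8% (98.0%–99.2%)
```

Reading it: the instruments agree almost perfectly (κ 0.82); a positive
result multiplies the disease odds by 29.4, so a 50% pre-test
probability becomes 97% post-test, while a negative result (LR− 0.11)
drops it to 10%.  At a community prevalence of 10% the same test has
PPV 76.5% and NPV 98.8% — predictive values travel with prevalence,
likelihood ratios do not.

Planning a study instead?  The total cohort needed so that an 85%
exact CI for a sensitivity of 80% is at most 0.15 wide, when 35% of the
cohort is expected to be diseased:

```sh
headachedx samplesize --p 0.80 --width 0.15 --conf 0.85 --prevalence 0.35
# group size 71, total sample size 203 (p=0.8, width<=0.15, conf=0.85, group fraction=0.35)
```

Other commands: `headachedx interview` (interactive adaptive session),
`headachedx diagnose` (batch answers CSV → labels), `headachedx
simulate` (synthetic paired cohort → CSVs).  A ready-made paired CSV
with the table above is shipped as `examples/synthetic_table3_pairs.csv`
(synthetic rows reproducing only the 2×2 margins):

```sh
headachedx simulate --seed 7 --out-pairs pairs.csv --out-atoms atoms.csv
headachedx evaluate --pairs pairs.csv --atom-pairs atoms.csv
```

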