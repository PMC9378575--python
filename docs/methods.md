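# Methods

## The rule base

Diagnostic criteria are operator trees over *atoms* — askable facts with
finite ordered answer domains of 2–5 values (booleans plus a few small
categoricals: attack count {0-1, 2-4, 5+}, untreated attack duration
{<4h, 4-72h, 72h-7d, >7d}, pain intensity {mild, moderate, severe},
monthly headache days {<15, 15+}, monthly acute-medication days
{<10, 10+}).  Categorical rather than numeric domains keep every answer
space finite and enumerable, which the engine's exactness guarantees
rely on.

Operators: `ATOM_EQUALS`, `NOT`, `ALL`, `ANY`, `AT_LEAST(k)`, and
`EXACTLY_ONE_FALSE`.  The last encodes "all criteria but one fulfilled"
(probable migraine).  Its three-valued table, for which no standard
exists: TRUE when exactly one child is FALSE and the rest are decided
TRUE; FALSE when at least two children are FALSE, or all are decided
TRUE; UNKNOWN otherwise.  This is exactly the completion semantics:
with one known-FALSE child and undecided ones, both "that stays the
only failure" and "a second failure appears" are reachable.

Evaluation is strong Kleene.  Decided values are final under answer-set
extension (monotone refinement).  Kleene evaluation is *sound* but not
*complete* against completion semantics when one atom occurs in several
leaves (e.g. `ANY` over an atom's whole domain is Kleene-UNKNOWN though
every completion is TRUE); the property tests assert soundness on
arbitrary trees and the full equivalence on trees whose leaves bind
distinct atoms.  Nothing in the engine depends on completeness — its
exact decisions always come from completion enumeration.

### The default bank

26 atoms, 9 rules: migraine without aura (1.1), migraine with aura
(1.2), probable migraine (1.5), tension-type (2), chronic migraine
(1.3), medication-overuse headache (8.2), a five-item red-flag screen
mapping to "secondary headache suspected", a catch-all "other
headache", and "no headache".  Design choices where ICHD-3 is richer
than a 26-atom bank can be:

- Aura is one "present" gate, one "fully reversible" atom, and six
  boolean characteristics with an `AT_LEAST(3)` requirement; aura
  symptom typing is collapsed into the reversibility atom.
- Criterion E ("not better accounted for…") is approximated by the
  red-flag screen on every primary rule plus explicit cross-rule
  exclusions inside the probable rule (`NOT` migraine-without-aura core,
  `NOT` migraine-with-aura core, `NOT` tension-type core).  The first
  two exclusions also enforce the invariant that a definite migraine is
  never simultaneously "probable"; the with-aura branch of the probable
  rule is gated on aura being present, so the single "missing" block can
  never be the aura itself — this is what makes the aura-detail
  questions provably irrelevant for respondents without aura.
- Tension-type duration is "30 minutes to 7 days"; the 4-value duration
  domain cannot carry the 30-minute lower bound, so it is folded into
  the `<4h` bucket.  Multi-day buckets exist precisely so tension-type
  (≤7d) and the catch-all (>7d) stay distinguishable.
- Chronic migraine reuses the pain/associated-symptom blocks of 1.1
  with ≥15 headache days/month for over three months; it can co-occur
  with other labels (label sets, not single labels, are the engine's
  output).

The bank is data, not code: it serializes to a schema-validated JSON
document and users may load alternative banks.

## The adaptive engine

One pass over an ordered question bank.  Before asking a question the
engine tests whether its answer can still matter: *q is relevant iff
some completion of the current answers yields different resolved-label
sets for two different answers to q*.  Because labels are unique per
rule, a label-set difference is a value difference in some rule, and a
rule's eventual value depends only on the unassigned atoms inside its
still-undecided subtrees (its support cone, computed alongside Kleene
evaluation).  The engine therefore enumerates, per candidate rule, the
product of cone-atom domains (budget: 14 atoms, configurable) and asks
the question as soon as any rule shows a difference.  Above budget it
falls back to the sound over-approximation "q occurs in an undecided
rule", asks the question, and flags it in the transcript — so skipping
is *always* sound and the final labels provably equal the exhaustive
questionnaire's labels, while minimality (never asking an irrelevant
question) is guaranteed whenever cones fit the budget, which they do
throughout the default bank's sessions in practice.

Question count depends on the initial ordering (chosen here:
screening → red flags → attack pattern → pain → associated symptoms →
aura block → chronicity/medication, a conversational order); final
labels never do.  Both properties are tested, the latter also against a
brute-force completion oracle on random small banks.

At session end a rule can be Kleene-UNKNOWN yet completion-invariant
(repeated atoms); such rules are settled by enumerating their cone and
asserting all completions agree.

## The cohort simulator

Respondents are drawn from a latent-class mixture; a class-specific
constructive proposal plus rejection guarantees the invariant that the
true answer set resolves to exactly the class label.  Defaults:

| class | weight |
|---|---|
| migraine without aura | 0.32 |
| migraine with aura | 0.08 |
| probable migraine | 0.27 |
| tension-type | 0.18 |
| other headache | 0.05 |
| no headache | 0.10 |

giving a migraine/probable-migraine mass of 0.67, the positive-class
prevalence of the study population emulated (n = 202 by default).

The index channel re-answers each atom independently: with the atom's
discordance probability the true value is replaced by a uniform draw
from the rest of its domain.  Defaults (phonophobia 0.32, aggravation
0.30, photophobia 0.27, pulsating 0.18, duration 0.15, intensity 0.08,
nausea/vomiting 0.04, all others 0) are a *qualitative* calibration of
the observed agreement gradient — lowest consistency on symptoms that
interviewers rephrase, perfect on aura and unilateral pain.  They are
configuration, not estimates: per-symptom agreement conditional on
diagnosis discordance in a 17-person subset does not identify
per-symptom flip probabilities, so no exact percentages are claimed.
Noise is independent across atoms; correlated noise is out of scope of
the default model.  The reference channel is noise-free (the reference
interview is the study's gold standard).

What passing simulator tests shows — and does not.  They show the
pipeline's internal consistency: zero noise gives κ = 1 exactly, seeds
reproduce byte-identical cohorts, raising any one symptom's discordance
does not raise expected diagnosis agreement, and the agreement ranking
tracks the configured gradient.  They do not show that real respondents
behave like the noise model: real discordance is correlated across
symptoms, asymmetric (denial vs. endorsement), and coupled to class.

## Statistics

- Proportion CIs: Clopper–Pearson, lower = Beta((1−conf)/2; x, n−x+1),
  upper = Beta(1−(1−conf)/2; x+1, n−x), with 0/1 at the boundary
  counts.  Coverage is verified *exactly* (summing the binomial pmf),
  not by simulation.
- Unweighted Cohen's κ with SE = sqrt(p_o(1−p_o)/(n(1−p_e)²)) and a
  normal interval clipped to [−1, 1]; interpretation uses the
  conventional bins (≤0 none, …, 0.81–1.00 almost perfect).
- Likelihood ratios: point estimates from raw counts (LR+ flagged
  infinite when specificity is 1); log-method (Simel) intervals with
  SE(ln LR+) = sqrt(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN)) and the
  analogous expression for LR−.  When a needed cell is zero the
  interval (only) uses a 0.5-added table, flagged
  `continuity-corrected`.
- Predictive values at a hypothetical prevalence use Bayes transport;
  their intervals use the logit-transform (Mercaldo-style) variance —
  the method is tagged in the output since fixed-prevalence PV
  intervals have no single standard.
- Fagan updates compute with unrounded likelihood ratios; at a 67%
  pretest the unrounded LR− 0.1137 gives a 19% post-test probability
  where the rounded 0.11 gives 18% — the report prints the former.
- Sample sizing searches m = 1, 2, … for the smallest group size whose
  exact CI at successes = round(p·m) has width ≤ w, then
  N = ⌈m / group fraction⌉.  With p = 0.80, w = 0.15, conf = 0.85 this
  gives m = 71 and totals 203 (fraction 0.35) and 110 (fraction 0.65).
- Contingency tables from paired label sets: the reference channel
  defines disease, the index channel the test; records whose reference
  labels match a contrast's exclusion predicate (probable migraine
  under the migraine-only contrast) are dropped and counted.

## Problem sizes and tolerances in the test suite

Engine correctness runs 2,000 latent assignments (half uniform, half
cohort-sampled) plus oracle-certified sessions on random 9-atom banks;
Monte-Carlo calibration checks use n = 5,000 over 10 seeds with
respondents shared across noise conditions (common random numbers), a
0.005 allowance on mean agreement comparisons, and 3σ binomial bands
elsewhere.  The large Monte-Carlo runs evaluate rules directly rather
than replaying every respondent through the interview loop; the two
paths are proven equal by the engine-correctness tests, and the
equality is itself re-checked on smaller runs.

## Known limitations

- The bank covers the common primary headaches plus two secondary
  screens, not all of ICHD-3 (no TACs/cluster, no fifth-digit
  subtyping, no pediatric criteria).
- One session diagnoses one headache-type block; respondents with
  several headache types need one session per type, orchestrated by the
  caller.
- Criterion E is an approximation (see above); full cross-diagnosis
  subsumption is not modelled.
- The noise model's independence assumption understates real response
  correlation; treat simulator-derived accuracy figures as mechanism
  demonstrations, not forecasts.
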