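"""Adaptive questioning engine with provably sound question skipping.

A session walks once over an ordered question bank.  At each question it
decides, relative to the current answer set and the diagnostic rules,
whether the answer may still logically affect the final diagnostic
impression; the question is asked only if so.  "May affect" is made
precise as: there exists a completion of the current answers under which
two different answers to the question yield different resolved-label
sets.  Within an enumeration budget the check is exact; above budget a
sound over-approximation is used (the question is asked and flagged),
so skipping never changes the outcome.

The check is decomposed per rule: a label-set difference is exactly a
value difference in some rule (labels are unique per rule), and a rule's
eventual value depends only on the unassigned atoms in its undecided
subtrees (its "support cone").  Enumerating each candidate rule's cone
is therefore exact and far cheaper than enumerating all free atoms.
"""

from __future__ import annotations

import itertools
from collections.abc import Callable, Mapping
from dataclasses import dataclass, field

from .rulebase import (
    FALSE,
    TRUE,
    UNKNOWN,
    BankError,
    Expression,
    Impression,
    RuleSet,
    TruthValue,
    default_ichd_ruleset,
    evaluate,
    evaluate_influence,
    resolve,
    AURA_CHARACTERISTIC_ATOMS,
    RED_FLAG_ATOMS,
)

__all__ = [
    "Question",
    "QuestionBank",
    "Session",
    "Transcript",
    "CompletionOracle",
    "RelevanceDecision",
    "relevance",
    "is_relevant",
    "next_question",
    "record_answer",
    "run_session",
    "replay",
    "enumerate_label_sets",
    "default_question_bank",
    "DEFAULT_BUDGET",
]

#: Default cap on the number of free atoms enumerated by the exact
#: relevance check and the completion oracle.
DEFAULT_BUDGET = 14


class EngineError(RuntimeError):
    """Misuse of the session protocol (e.g. answering an unasked question)."""


@dataclass(frozen=True)
class Question:
    """One prompt bound to one atom; text aims at a 6th-grade reading level."""

    id: str
    atom_id: str
    text: str
    order_index: int
    answer_labels: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class QuestionBank:
    """Ordered questions covering every atom the bound rule set references."""

    questions: tuple[Question, ...]
    ruleset: RuleSet

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "questions",
            tuple(sorted(self.questions, key=lambda q: q.order_index)),
        )
        indices = [q.order_index for q in self.questions]
        if len(set(indices)) != len(indices):
            raise BankError("question order indices must be unique")
        by_atom = [q.atom_id for q in self.questions]
        if len(set(by_atom)) != len(by_atom):
            raise BankError("at most one question per atom")
        for q in self.questions:
            if q.atom_id not in self.ruleset.atom_map:
                raise BankError(f"question {q.id!r} references unknown atom {q.atom_id!r}")
        referenced = {a for r in self.ruleset.rules for a in r.expression.atoms()}
        missing = referenced - set(by_atom)
        if missing:
            raise BankError(f"no question for rule-referenced atoms: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.questions)


@dataclass(frozen=True)
class RelevanceDecision:
    """Outcome of a relevance check.

    ``exact`` is False when the enumeration budget was exceeded and the
    sound over-approximation ("atom still occurs in an undecided rule")
    forced the question to be asked.
    """

    relevant: bool
    exact: bool


def _rule_sensitive(
    expr: Expression,
    answers: Mapping[str, str],
    atom_id: str,
    atom_domain: tuple[str, ...],
    cone: tuple[str, ...],
    ruleset: RuleSet,
) -> bool:
    """Does some completion of ``cone`` make ``expr`` depend on ``atom_id``?"""
    domains = [ruleset.atom(a).domain for a in cone]
    ext = dict(answers)
    for combo in itertools.product(*domains):
        for a, v in zip(cone, combo):
            ext[a] = v
        base: TruthValue | None = None
        for v in atom_domain:
            ext[atom_id] = v
            val = evaluate(expr, ext)
            if base is None:
                base = val
            elif val is not base:
                return True
        del ext[atom_id]
    return False


def relevance(
    question: Question,
    ruleset: RuleSet,
    answers: Mapping[str, str],
    budget: int = DEFAULT_BUDGET,
    _influences: Mapping[str, tuple[TruthValue, frozenset[str]]] | None = None,
) -> RelevanceDecision:
    """Full relevance check; see module docstring for the semantics."""
    if question.atom_id in answers:
        raise EngineError(f"question {question.id!r} is already answered")
    if _influences is None:
        _influences = {
            r.id: evaluate_influence(r.expression, answers) for r in ruleset.rules
        }
    atom = ruleset.atom(question.atom_id)
    over_budget = False
    for rule in ruleset.rules:
        status, influential = _influences[rule.id]
        if status is not UNKNOWN or atom.id not in influential:
            continue
        cone = tuple(sorted(influential - {atom.id}))
        if len(cone) > budget:
            over_budget = True
            continue
        if _rule_sensitive(rule.expression, answers, atom.id, atom.domain, cone, ruleset):
            return RelevanceDecision(relevant=True, exact=True)
    if over_budget:
        return RelevanceDecision(relevant=True, exact=False)
    return RelevanceDecision(relevant=False, exact=True)


def is_relevant(
    question: Question,
    ruleset: RuleSet,
    answers: Mapping[str, str],
    budget: int = DEFAULT_BUDGET,
) -> bool:
    """True iff the question's answer may still affect the final label set."""
    return relevance(question, ruleset, answers, budget).relevant


@dataclass
class Session:
    """Mutable state of one adaptive interview pass."""

    bank: QuestionBank
    budget: int = DEFAULT_BUDGET
    answers: dict[str, str] = field(default_factory=dict)
    cursor: int = 0
    asked: list[tuple[str, str]] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    approximate: set[str] = field(default_factory=set)
    complete: bool = False
    _pending: Question | None = None

    @property
    def in_progress(self) -> bool:
        return not self.complete


def next_question(session: Session) -> Question | None:
    """Advance past irrelevant questions; return the next one to ask.

    Returns None (and marks the session complete) when the single pass
    over the bank is exhausted.  Idempotent between answers.
    """
    if session.complete:
        return None
    if session._pending is not None:
        return session._pending
    ruleset = session.bank.ruleset
    # The influence map stays valid while no new answer arrives, i.e. for
    # the whole run of consecutive skips below.
    influences = {
        r.id: evaluate_influence(r.expression, session.answers) for r in ruleset.rules
    }
    questions = session.bank.questions
    while session.cursor < len(questions):
        q = questions[session.cursor]
        decision = relevance(q, ruleset, session.answers, session.budget, influences)
        if decision.relevant:
            if not decision.exact:
                session.approximate.add(q.id)
            session._pending = q
            return q
        session.skipped.append(q.id)
        session.cursor += 1
    session.complete = True
    return None


def record_answer(session: Session, question: Question, value: str) -> None:
    if session._pending is None or session._pending.id != question.id:
        raise EngineError(f"question {question.id!r} is not the pending question")
    atom = session.bank.ruleset.atom(question.atom_id)
    if value not in atom.domain:
        raise BankError(
            f"value {value!r} not in domain {atom.domain!r} of atom {atom.id!r}"
        )
    session.answers[question.atom_id] = value
    session.asked.append((question.id, value))
    session.cursor += 1
    session._pending = None


@dataclass(frozen=True)
class Transcript:
    """Record of an adaptive session: what was asked, skipped, concluded."""

    asked: tuple[tuple[str, str], ...]
    skipped: tuple[str, ...]
    labels: frozenset[str]
    approximate: frozenset[str]

    @property
    def question_count(self) -> int:
        return len(self.asked)


def _finalize_labels(
    ruleset: RuleSet, answers: Mapping[str, str], budget: int
) -> frozenset[str]:
    """Resolved labels at session end.

    A rule can finish Kleene-UNKNOWN yet be completion-invariant (the
    same atom occurring in several leaves defeats Kleene completeness);
    such rules are settled by enumerating their undecided-subtree atoms
    and checking that every completion agrees.
    """
    labels: set[str] = set()
    for rule in ruleset.rules:
        status, influential = evaluate_influence(rule.expression, answers)
        if status is TRUE:
            labels.add(rule.label)
            continue
        if status is FALSE:
            continue
        cone = tuple(sorted(influential))
        if len(cone) > budget:
            raise EngineError(
                f"rule {rule.id!r} undecided at session end with {len(cone)} free atoms"
            )
        domains = [ruleset.atom(a).domain for a in cone]
        ext = dict(answers)
        common: TruthValue | None = None
        for combo in itertools.product(*domains):
            for a, v in zip(cone, combo):
                ext[a] = v
            val = evaluate(rule.expression, ext)
            if common is None:
                common = val
            elif val is not common:
                raise EngineError(
                    f"rule {rule.id!r} not completion-invariant at session end"
                )
        if common is TRUE:
            labels.add(rule.label)
    return frozenset(labels)


def run_session(
    bank: QuestionBank,
    responder: Callable[[Question], str],
    budget: int = DEFAULT_BUDGET,
) -> Transcript:
    """Drive a session to completion with answers from ``responder``.

    The central correctness contract: the transcript's final labels equal
    ``resolve`` on the responder's full latent assignment.
    """
    session = Session(bank=bank, budget=budget)
    while True:
        question = next_question(session)
        if question is None:
            break
        record_answer(session, question, responder(question))
    return Transcript(
        asked=tuple(session.asked),
        skipped=tuple(session.skipped),
        labels=_finalize_labels(bank.ruleset, session.answers, budget),
        approximate=frozenset(session.approximate),
    )


def replay(assignment: Mapping[str, str]) -> Callable[[Question], str]:
    """Responder that replays a full latent assignment (batch mode)."""

    def _respond(question: Question) -> str:
        try:
            return assignment[question.atom_id]
        except KeyError:
            raise BankError(f"no latent answer for atom {question.atom_id!r}") from None

    return _respond


@dataclass(frozen=True)
class CompletionOracle:
    """Brute-force ground truth over all completions of a partial answer set.

    Independent of the incremental relevance machinery: it enumerates the
    full product of the unassigned atoms' domains (refusing above budget)
    and resolves each completion.
    """

    ruleset: RuleSet
    answers: Mapping[str, str]
    budget: int = DEFAULT_BUDGET

    def unassigned(self) -> tuple[str, ...]:
        return tuple(a.id for a in self.ruleset.atoms if a.id not in self.answers)

    def _check_budget(self, free: tuple[str, ...]) -> None:
        if len(free) > self.budget:
            raise EngineError(
                f"{len(free)} unassigned atoms exceed the enumeration budget {self.budget}"
            )

    def completions(self) -> "itertools.product":
        free = self.unassigned()
        self._check_budget(free)
        domains = [self.ruleset.atom(a).domain for a in free]
        for combo in itertools.product(*domains):
            full = dict(self.answers)
            full.update(zip(free, combo))
            yield full

    def label_sets(self) -> set[frozenset[str]]:
        """Exact set of resolved-label sets over all completions."""
        return {
            resolve(self.ruleset, full, validate=False).labels
            for full in self.completions()
        }

    def is_relevant(self, atom_id: str) -> bool:
        """Ground-truth relevance: some completion's labels depend on the atom."""
        if atom_id in self.answers:
            raise EngineError(f"atom {atom_id!r} is already answered")
        free = tuple(a for a in self.unassigned() if a != atom_id)
        self._check_budget(free)
        domain = self.ruleset.atom(atom_id).domain
        domains = [self.ruleset.atom(a).domain for a in free]
        for combo in itertools.product(*domains):
            full = dict(self.answers)
            full.update(zip(free, combo))
            base = None
            for v in domain:
                full[atom_id] = v
                labels = resolve(self.ruleset, full, validate=False).labels
                if base is None:
                    base = labels
                elif labels != base:
                    return True
        return False


def enumerate_label_sets(oracle: CompletionOracle) -> set[frozenset[str]]:
    return oracle.label_sets()


# ---------------------------------------------------------------------------
# Default question bank (screening -> red flags -> attacks -> pain ->
# associated symptoms -> aura block -> chronicity/medication)
# ---------------------------------------------------------------------------

_DEFAULT_QUESTIONS: tuple[tuple[str, str, dict[str, str]], ...] = (
    ("has_headache", "Do you get headaches?", {}),
    (
        "rf_thunderclap",
        "Have you ever had a headache that became very bad in under one minute?",
        {},
    ),
    ("rf_fever_stiff_neck", "Do your headaches come with fever or a stiff neck?", {}),
    (
        "rf_neurological_deficit",
        "Have you had new weakness, trouble speaking, or loss of vision with a headache?",
        {},
    ),
    ("rf_onset_after_50", "Did your headaches first start after age 50?", {}),
    ("rf_pattern_change", "Have your headaches changed or gotten much worse lately?", {}),
    (
        "attack_count",
        "How many headache attacks like this have you had in your life?",
        {"0-1": "one or none", "2-4": "2 to 4", "5+": "5 or more"},
    ),
    (
        "duration",
        "When you do not treat it, how long does a headache attack usually last?",
        {
            "<4h": "less than 4 hours",
            "4-72h": "4 hours to 3 days",
            "72h-7d": "3 days to 1 week",
            ">7d": "more than 1 week",
        },
    ),
    ("unilateral", "Is the pain usually on one side of your head?", {}),
    ("pulsating", "Does the pain pound or throb?", {}),
    (
        "intensity",
        "How bad is the pain most of the time?",
        {"mild": "mild", "moderate": "moderate", "severe": "severe"},
    ),
    (
        "aggravation_by_activity",
        "Does walking or climbing stairs make the pain worse, or do you avoid them?",
        {},
    ),
    (
        "nausea_vomiting",
        "Do you feel sick to your stomach or throw up with the headache?",
        {},
    ),
    ("photophobia", "During a headache, does light bother you?", {}),
    ("phonophobia", "During a headache, does noise bother you?", {}),
    (
        "aura_present",
        "Before or during some headaches, do you see spots or zigzag lines, or feel tingling?",
        {},
    ),
    ("aura_fully_reversible", "Do these warning symptoms go away completely?", {}),
    (
        "aura_gradual_spread",
        "Does a warning symptom spread slowly, over five minutes or more?",
        {},
    ),
    (
        "aura_symptoms_succession",
        "Do two or more warning symptoms come one after the other?",
        {},
    ),
    (
        "aura_duration_5_60min",
        "Does each warning symptom last between five minutes and one hour?",
        {},
    ),
    ("aura_unilateral_symptom", "Is a warning symptom on one side of your body only?", {}),
    (
        "aura_positive_phenomena",
        "Do you see added things, like flickering lights or zigzag lines?",
        {},
    ),
    (
        "aura_headache_within_60min",
        "Does the headache start within one hour of the warning symptoms?",
        {},
    ),
    (
        "headache_days_month",
        "On how many days each month do you have a headache?",
        {"<15": "fewer than 15", "15+": "15 or more"},
    ),
    ("duration_over_3_months", "Has this pattern lasted three months or longer?", {}),
    (
        "med_days_month",
        "On how many days each month do you take pain medicine for headache?",
        {"<10": "fewer than 10", "10+": "10 or more"},
    ),
)


def default_question_bank(ruleset: RuleSet | None = None) -> QuestionBank:
    """The shipped question ordering over the default ICHD-3 rule set."""
    ruleset = ruleset or default_ichd_ruleset()
    questions = []
    for index, (atom_id, text, labels) in enumerate(_DEFAULT_QUESTIONS):
        if not labels:
            labels = {"yes": "yes", "no": "no"}
        questions.append(
            Question(
                id=f"q_{atom_id}",
                atom_id=atom_id,
                text=text,
                order_index=index,
                answer_labels=labels,
            )
        )
    return QuestionBank(questions=tuple(questions), ruleset=ruleset)
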