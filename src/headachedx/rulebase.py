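"""Symptom atoms, diagnostic criteria as operator trees, three-valued evaluation.

The ICHD-3 criteria for the common primary headache disorders are small
boolean-combinational structures over answers to discrete questions:
"at least 2 of the following 4 pain characteristics", "all criteria but
one fulfilled" (probable migraine), and so on.  This module represents
those criteria as operator trees over *atoms* (one atom per question,
with a small finite answer domain) and evaluates them under a partial
answer set in strong Kleene three-valued logic: an expression is TRUE or
FALSE only once the answers given so far force that value, and UNKNOWN
otherwise.  That partial evaluation is what lets an adaptive interview
skip questions whose answers can no longer matter (see ``engine``).
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property

__all__ = [
    "BankError",
    "TruthValue",
    "Atom",
    "Expression",
    "Rule",
    "RuleSet",
    "AnswerSet",
    "Impression",
    "atom_equals",
    "not_",
    "all_of",
    "any_of",
    "at_least",
    "exactly_one_false",
    "evaluate",
    "evaluate_influence",
    "resolve",
    "default_ichd_ruleset",
    "RED_FLAG_ATOMS",
    "AURA_CHARACTERISTIC_ATOMS",
    "TRACKED_SYMPTOM_ATOMS",
]


class BankError(ValueError):
    """A rule bank, expression, or answer set failed validation."""


class TruthValue(Enum):
    """Kleene truth value.  UNKNOWN only ever arises from unanswered atoms."""

    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"

    def __invert__(self) -> "TruthValue":
        if self is TruthValue.TRUE:
            return TruthValue.FALSE
        if self is TruthValue.FALSE:
            return TruthValue.TRUE
        return TruthValue.UNKNOWN

    @property
    def decided(self) -> bool:
        return self is not TruthValue.UNKNOWN


TRUE = TruthValue.TRUE
FALSE = TruthValue.FALSE
UNKNOWN = TruthValue.UNKNOWN

# Expression operator tags (also the JSON "op" discriminators, see io).
ATOM_EQUALS = "atom_equals"
NOT = "not"
ALL = "all"
ANY = "any"
AT_LEAST = "at_least"
EXACTLY_ONE_FALSE = "exactly_one_false"

_OPS = frozenset({ATOM_EQUALS, NOT, ALL, ANY, AT_LEAST, EXACTLY_ONE_FALSE})


@dataclass(frozen=True)
class Atom:
    """A single askable fact with a small finite, ordered answer domain."""

    id: str
    domain: tuple[str, ...]
    prompt_key: str = ""

    def __post_init__(self) -> None:
        if not (2 <= len(self.domain) <= 5):
            raise BankError(
                f"atom {self.id!r}: domain must have 2-5 values, got {len(self.domain)}"
            )
        if len(set(self.domain)) != len(self.domain):
            raise BankError(f"atom {self.id!r}: duplicate domain values")
        if not self.prompt_key:
            object.__setattr__(self, "prompt_key", self.id)


@dataclass(frozen=True)
class Expression:
    """Operator-tree node.

    ``atom_id``/``value`` are set only for ATOM_EQUALS leaves; ``k`` only
    for AT_LEAST.  Use the factory helpers below rather than the raw
    constructor.
    """

    op: str
    children: tuple["Expression", ...] = ()
    atom_id: str | None = None
    value: str | None = None
    k: int | None = None

    def atoms(self) -> Iterator[str]:
        """Yield every atom id referenced anywhere in this tree."""
        if self.op == ATOM_EQUALS:
            yield self.atom_id  # type: ignore[misc]
        for child in self.children:
            yield from child.atoms()

    def validate(self, atoms: Mapping[str, Atom], where: str = "expression") -> None:
        if self.op not in _OPS:
            raise BankError(f"{where}: unknown operator {self.op!r}")
        if self.op == ATOM_EQUALS:
            if self.children:
                raise BankError(f"{where}: {ATOM_EQUALS} takes no children")
            atom = atoms.get(self.atom_id or "")
            if atom is None:
                raise BankError(f"{where}: references unknown atom {self.atom_id!r}")
            if self.value not in atom.domain:
                raise BankError(
                    f"{where}: value {self.value!r} not in domain of atom {self.atom_id!r}"
                )
            return
        if not self.children:
            raise BankError(f"{where}: {self.op} requires at least one child")
        if self.op == NOT and len(self.children) != 1:
            raise BankError(f"{where}: {NOT} takes exactly one child")
        if self.op == AT_LEAST:
            if self.k is None or not (1 <= self.k <= len(self.children)):
                raise BankError(
                    f"{where}: {AT_LEAST} requires 1 <= k <= {len(self.children)}, got k={self.k}"
                )
        for i, child in enumerate(self.children):
            child.validate(atoms, where=f"{where}/{self.op}[{i}]")


def atom_equals(atom_id: str, value: str) -> Expression:
    return Expression(ATOM_EQUALS, atom_id=atom_id, value=value)


def not_(child: Expression) -> Expression:
    return Expression(NOT, (child,))


def all_of(*children: Expression) -> Expression:
    return Expression(ALL, tuple(children))


def any_of(*children: Expression) -> Expression:
    return Expression(ANY, tuple(children))


def at_least(k: int, *children: Expression) -> Expression:
    return Expression(AT_LEAST, tuple(children), k=k)


def exactly_one_false(*children: Expression) -> Expression:
    return Expression(EXACTLY_ONE_FALSE, tuple(children))


class AnswerSet(Mapping[str, str]):
    """Immutable partial assignment of answer values to atoms.

    Unassigned atoms evaluate to UNKNOWN.  Plain dicts are accepted
    everywhere an AnswerSet is; this wrapper adds validation and a
    functional update.
    """

    __slots__ = ("_data",)

    def __init__(self, assignments: Mapping[str, str] | None = None):
        self._data: dict[str, str] = dict(assignments or {})

    def __getitem__(self, key: str) -> str:
        return self._data[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __repr__(self) -> str:
        return f"AnswerSet({self._data!r})"

    def assign(self, atom_id: str, value: str) -> "AnswerSet":
        merged = dict(self._data)
        merged[atom_id] = value
        return AnswerSet(merged)


def evaluate(expr: Expression, answers: Mapping[str, str]) -> TruthValue:
    """Evaluate ``expr`` under a (possibly partial) answer set, Kleene-style.

    A decided result (TRUE/FALSE) is final: it holds in every completion
    of ``answers``.  A full answer set never yields UNKNOWN.
    """
    op = expr.op
    if op == ATOM_EQUALS:
        got = answers.get(expr.atom_id)  # type: ignore[arg-type]
        if got is None:
            return UNKNOWN
        return TRUE if got == expr.value else FALSE
    if op == NOT:
        return ~evaluate(expr.children[0], answers)
    if op == ALL:
        unknown = False
        for child in expr.children:
            s = evaluate(child, answers)
            if s is FALSE:
                return FALSE
            if s is UNKNOWN:
                unknown = True
        return UNKNOWN if unknown else TRUE
    if op == ANY:
        unknown = False
        for child in expr.children:
            s = evaluate(child, answers)
            if s is TRUE:
                return TRUE
            if s is UNKNOWN:
                unknown = True
        return UNKNOWN if unknown else FALSE
    if op == AT_LEAST:
        k = expr.k or 0
        n_true = 0
        n_unknown = 0
        remaining = len(expr.children)
        for child in expr.children:
            s = evaluate(child, answers)
            remaining -= 1
            if s is TRUE:
                n_true += 1
                if n_true >= k:
                    return TRUE
            elif s is UNKNOWN:
                n_unknown += 1
        if n_true + n_unknown < k:
            return FALSE
        return UNKNOWN
    if op == EXACTLY_ONE_FALSE:
        n_false = 0
        n_unknown = 0
        for child in expr.children:
            s = evaluate(child, answers)
            if s is FALSE:
                n_false += 1
                if n_false >= 2:
                    return FALSE
            elif s is UNKNOWN:
                n_unknown += 1
        if n_unknown:
            return UNKNOWN
        # fully decided children: TRUE iff exactly one FALSE
        return TRUE if n_false == 1 else FALSE
    raise BankError(f"unknown operator {op!r}")


def evaluate_influence(
    expr: Expression, answers: Mapping[str, str]
) -> tuple[TruthValue, frozenset[str]]:
    """Kleene value plus the set of atoms that can still move it.

    Returns ``(status, influential)`` where ``influential`` is empty when
    the status is decided, and otherwise the union of unassigned atoms
    occurring in the still-undecided subtrees.  This is a sound
    over-approximation of true influence: if changing some atom's value
    could change the expression's eventual value, that atom is in the set.
    """
    op = expr.op
    if op == ATOM_EQUALS:
        got = answers.get(expr.atom_id)  # type: ignore[arg-type]
        if got is None:
            return UNKNOWN, frozenset((expr.atom_id,))  # type: ignore[arg-type]
        return (TRUE if got == expr.value else FALSE), frozenset()
    if op == NOT:
        status, infl = evaluate_influence(expr.children[0], answers)
        return ~status, infl
    if op == ALL:
        pending: list[frozenset[str]] = []
        for child in expr.children:
            s, infl = evaluate_influence(child, answers)
            if s is FALSE:
                return FALSE, frozenset()
            if s is UNKNOWN:
                pending.append(infl)
        if not pending:
            return TRUE, frozenset()
        return UNKNOWN, frozenset().union(*pending)
    if op == ANY:
        pending = []
        for child in expr.children:
            s, infl = evaluate_influence(child, answers)
            if s is TRUE:
                return TRUE, frozenset()
            if s is UNKNOWN:
                pending.append(infl)
        if not pending:
            return FALSE, frozenset()
        return UNKNOWN, frozenset().union(*pending)
    if op == AT_LEAST:
        k = expr.k or 0
        n_true = 0
        pending = []
        for child in expr.children:
            s, infl = evaluate_influence(child, answers)
            if s is TRUE:
                n_true += 1
            elif s is UNKNOWN:
                pending.append(infl)
        if n_true >= k:
            return TRUE, frozenset()
        if n_true + len(pending) < k:
            return FALSE, frozenset()
        return UNKNOWN, frozenset().union(*pending)
    if op == EXACTLY_ONE_FALSE:
        n_false = 0
        pending = []
        for child in expr.children:
            s, infl = evaluate_influence(child, answers)
            if s is FALSE:
                n_false += 1
            elif s is UNKNOWN:
                pending.append(infl)
        if n_false >= 2:
            return FALSE, frozenset()
        if not pending:
            return (TRUE if n_false == 1 else FALSE), frozenset()
        return UNKNOWN, frozenset().union(*pending)
    raise BankError(f"unknown operator {op!r}")


@dataclass(frozen=True)
class Rule:
    """A diagnosis label tied to a criterion tree."""

    id: str
    label: str
    expression: Expression
    precedence: int = 0


@dataclass(frozen=True)
class RuleSet:
    """A closed bank of atoms plus the diagnostic rules defined over them."""

    atoms: tuple[Atom, ...]
    rules: tuple[Rule, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        ids = [a.id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise BankError("duplicate atom ids in rule set")
        labels = [r.label for r in self.rules]
        if len(set(labels)) != len(labels):
            raise BankError("duplicate rule labels in rule set")
        rule_ids = [r.id for r in self.rules]
        if len(set(rule_ids)) != len(rule_ids):
            raise BankError("duplicate rule ids in rule set")
        amap = {a.id: a for a in self.atoms}
        for rule in self.rules:
            rule.expression.validate(amap, where=f"rule {rule.id!r}")

    @cached_property
    def atom_map(self) -> dict[str, Atom]:
        return {a.id: a for a in self.atoms}

    def atom(self, atom_id: str) -> Atom:
        try:
            return self.atom_map[atom_id]
        except KeyError:
            raise BankError(f"unknown atom {atom_id!r}") from None

    def validate_answers(self, answers: Mapping[str, str]) -> None:
        for atom_id, value in answers.items():
            atom = self.atom_map.get(atom_id)
            if atom is None:
                raise BankError(f"answer references unknown atom {atom_id!r}")
            if value not in atom.domain:
                raise BankError(
                    f"value {value!r} not in domain {atom.domain!r} of atom {atom_id!r}"
                )

    def label_of(self, rule_id: str) -> str:
        for rule in self.rules:
            if rule.id == rule_id:
                return rule.label
        raise BankError(f"unknown rule {rule_id!r}")


@dataclass(frozen=True)
class Impression:
    """Per-rule statuses and the labels of rules already proven TRUE.

    ``labels`` is final for TRUE rules (decided values never change under
    refinement).  ``complete`` is True when no rule is UNKNOWN, in which
    case ``labels`` is the full resolved-label set.
    """

    statuses: Mapping[str, TruthValue]
    labels: frozenset[str]

    @property
    def complete(self) -> bool:
        return all(s is not UNKNOWN for s in self.statuses.values())


def resolve(
    ruleset: RuleSet, answers: Mapping[str, str], validate: bool = True
) -> Impression:
    """Evaluate every rule under ``answers``; collect labels of TRUE rules."""
    if validate:
        ruleset.validate_answers(answers)
    statuses: dict[str, TruthValue] = {}
    labels: set[str] = set()
    for rule in ruleset.rules:
        status = evaluate(rule.expression, answers)
        statuses[rule.id] = status
        if status is TRUE:
            labels.add(rule.label)
    return Impression(statuses=statuses, labels=frozenset(labels))


# ---------------------------------------------------------------------------
# The default ICHD-3 bank
# ---------------------------------------------------------------------------

RED_FLAG_ATOMS = (
    "rf_thunderclap",
    "rf_fever_stiff_neck",
    "rf_neurological_deficit",
    "rf_onset_after_50",
    "rf_pattern_change",
)

AURA_CHARACTERISTIC_ATOMS = (
    "aura_gradual_spread",
    "aura_symptoms_succession",
    "aura_duration_5_60min",
    "aura_unilateral_symptom",
    "aura_positive_phenomena",
    "aura_headache_within_60min",
)

#: The nine symptom atoms tracked for instrument-agreement analysis.
TRACKED_SYMPTOM_ATOMS = (
    "unilateral",
    "intensity",
    "aura_present",
    "nausea_vomiting",
    "duration",
    "pulsating",
    "photophobia",
    "phonophobia",
    "aggravation_by_activity",
)

YES_NO = ("yes", "no")


def _yes(atom_id: str) -> Expression:
    return atom_equals(atom_id, "yes")


def _no(atom_id: str) -> Expression:
    return atom_equals(atom_id, "no")


def default_ichd_ruleset() -> RuleSet:
    """The shipped reduced ICHD-3 bank: 26 atoms, 9 rules.

    Covers migraine with/without aura (1.2, 1.1), probable migraine (1.5),
    tension-type headache (2), chronic migraine (1.3), medication-overuse
    headache (8.2), a red-flag screen for suspected secondary headache,
    a catch-all "other headache", and "no headache".  Criterion E ("not
    better accounted for by another diagnosis") is approximated by the
    red-flag screen plus cross-rule exclusions inside the probable rule.
    """
    atoms = (
        Atom("has_headache", YES_NO),
        Atom("rf_thunderclap", YES_NO),
        Atom("rf_fever_stiff_neck", YES_NO),
        Atom("rf_neurological_deficit", YES_NO),
        Atom("rf_onset_after_50", YES_NO),
        Atom("rf_pattern_change", YES_NO),
        Atom("attack_count", ("0-1", "2-4", "5+")),
        Atom("duration", ("<4h", "4-72h", "72h-7d", ">7d")),
        Atom("unilateral", YES_NO),
        Atom("pulsating", YES_NO),
        Atom("intensity", ("mild", "moderate", "severe")),
        Atom("aggravation_by_activity", YES_NO),
        Atom("nausea_vomiting", YES_NO),
        Atom("photophobia", YES_NO),
        Atom("phonophobia", YES_NO),
        Atom("aura_present", YES_NO),
        Atom("aura_fully_reversible", YES_NO),
        Atom("aura_gradual_spread", YES_NO),
        Atom("aura_symptoms_succession", YES_NO),
        Atom("aura_duration_5_60min", YES_NO),
        Atom("aura_unilateral_symptom", YES_NO),
        Atom("aura_positive_phenomena", YES_NO),
        Atom("aura_headache_within_60min", YES_NO),
        Atom("headache_days_month", ("<15", "15+")),
        Atom("duration_over_3_months", YES_NO),
        Atom("med_days_month", ("<10", "10+")),
    )

    has = _yes("has_headache")
    no_red_flags = not_(any_of(*(_yes(rf) for rf in RED_FLAG_ATOMS)))

    # 1.1 migraine without aura, criterion blocks A-D
    mwoa_a = atom_equals("attack_count", "5+")
    mwoa_b = atom_equals("duration", "4-72h")
    mwoa_c = at_least(
        2,
        _yes("unilateral"),
        _yes("pulsating"),
        any_of(atom_equals("intensity", "moderate"), atom_equals("intensity", "severe")),
        _yes("aggravation_by_activity"),
    )
    mwoa_d = at_least(
        1,
        _yes("nausea_vomiting"),
        all_of(_yes("photophobia"), _yes("phonophobia")),
    )
    mwoa_core = all_of(mwoa_a, mwoa_b, mwoa_c, mwoa_d)

    # 1.2 migraine with aura, criterion blocks
    mwa_attacks = any_of(atom_equals("attack_count", "2-4"), atom_equals("attack_count", "5+"))
    mwa_reversible = _yes("aura_fully_reversible")
    mwa_chars = at_least(3, *(_yes(c) for c in AURA_CHARACTERISTIC_ATOMS))
    mwa_core = all_of(_yes("aura_present"), mwa_attacks, mwa_reversible, mwa_chars)

    # 2 tension-type headache (episodic core; 30-min lower bound folded into "<4h")
    tth_core = all_of(
        any_of(
            atom_equals("duration", "<4h"),
            atom_equals("duration", "4-72h"),
            atom_equals("duration", "72h-7d"),
        ),
        at_least(
            2,
            _no("unilateral"),
            _no("pulsating"),
            any_of(atom_equals("intensity", "mild"), atom_equals("intensity", "moderate")),
            _no("aggravation_by_activity"),
        ),
        _no("nausea_vomiting"),
        not_(all_of(_yes("photophobia"), _yes("phonophobia"))),
    )

    # 1.5 probable migraine: all blocks but one, not fulfilling another disorder.
    # The with-aura branch is gated on aura_present so the "missing" block can
    # never be the aura itself.
    probable_core = all_of(
        any_of(
            exactly_one_false(mwoa_a, mwoa_b, mwoa_c, mwoa_d),
            all_of(
                _yes("aura_present"),
                exactly_one_false(mwa_attacks, mwa_reversible, mwa_chars),
            ),
        ),
        not_(mwoa_core),
        not_(mwa_core),
        not_(tth_core),
    )

    # 1.3 chronic migraine: >=15 headache days/month for >3 months with
    # migrainous features (MwoA's C and D blocks).
    chronic_core = all_of(
        atom_equals("headache_days_month", "15+"),
        _yes("duration_over_3_months"),
        mwoa_c,
        mwoa_d,
    )

    # 8.2 medication-overuse headache
    moh_core = all_of(
        atom_equals("headache_days_month", "15+"),
        atom_equals("med_days_month", "10+"),
        _yes("duration_over_3_months"),
    )

    rules = (
        Rule(
            "r_red_flag",
            "secondary_headache_suspected",
            all_of(has, any_of(*(_yes(rf) for rf in RED_FLAG_ATOMS))),
            precedence=0,
        ),
        Rule("r_mwa", "migraine_with_aura", all_of(has, no_red_flags, mwa_core), 1),
        Rule("r_mwoa", "migraine_without_aura", all_of(has, no_red_flags, mwoa_core), 2),
        Rule("r_probable", "probable_migraine", all_of(has, no_red_flags, probable_core), 3),
        Rule("r_tth", "tension_type", all_of(has, no_red_flags, tth_core), 4),
        Rule("r_chronic", "chronic_migraine", all_of(has, no_red_flags, chronic_core), 5),
        Rule("r_moh", "medication_overuse", all_of(has, moh_core), 6),
        Rule(
            "r_other",
            "other_headache",
            all_of(
                has,
                no_red_flags,
                not_(mwa_core),
                not_(mwoa_core),
                not_(probable_core),
                not_(tth_core),
                not_(chronic_core),
            ),
            7,
        ),
        Rule("r_no_headache", "no_headache", _no("has_headache"), 8),
    )
    return RuleSet(atoms=atoms, rules=rules, version="ichd3-reduced-1")
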