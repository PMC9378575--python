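"""Synthetic respondent cohort with a two-channel response model.

Emulates the structure of a paired diagnostic-accuracy study: each
respondent has a latent headache class and a *true* full answer set; the
reference channel sees the true answers, while the index channel sees a
perturbed copy in which each symptom answer flips with a per-atom
discordance probability (rephrasing/self-report noise).  Diagnosis
discordance between the channels then arises mechanistically from
symptom-level discordance, concentrated by default on the symptoms that
require verbal rephrasing (phonophobia, photophobia, aggravation by
activity) and absent on distinctly memorable ones (aura, unilateral
pain).

The default class mixture puts 0.67 of the mass on migraine or probable
migraine, the positive-class prevalence of the study population this
module emulates (n = 202).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .engine import QuestionBank, Transcript, default_question_bank, replay, run_session
from .rulebase import (
    AURA_CHARACTERISTIC_ATOMS,
    RED_FLAG_ATOMS,
    AnswerSet,
    BankError,
    RuleSet,
    default_ichd_ruleset,
    resolve,
)

__all__ = [
    "LatentClass",
    "RespondentProfile",
    "NoiseModel",
    "PairedRecord",
    "DEFAULT_MIXTURE",
    "DEFAULT_NOISE",
    "sample_profile",
    "perturb",
    "run_study",
]


@dataclass(frozen=True)
class LatentClass:
    """A headache class and its mixture weight in the cohort."""

    label: str
    weight: float


#: Default cohort mixture; migraine + probable migraine mass = 0.67.
DEFAULT_MIXTURE: tuple[LatentClass, ...] = (
    LatentClass("migraine_without_aura", 0.32),
    LatentClass("migraine_with_aura", 0.08),
    LatentClass("probable_migraine", 0.27),
    LatentClass("tension_type", 0.18),
    LatentClass("other_headache", 0.05),
    LatentClass("no_headache", 0.10),
)

#: Qualitative calibration of the per-symptom discordance gradient:
#: largest on phonophobia/aggravation/photophobia, zero on aura and
#: unilateral pain.  These are configuration defaults, not estimates.
DEFAULT_NOISE: dict[str, float] = {
    "phonophobia": 0.32,
    "aggravation_by_activity": 0.30,
    "photophobia": 0.27,
    "pulsating": 0.18,
    "duration": 0.15,
    "intensity": 0.08,
    "nausea_vomiting": 0.04,
}


@dataclass(frozen=True)
class NoiseModel:
    """Per-atom discordance channel.

    Each atom's answer is replaced, independently with its probability,
    by a value drawn uniformly from the rest of the atom's domain.
    Atoms absent from the map are never perturbed.
    """

    probabilities: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE))

    def __post_init__(self) -> None:
        for atom_id, p in self.probabilities.items():
            if not (0.0 <= p <= 1.0):
                raise BankError(f"discordance probability for {atom_id!r} not in [0,1]: {p}")

    def probability(self, atom_id: str) -> float:
        return self.probabilities.get(atom_id, 0.0)

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(probabilities={})

    def raised(self, atom_id: str, delta: float) -> "NoiseModel":
        """Copy with one atom's discordance increased (clipped to 1)."""
        probs = dict(self.probabilities)
        probs[atom_id] = min(1.0, probs.get(atom_id, 0.0) + delta)
        return NoiseModel(probabilities=probs)


@dataclass(frozen=True)
class RespondentProfile:
    """Latent class plus the true full answer set that realises it."""

    id: str
    latent_class: str
    answers: Mapping[str, str]


@dataclass(frozen=True)
class PairedRecord:
    """One respondent's paired evaluation through both channels."""

    respondent_id: str
    latent_class: str
    reference_labels: frozenset[str]
    index_labels: frozenset[str]
    reference_answers: Mapping[str, str]
    index_answers: Mapping[str, str]


def _rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _choice(rng: np.random.Generator, values: Sequence[str]) -> str:
    return values[int(rng.integers(len(values)))]


def _random_base(ruleset: RuleSet, rng: np.random.Generator) -> dict[str, str]:
    ans = {a.id: _choice(rng, a.domain) for a in ruleset.atoms}
    ans["has_headache"] = "yes"
    for rf in RED_FLAG_ATOMS:
        ans[rf] = "no"
    # keep chronicity benign so chronic/MOH rules cannot co-fire
    ans["headache_days_month"] = "<15"
    return ans


def _ensure_mwoa_c(ans: dict[str, str], rng: np.random.Generator) -> None:
    """Force at least two of the four migraine pain characteristics."""

    def flags() -> list[bool]:
        return [
            ans["unilateral"] == "yes",
            ans["pulsating"] == "yes",
            ans["intensity"] in ("moderate", "severe"),
            ans["aggravation_by_activity"] == "yes",
        ]

    setters = (
        lambda: ans.__setitem__("unilateral", "yes"),
        lambda: ans.__setitem__("pulsating", "yes"),
        lambda: ans.__setitem__("intensity", _choice(rng, ("moderate", "severe"))),
        lambda: ans.__setitem__("aggravation_by_activity", "yes"),
    )
    while sum(flags()) < 2:
        false_idx = [i for i, f in enumerate(flags()) if not f]
        setters[false_idx[int(rng.integers(len(false_idx)))]]()


def _ensure_mwoa_d(ans: dict[str, str], rng: np.random.Generator) -> None:
    if ans["nausea_vomiting"] == "yes":
        return
    if ans["photophobia"] == "yes" and ans["phonophobia"] == "yes":
        return
    if rng.random() < 0.5:
        ans["nausea_vomiting"] = "yes"
    else:
        ans["photophobia"] = "yes"
        ans["phonophobia"] = "yes"


def _propose(label: str, ruleset: RuleSet, rng: np.random.Generator) -> dict[str, str]:
    ans = _random_base(ruleset, rng)
    if label == "no_headache":
        ans["has_headache"] = "no"
        return ans
    if label == "secondary_headache_suspected":
        for rf in RED_FLAG_ATOMS:
            ans[rf] = "yes" if rng.random() < 0.4 else "no"
        if all(ans[rf] == "no" for rf in RED_FLAG_ATOMS):
            ans[RED_FLAG_ATOMS[int(rng.integers(len(RED_FLAG_ATOMS)))]] = "yes"
        return ans
    if label == "migraine_without_aura":
        ans["attack_count"] = "5+"
        ans["duration"] = "4-72h"
        ans["aura_present"] = "no"
        _ensure_mwoa_c(ans, rng)
        _ensure_mwoa_d(ans, rng)
        return ans
    if label == "migraine_with_aura":
        ans["aura_present"] = "yes"
        ans["aura_fully_reversible"] = "yes"
        for c in AURA_CHARACTERISTIC_ATOMS:
            ans[c] = "yes" if rng.random() < 0.7 else "no"
        chars_true = [c for c in AURA_CHARACTERISTIC_ATOMS if ans[c] == "yes"]
        while len(chars_true) < 3:
            missing = [c for c in AURA_CHARACTERISTIC_ATOMS if ans[c] == "no"]
            pick = missing[int(rng.integers(len(missing)))]
            ans[pick] = "yes"
            chars_true.append(pick)
        ans["attack_count"] = _choice(rng, ("2-4", "5+"))
        # migraine-like pain (blocks tension-type) but fail MwoA's D block
        ans["unilateral"] = "yes"
        ans["pulsating"] = "yes"
        ans["intensity"] = "severe"
        ans["aggravation_by_activity"] = "yes"
        ans["nausea_vomiting"] = "no"
        ans["photophobia"] = _choice(rng, ("yes", "no"))
        ans["phonophobia"] = "no"
        return ans
    if label == "probable_migraine":
        # migraine without aura with exactly one criterion block missing
        ans["aura_present"] = "no"
        ans["attack_count"] = "5+"
        ans["duration"] = "4-72h"
        failing = _choice(rng, ("A", "B", "C", "D"))
        if failing == "A":
            ans["attack_count"] = _choice(rng, ("0-1", "2-4"))
            _ensure_mwoa_c(ans, rng)
            _ensure_mwoa_d(ans, rng)
        elif failing == "B":
            ans["duration"] = _choice(rng, ("<4h", "72h-7d", ">7d"))
            _ensure_mwoa_c(ans, rng)
            _ensure_mwoa_d(ans, rng)
        elif failing == "C":
            # one pain characteristic only; nausea keeps tension-type out
            ans["unilateral"] = "yes"
            ans["pulsating"] = "no"
            ans["intensity"] = "mild"
            ans["aggravation_by_activity"] = "no"
            ans["nausea_vomiting"] = "yes"
        else:  # D fails: no nausea, never both photo- and phonophobia
            ans["unilateral"] = "yes"
            ans["pulsating"] = "yes"
            ans["intensity"] = "severe"
            ans["aggravation_by_activity"] = "yes"
            ans["nausea_vomiting"] = "no"
            ans["photophobia"] = _choice(rng, ("yes", "no"))
            ans["phonophobia"] = "no"
        return ans
    if label == "tension_type":
        ans["duration"] = _choice(rng, ("<4h", "4-72h", "72h-7d"))
        ans["unilateral"] = "no"
        ans["pulsating"] = "no"
        ans["intensity"] = _choice(rng, ("mild", "moderate"))
        ans["aggravation_by_activity"] = "no"
        ans["nausea_vomiting"] = "no"
        ans["aura_present"] = "no"
        if ans["photophobia"] == "yes":
            ans["phonophobia"] = "no"
        return ans
    if label == "other_headache":
        ans["attack_count"] = "0-1"
        ans["duration"] = ">7d"
        ans["aura_present"] = "no"
        return ans
    raise BankError(f"no proposal distribution for latent class {label!r}")


def sample_profile(
    classes: Sequence[LatentClass],
    ruleset: RuleSet,
    rng: np.random.Generator | int | None = None,
    respondent_id: str = "r0",
    max_tries: int = 1000,
) -> RespondentProfile:
    """Draw a latent class, then a true full answer set realising it.

    The profile invariant — resolving the true answers yields exactly the
    class label — is enforced by rejection against the rule set, so it
    holds whatever bank is in use.
    """
    rng = _rng(rng)
    weights = np.array([c.weight for c in classes], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise BankError(f"class weights must sum to 1, got {weights.sum():.6f}")
    label = classes[int(rng.choice(len(classes), p=weights))].label
    for _ in range(max_tries):
        ans = _propose(label, ruleset, rng)
        impression = resolve(ruleset, ans, validate=False)
        if impression.labels == frozenset({label}):
            return RespondentProfile(id=respondent_id, latent_class=label, answers=ans)
    raise BankError(
        f"could not realise latent class {label!r} under this rule set "
        f"after {max_tries} proposals"
    )


def perturb(
    profile: RespondentProfile | Mapping[str, str],
    noise: NoiseModel,
    rng: np.random.Generator | int | None = None,
    ruleset: RuleSet | None = None,
) -> AnswerSet:
    """Apply the discordance channel; returns a full answer set."""
    rng = _rng(rng)
    ruleset = ruleset or default_ichd_ruleset()
    answers = profile.answers if isinstance(profile, RespondentProfile) else profile
    out: dict[str, str] = {}
    for atom_id, value in answers.items():
        p = noise.probability(atom_id)
        if p > 0.0 and rng.random() < p:
            alternatives = [v for v in ruleset.atom(atom_id).domain if v != value]
            value = alternatives[int(rng.integers(len(alternatives)))]
        out[atom_id] = value
    return AnswerSet(out)


def run_study(
    n: int,
    classes: Sequence[LatentClass] = DEFAULT_MIXTURE,
    noise: NoiseModel | None = None,
    ruleset: RuleSet | None = None,
    bank: QuestionBank | None = None,
    rng: np.random.Generator | int | None = None,
    engine_replay: bool = True,
    profiles: Sequence[RespondentProfile] | None = None,
) -> list[PairedRecord]:
    """Simulate a paired two-channel study of ``n`` respondents.

    Reference labels come from the true answers; index labels from
    replaying the perturbed answers through the adaptive engine (or, with
    ``engine_replay=False``, from direct rule evaluation — equivalent by
    the adaptive==exhaustive property, and much faster for large Monte
    Carlo runs).  Pre-sampled ``profiles`` may be supplied to couple
    several noise conditions to the same respondents.
    """
    if n < 1:
        raise BankError("n must be >= 1")
    rng = _rng(rng)
    noise = NoiseModel() if noise is None else noise
    ruleset = ruleset or default_ichd_ruleset()
    if bank is None and engine_replay:
        bank = default_question_bank(ruleset)
    records: list[PairedRecord] = []
    for i in range(n):
        if profiles is not None:
            profile = profiles[i]
        else:
            profile = sample_profile(classes, ruleset, rng, respondent_id=f"r{i:05d}")
        reference = resolve(ruleset, profile.answers, validate=False).labels
        perturbed = perturb(profile, noise, rng, ruleset)
        if engine_replay:
            transcript: Transcript = run_session(bank, replay(perturbed))
            index = transcript.labels
        else:
            index = resolve(ruleset, perturbed, validate=False).labels
        records.append(
            PairedRecord(
                respondent_id=profile.id,
                latent_class=profile.latent_class,
                reference_labels=reference,
                index_labels=index,
                reference_answers=dict(profile.answers),
                index_answers=dict(perturbed),
            )
        )
    return records
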