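import numpy as np
import pytest

from headachedx.engine import default_question_bank
from headachedx.rulebase import RuleSet, default_ichd_ruleset


@pytest.fixture(scope="session")
def ruleset() -> RuleSet:
    return default_ichd_ruleset()


@pytest.fixture(scope="session")
def bank(ruleset):
    return default_question_bank(ruleset)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_full_assignment(ruleset: RuleSet, rng: np.random.Generator) -> dict[str, str]:
    """Uniform full latent assignment over the bank's atom domains."""
    return {
        a.id: a.domain[int(rng.integers(len(a.domain)))] for a in ruleset.atoms
    }


def mwoa_full_answers(ruleset: RuleSet) -> dict[str, str]:
    """A full assignment satisfying every migraine-without-aura criterion."""
    answers = {a.id: "no" for a in ruleset.atoms}
    answers.update(
        has_headache="yes",
        attack_count="5+",
        duration="4-72h",
        unilateral="yes",
        pulsating="yes",
        intensity="severe",
        aggravation_by_activity="yes",
        nausea_vomiting="yes",
        photophobia="yes",
        phonophobia="yes",
        aura_present="no",
        headache_days_month="<15",
        med_days_month="<10",
    )
    return answers
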