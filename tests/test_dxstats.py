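"""Diagnostic-accuracy statistics against published values and identities."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from headachedx.dxstats import (
    CONTRASTS,
    ContingencyTable,
    StatsError,
    accuracy_at_prevalence,
    build_report,
    build_report_from_table,
    clopper_pearson,
    cohen_kappa,
    contingency_from_pairs,
    core_rates,
    fagan_posttest,
    fagan_pretest,
    format_report,
    interpret_kappa,
    likelihood_ratios,
    predictive_values_at_prevalence,
    sample_size_for_ci,
    symptom_agreement,
)

import pandas as pd

TABLE3 = ContingencyTable(tp=121, fp=2, fn=15, tn=64)


# ---------------------------------------------------------------------------
# Core rates
# ---------------------------------------------------------------------------


def test_core_rates_on_study_table():
    r = core_rates(TABLE3)
    assert r.sensitivity == pytest.approx(0.8897, abs=5e-5)
    assert r.specificity == pytest.approx(0.9697, abs=5e-5)
    assert r.accuracy == pytest.approx(0.9158, abs=5e-5)
    assert r.ppv == pytest.approx(0.9837, abs=5e-5)
    assert r.npv == pytest.approx(0.8101, abs=5e-5)


def test_core_rates_degenerate_tables():
    perfect = core_rates(ContingencyTable(5, 0, 0, 5))
    assert (perfect.sensitivity, perfect.specificity, perfect.ppv, perfect.npv) == (
        1.0,
        1.0,
        1.0,
        1.0,
    )
    no_positives = core_rates(ContingencyTable(0, 0, 5, 5))
    assert no_positives.sensitivity == 0.0
    assert no_positives.specificity == 1.0
    assert math.isnan(no_positives.ppv)
    assert "ppv-undefined" in no_positives.flags


def test_accuracy_at_prevalence_identity():
    r = core_rates(TABLE3)
    transported = accuracy_at_prevalence(r.sensitivity, r.specificity, TABLE3.prevalence)
    assert transported == pytest.approx(r.accuracy, abs=1e-12)
    assert accuracy_at_prevalence(0.7, 0.7, 0.3) == pytest.approx(0.7)
    assert accuracy_at_prevalence(1.0, 1.0, 0.3) == 1.0


def test_predictive_value_transport():
    r = core_rates(TABLE3)
    ppv, npv = predictive_values_at_prevalence(r.sensitivity, r.specificity, 0.10)
    assert ppv == pytest.approx(0.765, abs=5e-4)
    assert npv == pytest.approx(0.988, abs=5e-4)
    # at the study's own prevalence the transport matches the counts
    ppv_s, npv_s = predictive_values_at_prevalence(
        r.sensitivity, r.specificity, TABLE3.prevalence
    )
    assert ppv_s == pytest.approx(r.ppv, abs=1e-12)
    assert npv_s == pytest.approx(r.npv, abs=1e-12)


def test_predictive_values_at_degenerate_prevalence():
    # at prevalence 1 every negative call is wrong: NPV = 0 while the
    # denominator is positive, NaN only when it vanishes (sens = 1 too)
    ppv, npv = predictive_values_at_prevalence(0.9, 0.9, 1.0)
    assert ppv == 1.0
    assert npv == 0.0
    _, npv_nan = predictive_values_at_prevalence(1.0, 0.9, 1.0)
    assert math.isnan(npv_nan)


@pytest.mark.parametrize("tp,fp,fn,tn", [(7, 3, 2, 8), (12, 5, 1, 30), (1, 1, 1, 1)])
def test_transport_identity_on_random_tables(tp, fp, fn, tn):
    t = ContingencyTable(tp, fp, fn, tn)
    r = core_rates(t)
    ppv, npv = predictive_values_at_prevalence(r.sensitivity, r.specificity, t.prevalence)
    assert ppv == pytest.approx(r.ppv, abs=1e-12)
    assert npv == pytest.approx(r.npv, abs=1e-12)
    assert accuracy_at_prevalence(
        r.sensitivity, r.specificity, t.prevalence
    ) == pytest.approx(r.accuracy, abs=1e-12)


# ---------------------------------------------------------------------------
# Clopper-Pearson
# ---------------------------------------------------------------------------


def test_clopper_pearson_reproduces_published_sensitivity_interval():
    ci = clopper_pearson(121, 136, 0.95)
    assert round(ci.lower, 3) == 0.825
    assert round(ci.upper, 3) == 0.937


def test_clopper_pearson_boundary_counts():
    assert clopper_pearson(0, 10).lower == 0.0
    assert clopper_pearson(10, 10).upper == 1.0
    with pytest.raises(StatsError):
        clopper_pearson(11, 10)


@pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
def test_clopper_pearson_exact_coverage_at_least_nominal(p):
    """Coverage computed exactly by summing the binomial pmf at n=30."""
    n, conf = 30, 0.95
    coverage = sum(
        sps.binom.pmf(x, n, p)
        for x in range(n + 1)
        if clopper_pearson(x, n, conf).lower <= p <= clopper_pearson(x, n, conf).upper
    )
    assert coverage >= conf - 1e-9


# ---------------------------------------------------------------------------
# Kappa
# ---------------------------------------------------------------------------


def test_kappa_on_study_table():
    k = cohen_kappa(TABLE3)
    assert round(k.kappa, 2) == 0.82
    assert round(k.ci.lower, 2) == 0.74
    assert round(k.ci.upper, 2) == 0.90
    assert k.interpretation == "almost perfect agreement"


def test_kappa_perfect_and_chance_agreement():
    assert cohen_kappa(ContingencyTable(50, 0, 0, 50)).kappa == pytest.approx(1.0)
    assert cohen_kappa(ContingencyTable(25, 25, 25, 25)).kappa == pytest.approx(0.0)


@pytest.mark.parametrize("tp,fp,fn,tn", [(10, 3, 5, 20), (40, 1, 2, 7), (3, 3, 3, 3)])
def test_kappa_properties(tp, fp, fn, tn):
    t = ContingencyTable(tp, fp, fn, tn)
    k = cohen_kappa(t)
    assert k.kappa == pytest.approx((k.p_observed - k.p_expected) / (1 - k.p_expected))
    assert k.kappa <= k.p_observed + 1e-12
    assert (k.kappa == pytest.approx(1.0)) == (fp == 0 and fn == 0)
    transposed = cohen_kappa(ContingencyTable(tp, fn, fp, tn))
    assert transposed.kappa == pytest.approx(k.kappa)


@pytest.mark.parametrize(
    "value, label",
    [
        (-0.2, "no agreement"),
        (0.1, "none to slight agreement"),
        (0.3, "fair agreement"),
        (0.5, "moderate agreement"),
        (0.7, "substantial agreement"),
        (0.9, "almost perfect agreement"),
    ],
)
def test_kappa_interpretation_bins(value, label):
    assert interpret_kappa(value) == label


# ---------------------------------------------------------------------------
# Likelihood ratios and Fagan updates
# ---------------------------------------------------------------------------


def test_likelihood_ratios_on_study_table():
    lr_pos, lr_neg = likelihood_ratios(TABLE3)
    assert round(lr_pos.point, 1) == 29.4
    assert round(lr_pos.lower, 1) == 7.5
    assert round(lr_pos.upper, 1) == 115.1
    assert lr_neg.point == pytest.approx(0.114, abs=5e-4)
    assert round(lr_neg.lower, 2) == 0.07
    assert round(lr_neg.upper, 2) == 0.18


def test_uninformative_test_has_unit_likelihood_ratios():
    lr_pos, lr_neg = likelihood_ratios(ContingencyTable(5, 5, 5, 5))
    assert lr_pos.point == pytest.approx(1.0)
    assert lr_neg.point == pytest.approx(1.0)


def test_perfect_table_likelihood_ratios():
    lr_pos, lr_neg = likelihood_ratios(ContingencyTable(8, 0, 0, 12))
    assert math.isinf(lr_pos.point)
    assert "infinite" in lr_pos.flags
    assert lr_neg.point == 0.0
    assert "continuity-corrected" in lr_neg.flags


def test_fagan_update_on_study_likelihood_ratios():
    lr_pos, lr_neg = likelihood_ratios(TABLE3)
    assert round(fagan_posttest(0.50, lr_pos.point).posttest, 2) == 0.97
    assert round(fagan_posttest(0.50, lr_neg.point).posttest, 2) == 0.10
    # with the rounded LR the published "18%" at the 67% clinic prevalence
    assert round(fagan_posttest(136 / 202, 0.11).posttest, 2) == 0.18
    assert fagan_posttest(0.3, 1.0).posttest == pytest.approx(0.3)


def test_fagan_degenerate_pretest_flagged():
    result = fagan_posttest(0.0, 5.0)
    assert result.posttest == 0.0
    assert "degenerate" in result.flags


@pytest.mark.parametrize("q,lr", [(0.2, 3.0), (0.9, 0.4), (0.5, 29.36)])
def test_fagan_round_trip(q, lr):
    assert fagan_posttest(fagan_pretest(q, lr), lr).posttest == pytest.approx(q)


# ---------------------------------------------------------------------------
# Sample sizing
# ---------------------------------------------------------------------------


def test_sample_size_reproduces_study_protocol():
    sens = sample_size_for_ci(0.80, 0.15, 0.85, group_fraction=0.35)
    spec = sample_size_for_ci(0.80, 0.15, 0.85, group_fraction=0.65)
    assert sens.total_n == 203
    assert spec.total_n == 110
    assert sens.group_size == spec.group_size  # same proportion and width


def test_sample_size_minimality():
    spec = sample_size_for_ci(0.80, 0.15, 0.85, group_fraction=0.35)
    m = spec.group_size
    below = clopper_pearson(round(0.80 * (m - 1)), m - 1, 0.85)
    assert below.upper - below.lower > 0.15


def test_sample_size_vacuous_width():
    spec = sample_size_for_ci(0.80, 1.0, 0.85, group_fraction=1.0)
    assert spec.group_size == 1
    assert spec.total_n == 1


# ---------------------------------------------------------------------------
# Contrasts, tables from pairs, symptom agreement
# ---------------------------------------------------------------------------


def _pairs(n, ref, idx):
    return [(frozenset(ref), frozenset(idx))] * n


def test_contingency_from_pairs_recovers_margins():
    records = (
        _pairs(121, {"migraine_without_aura"}, {"migraine_without_aura"})
        + _pairs(2, {"tension_type"}, {"probable_migraine"})
        + _pairs(15, {"probable_migraine"}, {"tension_type"})
        + _pairs(64, {"no_headache"}, {"other_headache"})
    )
    t = contingency_from_pairs(records, CONTRASTS["mpm_vs_nom"])
    assert (t.tp, t.fp, t.fn, t.tn) == (121, 2, 15, 64)
    assert t.excluded == 0
    assert t.discordant == 17


def test_all_concordant_positive_records():
    t = contingency_from_pairs(
        _pairs(9, {"migraine_with_aura"}, {"migraine_with_aura"}),
        CONTRASTS["mpm_vs_nom"],
    )
    assert (t.tp, t.fp, t.fn, t.tn) == (9, 0, 0, 0)


def test_migraine_only_contrast_excludes_reference_probable():
    records = (
        _pairs(10, {"migraine_without_aura"}, {"migraine_without_aura"})
        + _pairs(4, {"probable_migraine"}, {"migraine_without_aura"})
        + _pairs(6, {"tension_type"}, {"tension_type"})
    )
    t = contingency_from_pairs(records, CONTRASTS["m_vs_nom"])
    assert t.excluded == 4
    assert t.n == 16


def test_symptom_agreement_fractions():
    rows = []
    for i in range(17):
        rows.append(
            {
                "respondent_id": f"r{i}",
                "atom_id": "phonophobia",
                "reference_value": "yes",
                "index_value": "yes" if i < 8 else "no",
            }
        )
        rows.append(
            {
                "respondent_id": f"r{i}",
                "atom_id": "unilateral",
                "reference_value": "yes",
                "index_value": "yes",
            }
        )
    pairs = pd.DataFrame(rows)
    agreement = symptom_agreement(
        pairs, ["phonophobia", "unilateral"], [f"r{i}" for i in range(17)]
    )
    assert agreement["phonophobia"] == pytest.approx(8 / 17)
    assert round(100 * agreement["phonophobia"]) == 47
    assert agreement["unilateral"] == 1.0


def test_symptom_agreement_empty_subset_errors():
    pairs = pd.DataFrame(
        [{"respondent_id": "r0", "atom_id": "a", "reference_value": "x", "index_value": "x"}]
    )
    with pytest.raises(StatsError, match="empty"):
        symptom_agreement(pairs, ["a"], [])


# ---------------------------------------------------------------------------
# Full report assembly
# ---------------------------------------------------------------------------


def test_report_from_study_table_collects_all_published_numbers():
    report = build_report_from_table(TABLE3, extra_prevalences=[0.10])
    assert round(100 * report.sensitivity.point, 1) == 89.0
    assert round(100 * report.specificity.point, 1) == 97.0
    assert round(100 * report.accuracy.point, 1) == 91.6
    assert round(100 * report.ppv.point, 1) == 98.4
    assert round(100 * report.npv.point, 1) == 81.0
    assert round(report.kappa.kappa, 2) == 0.82
    assert round(report.lr_pos.point, 1) == 29.4
    assert round(report.lr_neg.point, 2) == 0.11
    assert report.discordant_count == 17
    scenario = report.transported[0]
    assert round(100 * scenario.ppv.point, 1) == 76.5
    assert round(100 * scenario.npv.point, 1) == 98.8
    text = format_report(report)
    assert "89.0%" in text and "97.0%" in text and "0.82" in text


def test_report_round_trips_to_dict():
    payload = build_report_from_table(TABLE3, extra_prevalences=[0.10]).to_dict()
    assert payload["table"]["tp"] == 121
    assert payload["kappa"]["interpretation"] == "almost perfect agreement"
    assert payload["fagan"]["positive_at_50"] == pytest.approx(0.967, abs=5e-4)


def test_report_from_concordant_records_has_perfect_kappa():
    records = _pairs(6, {"migraine_without_aura"}, {"migraine_without_aura"}) + _pairs(
        4, {"no_headache"}, {"no_headache"}
    )
    report = build_report(records, contrast="mpm_vs_nom", extra_prevalences=())
    assert report.kappa.kappa == pytest.approx(1.0)
    assert report.discordant_count == 0


def test_report_requires_records():
    with pytest.raises(StatsError):
        build_report([], contrast="mpm_vs_nom")
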