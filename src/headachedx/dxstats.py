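"""Diagnostic-accuracy statistics for a paired binary classification study.

Everything derivable from a 2x2 contingency table of an index test
against a reference standard: sensitivity/specificity/accuracy and
predictive values with exact Clopper-Pearson intervals, unweighted
Cohen's kappa with its asymptotic interval and the conventional
interpretation bins, likelihood ratios with log-method intervals,
prevalence transport of predictive values, Fagan (Bayes) pre-to-post-test
probability updates, exact-CI sample sizing, and per-symptom agreement
on the diagnosis-discordant subset.

Proportion CIs use the Clopper-Pearson exact method (Beta quantiles).
Predictive values at a *hypothetical* prevalence carry logit-transform
(Mercaldo-style) intervals, tagged as such.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

__all__ = [
    "Contrast",
    "CONTRASTS",
    "ContingencyTable",
    "IntervalEstimate",
    "KappaResult",
    "FaganResult",
    "SampleSizeSpec",
    "AccuracyReport",
    "MIGRAINE_LABELS",
    "PROBABLE_LABELS",
    "contingency_from_pairs",
    "core_rates",
    "accuracy_at_prevalence",
    "predictive_values_at_prevalence",
    "likelihood_ratios",
    "cohen_kappa",
    "interpret_kappa",
    "clopper_pearson",
    "fagan_posttest",
    "fagan_pretest",
    "sample_size_for_ci",
    "symptom_agreement",
    "build_report",
    "build_report_from_table",
    "format_report",
]


class StatsError(ValueError):
    """Invalid input to a diagnostic-accuracy computation."""


MIGRAINE_LABELS = frozenset(
    {"migraine_with_aura", "migraine_without_aura", "chronic_migraine"}
)
PROBABLE_LABELS = frozenset({"probable_migraine"})


@dataclass(frozen=True)
class Contrast:
    """A positive/negative dichotomy over resolved-label sets.

    A label set is positive when it intersects ``positive_labels``,
    excluded when it (only) intersects ``excluded_labels``, and negative
    otherwise.  Exclusion is applied to the reference channel when
    building contingency tables.
    """

    name: str
    positive_labels: frozenset[str]
    excluded_labels: frozenset[str] = frozenset()

    def classify(self, labels: frozenset[str] | set[str]) -> str:
        if labels & self.positive_labels:
            return "positive"
        if labels & self.excluded_labels:
            return "excluded"
        return "negative"


#: The three shipped outcome contrasts.
CONTRASTS: dict[str, Contrast] = {
    "mpm_vs_nom": Contrast("mpm_vs_nom", MIGRAINE_LABELS | PROBABLE_LABELS),
    "m_vs_nom": Contrast("m_vs_nom", MIGRAINE_LABELS, excluded_labels=PROBABLE_LABELS),
    "m_vs_nompm": Contrast("m_vs_nompm", MIGRAINE_LABELS),
}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of index test against the reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int
    excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0 or self.excluded < 0:
            raise StatsError("contingency counts must be non-negative")
        if self.n < 1:
            raise StatsError("contingency table must contain at least one record")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def diseased(self) -> int:
        return self.tp + self.fn

    @property
    def non_diseased(self) -> int:
        return self.fp + self.tn

    @property
    def prevalence(self) -> float:
        return self.diseased / self.n

    @property
    def discordant(self) -> int:
        """False positives + false negatives."""
        return self.fp + self.fn


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = ""
    flags: tuple[str, ...] = ()

    @property
    def defined(self) -> bool:
        return "undefined" not in self.flags


def _undefined(level: float, method: str) -> IntervalEstimate:
    return IntervalEstimate(
        point=math.nan,
        lower=math.nan,
        upper=math.nan,
        level=level,
        method=method,
        flags=("undefined",),
    )


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> IntervalEstimate:
    """Exact binomial interval from Beta quantiles."""
    if not (0 <= x <= n) or n < 1:
        raise StatsError(f"invalid counts x={x}, n={n}")
    if not (0.0 < conf < 1.0):
        raise StatsError(f"confidence level must be in (0,1), got {conf}")
    alpha = 1.0 - conf
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return IntervalEstimate(
        point=x / n, lower=lower, upper=upper, level=conf, method="clopper-pearson"
    )


@dataclass(frozen=True)
class Rates:
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    flags: tuple[str, ...] = ()


def core_rates(t: ContingencyTable) -> Rates:
    """Point estimates; zero denominators flag the rate as undefined (NaN)."""
    flags: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(f"{name}-undefined")
            return math.nan
        return num / den

    return Rates(
        sensitivity=ratio(t.tp, t.tp + t.fn, "sensitivity"),
        specificity=ratio(t.tn, t.tn + t.fp, "specificity"),
        accuracy=(t.tp + t.tn) / t.n,
        ppv=ratio(t.tp, t.tp + t.fp, "ppv"),
        npv=ratio(t.tn, t.tn + t.fn, "npv"),
        flags=tuple(flags),
    )


def accuracy_at_prevalence(sens: float, spec: float, prev: float) -> float:
    """Overall accuracy transported to a prevalence:
    sensitivity x prevalence + specificity x (1 - prevalence)."""
    for name, v in (("sensitivity", sens), ("specificity", spec), ("prevalence", prev)):
        if not (0.0 <= v <= 1.0):
            raise StatsError(f"{name} must be in [0,1], got {v}")
    return sens * prev + spec * (1.0 - prev)


def predictive_values_at_prevalence(
    sens: float, spec: float, prev: float
) -> tuple[float, float]:
    """Bayes transport of PPV/NPV to an assumed prevalence.

    Degenerate prevalences yield NaN for the undefined member (e.g. NPV
    at prevalence 1: there are no negatives to predict).
    """
    for name, v in (("sensitivity", sens), ("specificity", spec), ("prevalence", prev)):
        if not (0.0 <= v <= 1.0):
            raise StatsError(f"{name} must be in [0,1], got {v}")
    ppv_den = sens * prev + (1.0 - spec) * (1.0 - prev)
    npv_den = spec * (1.0 - prev) + (1.0 - sens) * prev
    ppv = sens * prev / ppv_den if ppv_den > 0 else math.nan
    npv = spec * (1.0 - prev) / npv_den if npv_den > 0 else math.nan
    return ppv, npv


def _pv_logit_interval(
    pv: float, variance: float, level: float, method: str
) -> IntervalEstimate:
    """Logit-scale (Mercaldo-style) interval around a predictive value."""
    if math.isnan(pv) or pv <= 0.0 or pv >= 1.0 or variance <= 0:
        return IntervalEstimate(
            pv, pv, pv, level=level, method=method, flags=("degenerate",)
        )
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    logit = math.log(pv / (1.0 - pv))
    half = z * math.sqrt(variance)
    lo = 1.0 / (1.0 + math.exp(-(logit - half)))
    hi = 1.0 / (1.0 + math.exp(-(logit + half)))
    return IntervalEstimate(pv, lo, hi, level=level, method=method)


def predictive_value_intervals_at_prevalence(
    t: ContingencyTable, prev: float, conf: float = 0.95
) -> tuple[IntervalEstimate, IntervalEstimate]:
    """PPV/NPV at an assumed prevalence with logit-transform intervals."""
    r = core_rates(t)
    ppv, npv = predictive_values_at_prevalence(r.sensitivity, r.specificity, prev)
    n1, n0 = t.diseased, t.non_diseased
    sens, spec = r.sensitivity, r.specificity
    var_ppv = var_npv = math.nan
    if 0 < sens < 1 and 0 < spec < 1 and n1 > 0 and n0 > 0:
        var_ppv = (1.0 - sens) / (sens * n1) + spec / ((1.0 - spec) * n0)
        var_npv = sens / ((1.0 - sens) * n1) + (1.0 - spec) / (spec * n0)
    method = "logit-transform"
    return (
        _pv_logit_interval(ppv, var_ppv, conf, method),
        _pv_logit_interval(npv, var_npv, conf, method),
    )


def likelihood_ratios(
    t: ContingencyTable, conf: float = 0.95
) -> tuple[IntervalEstimate, IntervalEstimate]:
    """LR+ = sens/(1-spec), LR- = (1-sens)/spec, log-method intervals.

    Point estimates come from the raw counts (LR+ is +inf, flagged, for a
    perfect specificity column).  When any cell needed by the standard
    error is zero, the interval is computed from a 0.5-added table and
    flagged ``continuity-corrected``.
    """
    r = core_rates(t)
    z = float(stats.norm.ppf(0.5 + conf / 2.0))

    def log_interval(
        point: float, a: float, a_tot: float, b: float, b_tot: float, flags: list[str]
    ) -> tuple[float, float]:
        se = math.sqrt(1.0 / a - 1.0 / a_tot + 1.0 / b - 1.0 / b_tot)
        ratio = (a / a_tot) / (b / b_tot)
        centre = math.log(ratio)
        return math.exp(centre - z * se), math.exp(centre + z * se)

    tp, fp, fn, tn = float(t.tp), float(t.fp), float(t.fn), float(t.tn)
    corrected = min(t.tp, t.fp, t.fn, t.tn) == 0
    if corrected:
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    cc_flag = ("continuity-corrected",) if corrected else ()

    # LR+
    if r.specificity == 1.0:
        lr_pos_point = math.inf
        flags: tuple[str, ...] = ("infinite",) + cc_flag
    else:
        lr_pos_point = r.sensitivity / (1.0 - r.specificity)
        flags = cc_flag
    lo, hi = log_interval(lr_pos_point, tp, tp + fn, fp, fp + tn, [])
    if math.isinf(lr_pos_point):
        hi = math.inf
    lr_pos = IntervalEstimate(lr_pos_point, lo, hi, conf, "simel-log", flags)

    # LR-
    if r.specificity == 0.0:
        lr_neg = _undefined(conf, "simel-log")
    else:
        lr_neg_point = (1.0 - r.sensitivity) / r.specificity
        lo, hi = log_interval(lr_neg_point, fn, tp + fn, tn, fp + tn, [])
        if lr_neg_point == 0.0:
            lo = 0.0
        lr_neg = IntervalEstimate(lr_neg_point, lo, hi, conf, "simel-log", cc_flag)
    return lr_pos, lr_neg


_KAPPA_BINS = (
    (0.00, "no agreement"),
    (0.20, "none to slight agreement"),
    (0.40, "fair agreement"),
    (0.60, "moderate agreement"),
    (0.80, "substantial agreement"),
    (1.00, "almost perfect agreement"),
)


def interpret_kappa(kappa: float) -> str:
    """Cohen's conventional interpretation bins (0.81-1.00 almost perfect...)."""
    for upper, label in _KAPPA_BINS:
        if kappa <= upper + 1e-12:
            return label
    return _KAPPA_BINS[-1][1]


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    se: float
    ci: IntervalEstimate
    interpretation: str


def cohen_kappa(t: ContingencyTable, conf: float = 0.95) -> KappaResult:
    """Unweighted Cohen's kappa between the two instruments on the 2x2 table.

    Asymptotic standard error sqrt(p_o(1-p_o) / (n (1-p_e)^2)) with a
    normal interval clipped to [-1, 1].
    """
    if t.n < 2:
        raise StatsError("kappa requires at least two paired records")
    n = t.n
    p_o = (t.tp + t.tn) / n
    p_e = ((t.tp + t.fp) * (t.tp + t.fn) + (t.fn + t.tn) * (t.fp + t.tn)) / (n * n)
    if p_e >= 1.0:
        return KappaResult(
            kappa=math.nan,
            p_observed=p_o,
            p_expected=p_e,
            se=math.nan,
            ci=_undefined(conf, "asymptotic-normal"),
            interpretation="undefined",
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = math.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2))
    z = float(stats.norm.ppf(0.5 + conf / 2.0))
    ci = IntervalEstimate(
        point=kappa,
        lower=max(-1.0, kappa - z * se),
        upper=min(1.0, kappa + z * se),
        level=conf,
        method="asymptotic-normal",
    )
    return KappaResult(
        kappa=kappa,
        p_observed=p_o,
        p_expected=p_e,
        se=se,
        ci=ci,
        interpretation=interpret_kappa(kappa),
    )


@dataclass(frozen=True)
class FaganResult:
    """Bayes update: post-odds = pre-odds x LR."""

    pretest: float
    likelihood_ratio: float
    posttest: float
    flags: tuple[str, ...] = ()


def fagan_posttest(pretest: float, lr: float) -> FaganResult:
    if not (0.0 <= pretest <= 1.0):
        raise StatsError(f"pretest probability must be in [0,1], got {pretest}")
    if lr < 0.0:
        raise StatsError(f"likelihood ratio must be non-negative, got {lr}")
    if pretest in (0.0, 1.0):
        return FaganResult(pretest, lr, pretest, flags=("degenerate",))
    odds = pretest / (1.0 - pretest) * lr
    return FaganResult(pretest, lr, odds / (1.0 + odds))


def fagan_pretest(posttest: float, lr: float) -> float:
    """Inverse update: the pretest probability that maps to ``posttest``."""
    if not (0.0 < posttest < 1.0):
        raise StatsError(f"posttest probability must be in (0,1), got {posttest}")
    if lr <= 0.0:
        raise StatsError(f"likelihood ratio must be positive, got {lr}")
    pre_odds = posttest / (1.0 - posttest) / lr
    return pre_odds / (1.0 + pre_odds)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Exact-CI width sample sizing for one proportion.

    ``group_size`` is the minimal group (e.g. diseased) size whose
    two-sided Clopper-Pearson interval at the anticipated proportion has
    width at most ``max_width``; ``total_n`` scales it by the fraction of
    the cohort expected to land in that group.
    """

    proportion: float
    max_width: float
    conf: float
    group_fraction: float
    group_size: int
    total_n: int


def sample_size_for_ci(
    p: float, max_width: float, conf: float, group_fraction: float = 1.0
) -> SampleSizeSpec:
    if not (0.0 < p < 1.0):
        raise StatsError(f"anticipated proportion must be in (0,1), got {p}")
    if not (0.0 < max_width < 1.0 or max_width == 1.0):
        raise StatsError(f"max CI width must be in (0,1], got {max_width}")
    if not (0.0 < group_fraction <= 1.0):
        raise StatsError(f"group fraction must be in (0,1], got {group_fraction}")
    m = 1
    while True:
        x = round(p * m)
        ci = clopper_pearson(x, m, conf)
        if ci.upper - ci.lower <= max_width:
            break
        m += 1
    return SampleSizeSpec(
        proportion=p,
        max_width=max_width,
        conf=conf,
        group_fraction=group_fraction,
        group_size=m,
        total_n=math.ceil(m / group_fraction),
    )


# ---------------------------------------------------------------------------
# From paired records to tables and reports
# ---------------------------------------------------------------------------


def contingency_from_pairs(
    records: Iterable[tuple[frozenset[str] | set[str], frozenset[str] | set[str]]],
    contrast: Contrast,
) -> ContingencyTable:
    """Cross-classify (reference labels, index labels) pairs.

    The reference channel defines disease status; the index channel the
    test result.  Records whose *reference* labels match the contrast's
    exclusion predicate are dropped and counted in ``excluded``.
    """
    tp = fp = fn = tn = excluded = 0
    for reference, index in records:
        ref_class = contrast.classify(frozenset(reference))
        if ref_class == "excluded":
            excluded += 1
            continue
        idx_positive = bool(frozenset(index) & contrast.positive_labels)
        if ref_class == "positive":
            tp += idx_positive
            fn += not idx_positive
        else:
            fp += idx_positive
            tn += not idx_positive
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn, excluded=excluded)


def symptom_agreement(
    pairs: pd.DataFrame,
    atoms: Sequence[str],
    subset: Iterable[str],
) -> dict[str, float]:
    """Per-atom agreement fraction between the two channels.

    ``pairs`` is long-format with columns respondent_id, atom_id,
    reference_value, index_value; ``subset`` is the respondent ids to
    restrict to (typically the diagnosis-discordant participants).
    """
    subset = set(subset)
    if not subset:
        raise StatsError("symptom agreement requested for an empty respondent subset")
    sub = pairs[pairs["respondent_id"].isin(subset)]
    out: dict[str, float] = {}
    for atom_id in atoms:
        rows = sub[sub["atom_id"] == atom_id]
        if rows.empty:
            raise StatsError(f"no answer pairs for atom {atom_id!r} in the subset")
        out[atom_id] = float(
            (rows["reference_value"] == rows["index_value"]).mean()
        )
    return out


@dataclass(frozen=True)
class PrevalenceScenario:
    prevalence: float
    ppv: IntervalEstimate
    npv: IntervalEstimate
    accuracy: float


@dataclass(frozen=True)
class AccuracyReport:
    """Everything the study computes for one contrast."""

    contrast: str
    table: ContingencyTable
    prevalence: IntervalEstimate
    sensitivity: IntervalEstimate
    specificity: IntervalEstimate
    accuracy: IntervalEstimate
    ppv: IntervalEstimate
    npv: IntervalEstimate
    lr_pos: IntervalEstimate
    lr_neg: IntervalEstimate
    kappa: KappaResult
    fagan_positive_50: FaganResult
    fagan_negative_50: FaganResult
    fagan_positive_study: FaganResult
    fagan_negative_study: FaganResult
    transported: tuple[PrevalenceScenario, ...] = ()
    symptom_agreement: Mapping[str, float] = field(default_factory=dict)
    discordant_count: int = 0

    def to_dict(self) -> dict:
        def interval(ci: IntervalEstimate) -> dict:
            return {
                "point": ci.point,
                "lower": ci.lower,
                "upper": ci.upper,
                "level": ci.level,
                "method": ci.method,
                "flags": list(ci.flags),
            }

        return {
            "contrast": self.contrast,
            "table": {
                "tp": self.table.tp,
                "fp": self.table.fp,
                "fn": self.table.fn,
                "tn": self.table.tn,
                "excluded": self.table.excluded,
                "n": self.table.n,
            },
            "prevalence": interval(self.prevalence),
            "kappa": {
                "point": self.kappa.kappa,
                "ci": interval(self.kappa.ci),
                "p_observed": self.kappa.p_observed,
                "p_expected": self.kappa.p_expected,
                "se": self.kappa.se,
                "interpretation": self.kappa.interpretation,
            },
            "accuracy": interval(self.accuracy),
            "sensitivity": interval(self.sensitivity),
            "specificity": interval(self.specificity),
            "ppv": interval(self.ppv),
            "npv": interval(self.npv),
            "lr_pos": interval(self.lr_pos),
            "lr_neg": interval(self.lr_neg),
            "fagan": {
                "positive_at_50": self.fagan_positive_50.posttest,
                "negative_at_50": self.fagan_negative_50.posttest,
                "positive_at_study_prevalence": self.fagan_positive_study.posttest,
                "negative_at_study_prevalence": self.fagan_negative_study.posttest,
            },
            "transported": [
                {
                    "prevalence": s.prevalence,
                    "ppv": interval(s.ppv),
                    "npv": interval(s.npv),
                    "accuracy": s.accuracy,
                }
                for s in self.transported
            ],
            "symptom_agreement": dict(self.symptom_agreement),
            "discordant_count": self.discordant_count,
        }


def build_report_from_table(
    table: ContingencyTable,
    contrast: str = "mpm_vs_nom",
    extra_prevalences: Sequence[float] = (),
    conf: float = 0.95,
    symptom_agreement_rates: Mapping[str, float] | None = None,
) -> AccuracyReport:
    """Assemble the full report from a 2x2 table."""
    rates = core_rates(table)
    lr_pos, lr_neg = likelihood_ratios(table, conf)
    kappa = cohen_kappa(table, conf)
    transported = []
    for prev in extra_prevalences:
        ppv_ci, npv_ci = predictive_value_intervals_at_prevalence(table, prev, conf)
        transported.append(
            PrevalenceScenario(
                prevalence=prev,
                ppv=ppv_ci,
                npv=npv_ci,
                accuracy=accuracy_at_prevalence(
                    rates.sensitivity, rates.specificity, prev
                ),
            )
        )
    study_prev = table.prevalence
    lr_neg_point = lr_neg.point if lr_neg.defined else math.nan
    return AccuracyReport(
        contrast=contrast,
        table=table,
        prevalence=clopper_pearson(table.diseased, table.n, conf),
        sensitivity=clopper_pearson(table.tp, table.diseased, conf)
        if table.diseased
        else _undefined(conf, "clopper-pearson"),
        specificity=clopper_pearson(table.tn, table.non_diseased, conf)
        if table.non_diseased
        else _undefined(conf, "clopper-pearson"),
        accuracy=clopper_pearson(table.tp + table.tn, table.n, conf),
        ppv=clopper_pearson(table.tp, table.tp + table.fp, conf)
        if table.tp + table.fp
        else _undefined(conf, "clopper-pearson"),
        npv=clopper_pearson(table.tn, table.tn + table.fn, conf)
        if table.tn + table.fn
        else _undefined(conf, "clopper-pearson"),
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        kappa=kappa,
        fagan_positive_50=fagan_posttest(0.5, lr_pos.point),
        fagan_negative_50=fagan_posttest(0.5, lr_neg_point),
        fagan_positive_study=fagan_posttest(study_prev, lr_pos.point),
        fagan_negative_study=fagan_posttest(study_prev, lr_neg_point),
        transported=tuple(transported),
        symptom_agreement=dict(symptom_agreement_rates or {}),
        discordant_count=table.discordant,
    )


def build_report(
    records: Sequence,
    contrast: Contrast | str = "mpm_vs_nom",
    extra_prevalences: Sequence[float] = (0.10,),
    conf: float = 0.95,
    atom_pairs: pd.DataFrame | None = None,
    tracked_atoms: Sequence[str] | None = None,
) -> AccuracyReport:
    """Full report from paired records (``cohort.PairedRecord`` or 2-tuples).

    When long-format per-atom answer pairs are supplied, per-symptom
    agreement is computed on the diagnosis-discordant subset (false
    positives and false negatives under the contrast).
    """
    if not records:
        raise StatsError("no paired records supplied")
    if isinstance(contrast, str):
        contrast = CONTRASTS[contrast]
    label_pairs = []
    ids: list[str] = []
    for rec in records:
        if hasattr(rec, "reference_labels"):
            label_pairs.append((rec.reference_labels, rec.index_labels))
            ids.append(rec.respondent_id)
        else:
            reference, index = rec
            label_pairs.append((frozenset(reference), frozenset(index)))
            ids.append(f"r{len(ids)}")
    table = contingency_from_pairs(label_pairs, contrast)

    agreement: dict[str, float] = {}
    if atom_pairs is not None and table.discordant > 0:
        discordant_ids = []
        for rid, (reference, index) in zip(ids, label_pairs):
            if contrast.classify(reference) == "excluded":
                continue
            ref_pos = bool(reference & contrast.positive_labels)
            idx_pos = bool(index & contrast.positive_labels)
            if ref_pos != idx_pos:
                discordant_ids.append(rid)
        if tracked_atoms is None:
            from .rulebase import TRACKED_SYMPTOM_ATOMS as tracked_atoms  # noqa: N813
        agreement = symptom_agreement(atom_pairs, tracked_atoms, discordant_ids)

    return build_report_from_table(
        table,
        contrast=contrast.name,
        extra_prevalences=extra_prevalences,
        conf=conf,
        symptom_agreement_rates=agreement,
    )


def _pct(x: float, digits: int = 1) -> str:
    return "undefined" if math.isnan(x) else f"{100 * x:.{digits}f}%"


def _ratio(x: float) -> str:
    if math.isnan(x):
        return "undefined"
    if math.isinf(x):
        return "inf"
    return f"{x:.1f}" if x >= 10 else f"{x:.2f}"


def format_report(report: AccuracyReport) -> str:
    """Aligned-text summary in the conventional accuracy-study layout."""
    t = report.table
    k = report.kappa
    lines = [
        f"Diagnostic accuracy report — contrast: {report.contrast}",
        f"  2x2 table: TP={t.tp}  FP={t.fp}  FN={t.fn}  TN={t.tn}  (n={t.n}"
        + (f", excluded={t.excluded})" if t.excluded else ")"),
        f"  Study prevalence      {_pct(report.prevalence.point)} "
        f"({_pct(report.prevalence.lower)}–{_pct(report.prevalence.upper)})",
        f"  Kappa                 {k.kappa:.2f} "
        f"({k.ci.lower:.2f}–{k.ci.upper:.2f}) — {k.interpretation}",
        f"  Accuracy              {_pct(report.accuracy.point)} "
        f"({_pct(report.accuracy.lower)}–{_pct(report.accuracy.upper)})",
        f"  Sensitivity           {_pct(report.sensitivity.point)} "
        f"({_pct(report.sensitivity.lower)}–{_pct(report.sensitivity.upper)})",
        f"  Specificity           {_pct(report.specificity.point)} "
        f"({_pct(report.specificity.lower)}–{_pct(report.specificity.upper)})",
        f"  PPV                   {_pct(report.ppv.point)} "
        f"({_pct(report.ppv.lower)}–{_pct(report.ppv.upper)})",
        f"  NPV                   {_pct(report.npv.point)} "
        f"({_pct(report.npv.lower)}–{_pct(report.npv.upper)})",
        f"  LR+                   {_ratio(report.lr_pos.point)} "
        f"({_ratio(report.lr_pos.lower)}–{_ratio(report.lr_pos.upper)})",
        f"  LR-                   {_ratio(report.lr_neg.point)} "
        f"({_ratio(report.lr_neg.lower)}–{_ratio(report.lr_neg.upper)})",
        f"  Fagan 50% pretest:    positive → {_pct(report.fagan_positive_50.posttest, 0)}, "
        f"negative → {_pct(report.fagan_negative_50.posttest, 0)}",
        f"  Fagan study pretest:  positive → {_pct(report.fagan_positive_study.posttest, 0)}, "
        f"negative → {_pct(report.fagan_negative_study.posttest, 0)}",
        f"  Discordant records    {report.discordant_count}",
    ]
    for s in report.transported:
        lines.append(
            f"  At prevalence {_pct(s.prevalence, 0):>4}:   PPV {_pct(s.ppv.point)} "
            f"({_pct(s.ppv.lower)}–{_pct(s.ppv.upper)}), NPV {_pct(s.npv.point)} "
            f"({_pct(s.npv.lower)}–{_pct(s.npv.upper)})"
        )
    if report.symptom_agreement:
        lines.append("  Symptom agreement on discordant subset:")
        for atom_id, frac in sorted(report.symptom_agreement.items(), key=lambda kv: kv[1]):
            lines.append(f"    {atom_id:<28}{_pct(frac, 0)}")
    return "\n".join(lines)
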