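"""File formats: rule-bank JSON, study-config JSON, answer/paired CSVs.

Documents are schema-validated with pydantic; validation errors carry a
JSON-pointer-style location.  Serialization is canonical (sorted keys,
fixed indentation) so save -> load -> save is byte-identical.  CSV answer
values are the atom-domain strings verbatim, and readers tolerate
arbitrary column order.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import cohort as _cohort
from .dxstats import CONTRASTS, Contrast
from .engine import Question, QuestionBank, default_question_bank
from .rulebase import (
    ALL,
    ANY,
    AT_LEAST,
    ATOM_EQUALS,
    EXACTLY_ONE_FALSE,
    NOT,
    Atom,
    BankError,
    Expression,
    Rule,
    RuleSet,
    default_ichd_ruleset,
)

__all__ = [
    "RuleBankDocument",
    "StudyConfigDocument",
    "load_rulebank",
    "save_rulebank",
    "default_rulebank_document",
    "load_study_config",
    "write_answers_csv",
    "read_answers_csv",
    "write_paired_csv",
    "read_paired_csv",
    "write_atom_pairs_csv",
    "read_atom_pairs_csv",
]

FORMAT_VERSION = 1


class ExprNode(BaseModel):
    model_config = ConfigDict(extra="forbid")

    op: Literal["atom_equals", "not", "all", "any", "at_least", "exactly_one_false"]
    atom: str | None = None
    value: str | None = None
    k: int | None = None
    children: list["ExprNode"] = Field(default_factory=list)


class AtomDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    domain: list[str]
    prompt_key: str = ""


class QuestionDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    atom: str
    order_index: int
    text: str
    answer_labels: dict[str, str] = Field(default_factory=dict)


class RuleDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    label: str
    precedence: int = 0
    expression: ExprNode


class ContrastDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    positive_labels: list[str]
    negative_labels: list[str] = Field(default_factory=list)
    excluded_labels: list[str] = Field(default_factory=list)


class RuleBankDocument(BaseModel):
    model_config = ConfigDict(extra="forbid")

    format_version: int = FORMAT_VERSION
    version: str = "unversioned"
    atoms: list[AtomDoc]
    questions: list[QuestionDoc]
    rules: list[RuleDoc]
    contrasts: list[ContrastDoc] = Field(default_factory=list)


def _expr_to_node(expr: Expression) -> ExprNode:
    return ExprNode(
        op=expr.op,
        atom=expr.atom_id,
        value=expr.value,
        k=expr.k,
        children=[_expr_to_node(c) for c in expr.children],
    )


def _node_to_expr(node: ExprNode) -> Expression:
    return Expression(
        op=node.op,
        children=tuple(_node_to_expr(c) for c in node.children),
        atom_id=node.atom,
        value=node.value,
        k=node.k,
    )


def rulebank_document(
    ruleset: RuleSet,
    bank: QuestionBank,
    contrasts: Mapping[str, Contrast] | None = None,
) -> RuleBankDocument:
    contrasts = CONTRASTS if contrasts is None else contrasts
    return RuleBankDocument(
        format_version=FORMAT_VERSION,
        version=ruleset.version,
        atoms=[
            AtomDoc(id=a.id, domain=list(a.domain), prompt_key=a.prompt_key)
            for a in ruleset.atoms
        ],
        questions=[
            QuestionDoc(
                id=q.id,
                atom=q.atom_id,
                order_index=q.order_index,
                text=q.text,
                answer_labels=dict(q.answer_labels),
            )
            for q in bank.questions
        ],
        rules=[
            RuleDoc(
                id=r.id,
                label=r.label,
                precedence=r.precedence,
                expression=_expr_to_node(r.expression),
            )
            for r in ruleset.rules
        ],
        contrasts=[
            ContrastDoc(
                name=c.name,
                positive_labels=sorted(c.positive_labels),
                excluded_labels=sorted(c.excluded_labels),
            )
            for c in contrasts.values()
        ],
    )


def default_rulebank_document() -> RuleBankDocument:
    ruleset = default_ichd_ruleset()
    return rulebank_document(ruleset, default_question_bank(ruleset))


def document_to_objects(
    doc: RuleBankDocument,
) -> tuple[RuleSet, QuestionBank, dict[str, Contrast]]:
    ruleset = RuleSet(
        atoms=tuple(
            Atom(id=a.id, domain=tuple(a.domain), prompt_key=a.prompt_key or a.id)
            for a in doc.atoms
        ),
        rules=tuple(
            Rule(
                id=r.id,
                label=r.label,
                expression=_node_to_expr(r.expression),
                precedence=r.precedence,
            )
            for r in doc.rules
        ),
        version=doc.version,
    )
    bank = QuestionBank(
        questions=tuple(
            Question(
                id=q.id,
                atom_id=q.atom,
                text=q.text,
                order_index=q.order_index,
                answer_labels=dict(q.answer_labels),
            )
            for q in doc.questions
        ),
        ruleset=ruleset,
    )
    contrasts = {
        c.name: Contrast(
            name=c.name,
            positive_labels=frozenset(c.positive_labels),
            excluded_labels=frozenset(c.excluded_labels),
        )
        for c in doc.contrasts
    }
    return ruleset, bank, contrasts


def _canonical_json(model: BaseModel) -> str:
    payload = model.model_dump(mode="json")
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def save_rulebank(
    path: str | Path,
    ruleset: RuleSet,
    bank: QuestionBank,
    contrasts: Mapping[str, Contrast] | None = None,
) -> None:
    doc = rulebank_document(ruleset, bank, contrasts)
    Path(path).write_text(_canonical_json(doc))


def load_rulebank(
    path: str | Path,
) -> tuple[RuleSet, QuestionBank, dict[str, Contrast]]:
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise BankError(f"{path}: not valid JSON: {exc}") from exc
    try:
        doc = RuleBankDocument.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        pointer = "/" + "/".join(str(p) for p in first["loc"])
        raise BankError(f"{path}: schema violation at {pointer}: {first['msg']}") from exc
    return document_to_objects(doc)


class StudyConfigDocument(BaseModel):
    """Simulation scenario; defaults emulate the study-like cohort."""

    model_config = ConfigDict(extra="forbid")

    n: int = 202
    class_weights: dict[str, float] = Field(
        default_factory=lambda: {c.label: c.weight for c in _cohort.DEFAULT_MIXTURE}
    )
    noise: dict[str, float] = Field(default_factory=lambda: dict(_cohort.DEFAULT_NOISE))
    seed: int = 0
    contrast: str = "mpm_vs_nom"
    extra_prevalences: list[float] = Field(default_factory=lambda: [0.10])
    confidence: float = 0.95


def load_study_config(path: str | Path | None) -> StudyConfigDocument:
    if path is None:
        return StudyConfigDocument()
    try:
        raw = json.loads(Path(path).read_text())
        return StudyConfigDocument.model_validate(raw)
    except json.JSONDecodeError as exc:
        raise BankError(f"{path}: not valid JSON: {exc}") from exc
    except ValidationError as exc:
        first = exc.errors()[0]
        pointer = "/" + "/".join(str(p) for p in first["loc"])
        raise BankError(f"{path}: schema violation at {pointer}: {first['msg']}") from exc


# ---------------------------------------------------------------------------
# CSV formats
# ---------------------------------------------------------------------------


def write_answers_csv(
    path: str | Path,
    rows: Sequence[tuple[str, Mapping[str, str]]],
    ruleset: RuleSet,
) -> None:
    """Respondent x atom matrix of answer strings."""
    atom_ids = [a.id for a in ruleset.atoms]
    frame = pd.DataFrame(
        [{"respondent_id": rid, **{a: ans.get(a, "") for a in atom_ids}} for rid, ans in rows]
    )
    frame.to_csv(path, index=False)


def read_answers_csv(
    path: str | Path, ruleset: RuleSet
) -> list[tuple[str, dict[str, str]]]:
    frame = pd.read_csv(path, dtype=str).fillna("")
    if "respondent_id" not in frame.columns:
        raise BankError(f"{path}: missing required column 'respondent_id'")
    atom_ids = [a.id for a in ruleset.atoms if a.id in frame.columns]
    out: list[tuple[str, dict[str, str]]] = []
    for _, row in frame.iterrows():
        answers = {a: row[a] for a in atom_ids if row[a] != ""}
        ruleset.validate_answers(answers)
        out.append((str(row["respondent_id"]), answers))
    return out


def _join_labels(labels: frozenset[str] | set[str]) -> str:
    return ";".join(sorted(labels))


def _split_labels(text: str) -> frozenset[str]:
    text = (text or "").strip()
    return frozenset(part for part in text.split(";") if part)


def write_paired_csv(path: str | Path, records: Sequence) -> None:
    frame = pd.DataFrame(
        [
            {
                "respondent_id": r.respondent_id,
                "latent_class": r.latent_class,
                "reference_labels": _join_labels(r.reference_labels),
                "index_labels": _join_labels(r.index_labels),
            }
            for r in records
        ]
    )
    frame.to_csv(path, index=False)


def read_paired_csv(path: str | Path) -> list["_cohort.PairedRecord"]:
    frame = pd.read_csv(path, dtype=str).fillna("")
    required = {"respondent_id", "reference_labels", "index_labels"}
    missing = required - set(frame.columns)
    if missing:
        raise BankError(f"{path}: missing required columns {sorted(missing)}")
    return [
        _cohort.PairedRecord(
            respondent_id=str(row["respondent_id"]),
            latent_class=str(row.get("latent_class", "")),
            reference_labels=_split_labels(row["reference_labels"]),
            index_labels=_split_labels(row["index_labels"]),
            reference_answers={},
            index_answers={},
        )
        for _, row in frame.iterrows()
    ]


def write_atom_pairs_csv(path: str | Path, records: Sequence) -> None:
    """Long-format per-atom answer pairs (both channels)."""
    rows = []
    for r in records:
        for atom_id, ref_value in r.reference_answers.items():
            rows.append(
                {
                    "respondent_id": r.respondent_id,
                    "atom_id": atom_id,
                    "reference_value": ref_value,
                    "index_value": r.index_answers.get(atom_id, ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_atom_pairs_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str).fillna("")
    required = {"respondent_id", "atom_id", "reference_value", "index_value"}
    missing = required - set(frame.columns)
    if missing:
        raise BankError(f"{path}: missing required columns {sorted(missing)}")
    return frame
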