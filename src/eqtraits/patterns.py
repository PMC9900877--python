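"""Design-pattern template compiler for Entity-Quality trait classes.

A pattern is a YAML document pairing variable declarations (each with a
semantic range class) with text templates (label, definition, synonyms) and
logic templates (an equivalence schema and optional GCI schemas) written in
the package's Manchester-like expression syntax with ``%s`` slots.  A filler
table binds each pattern variable to a reference-ontology term per row; the
compiler substitutes filler labels into the text templates and filler
identifiers into the logic templates, producing one defined trait class per
row.

Compiled fragments never assert subclass links between two compiled trait
terms: the polyhierarchy is entirely the reasoner's job.  The GCI schemas
propagate mereology, e.g.::

    Q and (characteristic_of some (part_of some E))
        SubClassOf  part_of some (Q and (characteristic_of some E))

so that with ``ulna part_of forelimb skeleton`` asserted in the anatomy
reference, "ulna size" is entailed ``part_of some "forelimb skeleton size"``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
import yaml

from .manchester import parse_class_expression
from .model import (And, Axiom, ClassExpression, Curie, EquivalentTo, IdMinter,
                    Named, Ontology, OntologyError, Some, SubClassOf,
                    TermRecord, canonicalize, expr_signature, parse_curie)
from .reasoner import ClassificationResult, classify


class PatternError(OntologyError):
    pass


class CompileError(OntologyError):
    """Aggregate of all row-level compilation failures in a table."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class TextTemplate:
    text: str
    vars: tuple[str, ...]

    def instantiate(self, labels: dict[str, str]) -> str:
        return self.text % tuple(labels[v] for v in self.vars)


@dataclass
class LogicTemplate:
    text: str
    vars: tuple[str, ...]

    def instantiate(self, bindings: dict[str, Curie],
                    prefixes: dict[str, str]) -> ClassExpression:
        rendered = self.text % tuple(str(bindings[v]) for v in self.vars)
        return parse_class_expression(rendered, prefixes)


@dataclass
class Pattern:
    """A validated design-pattern template."""

    pattern_id: str
    vars: dict[str, Curie]  # var name -> range class (insertion ordered)
    name_template: TextTemplate
    def_template: TextTemplate
    equiv_template: LogicTemplate
    synonym_templates: list[TextTemplate] = field(default_factory=list)
    gci_templates: list[tuple[LogicTemplate, LogicTemplate]] = field(
        default_factory=list)
    annotations: dict[str, str] = field(default_factory=dict)
    relations: dict[str, Curie] = field(default_factory=dict)


@dataclass
class FillerRow:
    """One curated row of a filler table: a defined class plus bindings."""

    defined_class: Curie
    bindings: dict[str, Curie]
    label_override: Optional[str] = None
    needs_review: bool = False


DEFAULT_DEF_TEMPLATE = "The %s of %s."


def _text_template(doc: dict, key: str, pattern_vars: Iterable[str],
                   default: Optional[TextTemplate] = None) -> TextTemplate:
    if key not in doc:
        if default is not None:
            return default
        raise PatternError(f"pattern is missing required section {key!r}")
    section = doc[key]
    tmpl = TextTemplate(section["text"], tuple(section.get("vars", ())))
    n_slots = tmpl.text.count("%s")
    if n_slots != len(tmpl.vars):
        raise PatternError(
            f"{key}: template has {n_slots} %s slots but {len(tmpl.vars)} "
            "vars")
    for v in tmpl.vars:
        if v not in pattern_vars:
            raise PatternError(f"{key}: undeclared var {v!r}")
    return tmpl


def _logic_template(section: dict, key: str,
                    pattern_vars: Iterable[str]) -> LogicTemplate:
    tmpl = LogicTemplate(section["text"], tuple(section.get("vars", ())))
    n_slots = tmpl.text.count("%s")
    if n_slots != len(tmpl.vars):
        raise PatternError(
            f"{key}: logic schema has {n_slots} %s slots but "
            f"{len(tmpl.vars)} vars")
    for v in tmpl.vars:
        if v not in pattern_vars:
            raise PatternError(f"{key}: undeclared var {v!r} in schema")
    return tmpl


def load_pattern(text: str,
                 prefixes: Optional[dict[str, str]] = None) -> Pattern:
    """Load and validate a pattern YAML document."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise PatternError("pattern document is not a mapping")
    try:
        pattern_id = doc["pattern_id"]
        raw_vars = doc["vars"]
    except KeyError as exc:
        raise PatternError(f"pattern is missing section {exc}") from None
    if not raw_vars:
        raise PatternError("pattern declares no vars")
    vars_ = {name: parse_curie(rng, prefixes)
             for name, rng in raw_vars.items()}

    name_t = _text_template(doc, "name", vars_)
    default_def = None
    if "definition" not in doc and len(vars_) == 2:
        ordered = list(vars_)
        default_def = TextTemplate(DEFAULT_DEF_TEMPLATE, tuple(ordered))
    def_t = _text_template(doc, "definition", vars_, default=default_def)
    synonyms = [_text_template({"synonym": s}, "synonym", vars_)
                for s in doc.get("synonyms", ())]

    if "equivalent_to" not in doc:
        raise PatternError("pattern is missing section 'equivalent_to'")
    equiv_t = _logic_template(doc["equivalent_to"], "equivalent_to", vars_)
    gcis = []
    for i, gci in enumerate(doc.get("gcis", ())):
        gcis.append((_logic_template(gci["sub"], f"gcis[{i}].sub", vars_),
                     _logic_template(gci["sup"], f"gcis[{i}].sup", vars_)))
    relations = {name: parse_curie(cid, prefixes)
                 for name, cid in doc.get("relations", {}).items()}
    return Pattern(pattern_id=pattern_id, vars=vars_, name_template=name_t,
                   def_template=def_t, equiv_template=equiv_t,
                   synonym_templates=synonyms, gci_templates=gcis,
                   annotations=doc.get("annotations", {}),
                   relations=relations)


def load_filler_table(text: str, pattern: Pattern,
                      prefixes: Optional[dict[str, str]] = None
                      ) -> list[FillerRow]:
    """Read a TSV filler table: first column ``defined_class``, one column
    per pattern var, optional ``label`` column for overrides."""
    frame = pd.read_csv(_io.StringIO(text), sep="\t", dtype=str).fillna("")
    expected = ["defined_class"] + list(pattern.vars)
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise PatternError(
            f"filler table is missing columns {missing} for pattern "
            f"{pattern.pattern_id!r}")
    rows: list[FillerRow] = []
    for _, record in frame.iterrows():
        bindings = {v: parse_curie(record[v], prefixes)
                    for v in pattern.vars}
        rows.append(FillerRow(
            defined_class=parse_curie(record["defined_class"], prefixes),
            bindings=bindings,
            label_override=(record["label"]
                            if "label" in frame.columns and record["label"]
                            else None)))
    return rows


def compile_row(pattern: Pattern, row: FillerRow, refs: Ontology,
                refs_result: Optional[ClassificationResult] = None
                ) -> tuple[TermRecord, list[Axiom]]:
    """Compile one filler row into a term record plus logical axioms.

    Each binding must resolve in ``refs`` and classify under its variable's
    declared range (checked semantically with the reasoner, not by prefix).
    """
    if set(row.bindings) != set(pattern.vars):
        raise PatternError(
            f"{row.defined_class}: bindings {sorted(row.bindings)} do not "
            f"match pattern vars {sorted(pattern.vars)}")
    if refs_result is None:
        refs_result = classify(refs)
    labels: dict[str, str] = {}
    for var, filler in row.bindings.items():
        if filler not in refs.terms:
            raise PatternError(
                f"{row.defined_class}: unknown filler {filler} for var "
                f"{var!r}")
        rng = pattern.vars[var]
        if rng != Curie("owl", "Thing") and \
                not refs_result.is_subsumed(filler, rng):
            raise PatternError(
                f"{row.defined_class}: filler {filler} is outside the range "
                f"{rng} of var {var!r}")
        labels[var] = refs.label_of(filler)

    label = row.label_override or pattern.name_template.instantiate(labels)
    definition = pattern.def_template.instantiate(labels)
    synonyms = [(t.instantiate(labels), "EXACT")
                for t in pattern.synonym_templates]
    record = TermRecord(id=row.defined_class, label=label,
                        definition=definition, synonyms=synonyms)

    axioms: list[Axiom] = [EquivalentTo(
        row.defined_class,
        pattern.equiv_template.instantiate(row.bindings, refs.prefixes))]
    for sub_t, sup_t in pattern.gci_templates:
        axioms.append(SubClassOf(
            sub_t.instantiate(row.bindings, refs.prefixes),
            sup_t.instantiate(row.bindings, refs.prefixes)))
    return record, axioms


def compile_table(pattern: Pattern, rows: list[FillerRow], refs: Ontology,
                  refs_result: Optional[ClassificationResult] = None
                  ) -> Ontology:
    """Compile a whole filler table into an ontology fragment.

    Row-level failures are aggregated into one :class:`CompileError` rather
    than failing fast.  The fragment contains the compiled terms, their
    equivalence and GCI axioms, declarations for the referenced roles and
    copies of the referenced filler terms; no subclass link between two
    compiled terms is ever asserted.
    """
    if refs_result is None:
        refs_result = classify(refs)
    errors: list[str] = []
    seen: dict[Curie, int] = {}
    for i, row in enumerate(rows, start=1):
        if row.defined_class in seen:
            errors.append(
                f"duplicate defined_class {row.defined_class} in rows "
                f"{seen[row.defined_class]} and {i}")
        else:
            seen[row.defined_class] = i

    out = Ontology(prefixes=dict(refs.prefixes))
    for i, row in enumerate(rows, start=1):
        try:
            record, axioms = compile_row(pattern, row, refs, refs_result)
        except OntologyError as exc:
            errors.append(f"row {i}: {exc}")
            continue
        out.terms[record.id] = record
        for ax in axioms:
            out.add_axiom(ax)
    if errors:
        raise CompileError(errors)

    # declare everything the compiled axioms reference
    for ax in list(out.axioms):
        if isinstance(ax, EquivalentTo):
            sig = expr_signature(ax.expr)
        else:
            sig = expr_signature(ax.sub) | expr_signature(ax.sup)
        for cid in sig:
            if cid in out.terms or cid in out.roles:
                continue
            if cid in refs.roles:
                out.add_role(cid, refs.roles[cid])
            elif cid in refs.terms:
                rec = refs.terms[cid]
                out.add_term(cid, rec.label, definition=rec.definition)
            elif cid in pattern.relations.values():
                out.add_role(cid)
    return out


# --------------------------------------------------------------------------
# Realignment: propose trait rows from phenotype EQ definitions
# --------------------------------------------------------------------------


def _nearest_attribute(state: Curie, characteristics: Ontology,
                       chars_result: ClassificationResult,
                       attribute_level: set[Curie]) -> Optional[Curie]:
    """The most specific attribute-level ancestor of a state quality
    (e.g. "increased amount" -> "amount")."""
    candidates = [a for a in chars_result.subsumers.get(state, set())
                  if a in attribute_level]
    if not candidates:
        return None
    # most specific: subsumed by every other candidate
    best = [a for a in candidates
            if all(chars_result.is_subsumed(a, b) for b in candidates)]
    return sorted(best or candidates, key=str)[0]


def derive_trait_candidates(pheno: Ontology, characteristics: Ontology,
                            characteristic_of: Curie,
                            minter: Optional[IdMinter] = None,
                            attribute_subset: str = "attribute_slim"
                            ) -> tuple[list[FillerRow], list[Curie]]:
    """Propose entity-attribute filler rows from phenotype EQ definitions.

    For each phenotype class with an equivalence of the abnormality shape
    ``state and (characteristic_of some E) and (modifier conjuncts…)`` where
    E is a named entity, propose a row binding ``attribute`` to the nearest
    attribute-level ancestor of the state quality and ``entity`` to E.  The
    rows are flagged for curator review; undecomposable classes are returned
    as the skipped list.
    """
    minter = minter or IdMinter()
    chars_result = classify(characteristics)
    attribute_level = set(characteristics.subsets.get(attribute_subset, ()))
    rows: list[FillerRow] = []
    skipped: list[Curie] = []
    for cid in pheno.live_terms():
        equiv = pheno.equiv_for(cid)
        if equiv is None:
            skipped.append(cid)
            continue
        expr = canonicalize(equiv.expr)
        operands = expr.operands if isinstance(expr, And) else (expr,)
        state: Optional[Curie] = None
        entity: Optional[Curie] = None
        decomposable = True
        for op in operands:
            if isinstance(op, Named):
                if state is not None:
                    decomposable = False
                    break
                state = op.id
            elif isinstance(op, Some) and op.role == characteristic_of:
                if entity is not None or not isinstance(op.filler, Named):
                    decomposable = False
                    break
                entity = op.filler.id
            elif isinstance(op, Some):
                continue  # modifier conjuncts are ignored
            else:
                decomposable = False
                break
        if not decomposable or state is None or entity is None:
            skipped.append(cid)
            continue
        attribute = _nearest_attribute(state, characteristics, chars_result,
                                       attribute_level)
        if attribute is None:
            skipped.append(cid)
            continue
        rows.append(FillerRow(defined_class=minter.mint(),
                              bindings={"attribute": attribute,
                                        "entity": entity},
                              needs_review=True))
    return rows, skipped
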