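"""Lexical alignment of external trait vocabularies (the Match/Sync steps).

``match_terms`` links external terms to existing trait terms by normalised
label/exact-synonym equality; terms that do not match fall through to
``propose_decomposition``, which scans the normalised label against an
ordered list of reference ontologies (chemicals before anatomy before
qualities, mirroring the production ordering) and proposes bindings for a
design-pattern's variable slots.  Curators accept or reject candidates via
a plain TSV review file; ``apply_review`` turns accepted exact matches into
SSSOM rows and accepted decompositions into filler rows for the pattern
compiler (the Compile step).
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .io.sssom import JUSTIFICATION_LEXICAL, SSSOMRow
from .model import Curie, IdMinter, Named, Ontology, OntologyError
from .patterns import FillerRow, Pattern
from .reasoner import ClassificationResult, classify

#: Normalisation stop words: the curation-pipeline fillers that carry no
#: trait semantics, plus plurals.  Configurable per call.
DEFAULT_STOPLIST = frozenset(
    {"measurement", "measurements", "trait", "traits"})

EXACT_MATCH_PREDICATE = "skos:exactMatch"

_PUNCT = re.compile(r"[^a-z0-9]+")


def normalize_label(text: str,
                    stoplist: Iterable[str] = DEFAULT_STOPLIST) -> list[str]:
    """Lowercase, strip punctuation, tokenise, drop stop words.

    Deterministic and idempotent on its own (re-joined) output.
    """
    stop = set(stoplist)
    tokens = [t for t in _PUNCT.split(text.lower()) if t]
    return [t for t in tokens if t not in stop]


@dataclass
class MatchCandidate:
    external_id: Curie
    external_label: str
    kind: str = "NONE"  # EXACT_LABEL | EXACT_SYNONYM | DECOMPOSITION | NONE
    matched_trait: Optional[Curie] = None
    proposed_bindings: dict[str, Curie] = field(default_factory=dict)
    pattern_id: Optional[str] = None
    decision: str = "PENDING"  # PENDING | ACCEPTED | REJECTED
    note: str = ""


def _norm_forms(rec, stoplist) -> tuple[tuple[str, ...], set[tuple[str, ...]]]:
    """(normalised label, set of normalised EXACT synonyms)."""
    label = tuple(normalize_label(rec.label, stoplist))
    synonyms = {tuple(normalize_label(s, stoplist))
                for s in rec.exact_synonyms()}
    synonyms.discard(())
    return label, synonyms


def match_terms(external: Ontology, traits: Ontology,
                stoplist: Iterable[str] = DEFAULT_STOPLIST
                ) -> list[MatchCandidate]:
    """Exact lexical matching on normalised labels and EXACT synonyms.

    Each external term yields one candidate: EXACT_LABEL when the
    normalised labels are equal, EXACT_SYNONYM when a synonym is involved
    on either side, NONE otherwise.  An external term whose normalised form
    matches two distinct trait terms is ambiguous and yields NONE with an
    explanatory note (a trait-side uniqueness problem, not a mapping).
    """
    from .model import EquivalentTo
    defined = {ax.named for ax in traits.axioms
               if isinstance(ax, EquivalentTo)}
    # compiled trait terms are the match targets; reference terms copied
    # into the release (fillers like "lysine") are not traits themselves.
    # A plain vocabulary without logical definitions is indexed wholesale.
    targets = [c for c in traits.live_terms() if c in defined] \
        or traits.live_terms()
    label_index: dict[tuple[str, ...], set[Curie]] = {}
    synonym_index: dict[tuple[str, ...], set[Curie]] = {}
    for cid in targets:
        label, synonyms = _norm_forms(traits.terms[cid], stoplist)
        if label:
            label_index.setdefault(label, set()).add(cid)
        for s in synonyms:
            synonym_index.setdefault(s, set()).add(cid)

    candidates: list[MatchCandidate] = []
    for cid in external.live_terms():
        rec = external.terms[cid]
        label, synonyms = _norm_forms(rec, stoplist)
        cand = MatchCandidate(external_id=cid, external_label=rec.label)
        hits: set[Curie] = set()
        kind = "NONE"
        if label in label_index:
            hits = set(label_index[label])
            kind = "EXACT_LABEL"
        if not hits:
            for form in [label] + sorted(synonyms):
                if form in label_index:
                    hits = set(label_index[form])
                    kind = "EXACT_SYNONYM"
                    break
                if form in synonym_index:
                    hits = set(synonym_index[form])
                    kind = "EXACT_SYNONYM"
                    break
        if len(hits) == 1:
            cand.kind = kind
            cand.matched_trait = next(iter(hits))
        elif len(hits) > 1:
            cand.kind = "NONE"
            cand.note = ("ambiguous: multiple trait terms normalise "
                         "identically: "
                         + ", ".join(sorted(map(str, hits))))
        candidates.append(cand)
    return candidates


def _reference_index(ref: Ontology, stoplist) -> dict[tuple[str, ...],
                                                      Curie]:
    index: dict[tuple[str, ...], Curie] = {}
    for cid in sorted(ref.live_terms(), key=str):
        label, synonyms = _norm_forms(ref.terms[cid], stoplist)
        for form in [label] + sorted(synonyms):
            if form and form not in index:
                index[form] = cid
    return index


def propose_decomposition(label: str, refs: list[Ontology],
                          patterns: list[Pattern],
                          stoplist: Iterable[str] = DEFAULT_STOPLIST,
                          external_id: Optional[Curie] = None,
                          refs_result: Optional[ClassificationResult] = None
                          ) -> MatchCandidate:
    """Decompose an external label into reference-term fillers and propose
    pattern variable bindings.

    Token runs are matched longest-first, leftmost, non-overlapping;
    reference ontologies earlier in ``refs`` claim tokens first.  Fillers
    are then assigned to the variables of the best-fitting pattern by
    semantic range.  Returns a DECOMPOSITION candidate when at least one
    slot is filled, NONE otherwise.
    """
    cand = MatchCandidate(
        external_id=external_id or Curie("TST", "external"),
        external_label=label)
    tokens = normalize_label(label, stoplist)
    if not tokens:
        return cand
    claimed = [False] * len(tokens)
    fillers: list[tuple[int, Curie]] = []  # (start position, term)
    merged_refs: Optional[Ontology] = None
    for ref in refs:
        index = _reference_index(ref, stoplist)
        merged_refs = ref if merged_refs is None else merged_refs.merge(ref)
        start = 0
        while start < len(tokens):
            if claimed[start]:
                start += 1
                continue
            hit = None
            for end in range(len(tokens), start, -1):
                if any(claimed[start:end]):
                    continue
                form = tuple(tokens[start:end])
                if form in index:
                    hit = (end, index[form])
                    break
            if hit is None:
                start += 1
                continue
            end, cid = hit
            for i in range(start, end):
                claimed[i] = True
            fillers.append((start, cid))
            start = end
    if not fillers:
        return cand
    fillers.sort(key=lambda f: f[0])

    if refs_result is None:
        refs_result = classify(merged_refs)

    best: Optional[tuple[tuple[int, int], Pattern, dict[str, Curie]]] = None
    for pattern in patterns:
        bindings: dict[str, Curie] = {}
        assigned = 0
        for _, filler in fillers:
            for var, rng in pattern.vars.items():
                if var in bindings:
                    continue
                if rng == Curie("owl", "Thing") or \
                        refs_result.is_subsumed(filler, rng):
                    bindings[var] = filler
                    assigned += 1
                    break
        if not bindings:
            continue
        unfilled = len(pattern.vars) - len(bindings)
        score = (assigned, -unfilled)
        if best is None or score > best[0]:
            best = (score, pattern, bindings)
    if best is None:
        return cand
    _, pattern, bindings = best
    cand.kind = "DECOMPOSITION"
    cand.pattern_id = pattern.pattern_id
    cand.proposed_bindings = bindings
    return cand


def match_and_decompose(external: Ontology, traits: Ontology,
                        refs: list[Ontology], patterns: list[Pattern],
                        stoplist: Iterable[str] = DEFAULT_STOPLIST
                        ) -> list[MatchCandidate]:
    """Full Match-then-Sync pass: exact matching first, decomposition only
    for the leftovers (no candidate is ever both)."""
    refs_result = None
    merged: Optional[Ontology] = None
    for ref in refs:
        merged = ref if merged is None else merged.merge(ref)
    if merged is not None:
        refs_result = classify(merged)
    out: list[MatchCandidate] = []
    for cand in match_terms(external, traits, stoplist):
        if cand.kind == "NONE" and not cand.note:
            rec = external.terms[cand.external_id]
            cand = propose_decomposition(
                rec.label, refs, patterns, stoplist,
                external_id=cand.external_id, refs_result=refs_result)
        out.append(cand)
    return out


# --------------------------------------------------------------------------
# Review round trip
# --------------------------------------------------------------------------

CANDIDATE_COLUMNS = ("external_id", "external_label", "kind",
                     "matched_trait", "pattern_id", "bindings", "decision",
                     "note")


def write_candidates_tsv(candidates: list[MatchCandidate]) -> str:
    lines = ["\t".join(CANDIDATE_COLUMNS)]
    for c in sorted(candidates, key=lambda c: str(c.external_id)):
        bindings = ";".join(f"{v}={c.proposed_bindings[v]}"
                            for v in sorted(c.proposed_bindings))
        lines.append("\t".join((
            str(c.external_id), c.external_label, c.kind,
            str(c.matched_trait) if c.matched_trait else "",
            c.pattern_id or "", bindings, c.decision, c.note)))
    return "\n".join(lines) + "\n"


def apply_review(candidates: list[MatchCandidate], review_text: str,
                 minter: Optional[IdMinter] = None,
                 prefixes: Optional[dict[str, str]] = None
                 ) -> tuple[list[SSSOMRow], list[FillerRow]]:
    """Apply a curator review file (TSV: candidate id, decision, note).

    Accepted EXACT_* candidates become SSSOM rows with justification
    LexicalMatching; accepted DECOMPOSITION candidates become filler rows
    with freshly minted identifiers, ready for the pattern compiler.
    Rejected and pending candidates are excluded.  A decision referencing
    an unknown candidate is an error.
    """
    minter = minter or IdMinter()
    by_id = {str(c.external_id): c for c in candidates}
    frame = pd.read_csv(_io.StringIO(review_text), sep="\t",
                        dtype=str).fillna("")
    for col in ("candidate_id", "decision"):
        if col not in frame.columns:
            raise OntologyError(f"review file is missing column {col!r}")
    for _, record in frame.iterrows():
        cid = record["candidate_id"]
        if cid not in by_id:
            raise OntologyError(f"review references unknown candidate {cid}")
        decision = record["decision"].upper()
        if decision not in ("ACCEPTED", "REJECTED", "PENDING"):
            raise OntologyError(
                f"invalid decision {record['decision']!r} for {cid}")
        by_id[cid].decision = decision
        if "note" in frame.columns and record["note"]:
            by_id[cid].note = record["note"]

    sssom_rows: list[SSSOMRow] = []
    filler_rows: list[FillerRow] = []
    for c in sorted(candidates, key=lambda c: str(c.external_id)):
        if c.decision != "ACCEPTED":
            continue
        if c.kind in ("EXACT_LABEL", "EXACT_SYNONYM"):
            sssom_rows.append(SSSOMRow(
                subject_id=c.external_id, subject_label=c.external_label,
                predicate_id=EXACT_MATCH_PREDICATE,
                object_id=c.matched_trait, object_label="",
                mapping_justification=JUSTIFICATION_LEXICAL))
        elif c.kind == "DECOMPOSITION":
            filler_rows.append(FillerRow(
                defined_class=minter.mint(),
                bindings=dict(c.proposed_bindings),
                needs_review=False))
    return sssom_rows, filler_rows
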