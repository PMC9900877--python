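"""Composed pipeline: compile -> classify -> relation graph -> link/match -> QC.

Drives the whole workflow from a single configuration (YAML file and/or
flag overrides), writing deterministic artifacts plus a machine-readable
run manifest to the output directory.  Exit codes are a stable contract:
0 clean, 1 QC error, 2 input/parse error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import qc as qc_mod
from .io import (parse_functional_syntax, parse_obo, write_functional_syntax,
                 write_obograph_json, write_sssom)
from .linking import link_phenotypes
from .matching import (DEFAULT_STOPLIST, match_and_decompose,
                       write_candidates_tsv)
from .model import (Curie, EquivalentTo, IdMinter, Named, Ontology,
                    OntologyError, default_prefixes, parse_curie)
from .patterns import compile_table, load_filler_table, load_pattern
from .reasoner import classify
from .relgraph import materialize, nonredundant, write_edges_tsv

logger = logging.getLogger("eqtraits")

EXIT_CLEAN = 0
EXIT_QC_ERROR = 1
EXIT_INPUT_ERROR = 2


@dataclass
class RunConfig:
    """Configuration for a composed pipeline run."""

    reference_paths: list[str] = field(default_factory=list)  # ordered
    pattern_tables: list[tuple[str, str]] = field(default_factory=list)
    phenotype_path: Optional[str] = None
    external_path: Optional[str] = None
    root: str = "OBA:0000001"
    root_equivalent: Optional[str] = "PATO:0000001"
    roles: list[str] = field(default_factory=lambda: ["BFO:0000050",
                                                      "RO:0000052"])
    stoplist: list[str] = field(default_factory=lambda:
                                sorted(DEFAULT_STOPLIST))
    id_mint_start: int = 9000001
    output_dir: str = "out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text) or {}
        cfg = cls()
        for key, value in doc.items():
            if key == "pattern_tables":
                value = [tuple(pair) for pair in value]
            if not hasattr(cfg, key):
                raise OntologyError(f"unknown config key {key!r}")
            setattr(cfg, key, value)
        return cfg


def load_ontology(path: str | Path,
                  prefixes: Optional[dict[str, str]] = None) -> Ontology:
    """Load an ontology from .obo or .ofn/.owl (functional syntax) by
    extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".obo":
        return parse_obo(text, prefixes)
    return parse_functional_syntax(text, prefixes)


def run_pipeline(cfg: RunConfig) -> int:
    """Execute the composed workflow; returns the exit status.

    Artifacts (all deterministic for identical config + inputs):
    compiled.ofn, taxonomy.tsv, edges.tsv, obograph.json, optionally
    links.sssom.tsv and candidates.tsv, qc_report.json and manifest.json.
    On failure, partial artifacts are retained and the manifest marks the
    run incomplete.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {
        "reference_paths": list(cfg.reference_paths),
        "pattern_tables": [list(p) for p in cfg.pattern_tables],
        "phenotype_path": cfg.phenotype_path,
        "external_path": cfg.external_path,
        "root": cfg.root, "roles": list(cfg.roles), "seed": cfg.seed,
    }, "stages": {}, "complete": False}

    def finish(status: int) -> int:
        manifest["complete"] = status == EXIT_CLEAN
        manifest["exit_status"] = status
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return status

    try:
        prefixes = default_prefixes()
        refs: Optional[Ontology] = None
        ref_onts: list[Ontology] = []
        for path in cfg.reference_paths:
            ont = load_ontology(path, prefixes)
            ref_onts.append(ont)
            refs = ont if refs is None else refs.merge(ont)
        if refs is None:
            raise OntologyError("no reference ontologies configured")
        manifest["stages"]["references"] = {
            "files": len(cfg.reference_paths),
            "terms": len(refs.terms)}

        refs_result = classify(refs)
        compiled = Ontology(prefixes=dict(refs.prefixes))
        for pattern_path, table_path in cfg.pattern_tables:
            pattern = load_pattern(Path(pattern_path).read_text(),
                                   refs.prefixes)
            rows = load_filler_table(Path(table_path).read_text(), pattern,
                                     refs.prefixes)
            fragment = compile_table(pattern, rows, refs, refs_result)
            compiled = compiled.merge(fragment)
        root = parse_curie(cfg.root, prefixes)
        if root not in compiled.terms:
            compiled.add_term(root, "biological attribute")
            if cfg.root_equivalent:
                root_eq = parse_curie(cfg.root_equivalent, prefixes)
                compiled.add_axiom(EquivalentTo(root, Named(root_eq)))
                if root_eq not in compiled.terms:
                    rec = refs.terms.get(root_eq)
                    compiled.add_term(root_eq, rec.label if rec else "")
        n_compiled = len([c for c in compiled.live_terms()
                          if compiled.equiv_for(c) is not None])
        logger.info("compiled %d trait terms", n_compiled)
        manifest["stages"]["compile"] = {"terms": n_compiled}
        (out_dir / "compiled.ofn").write_text(
            write_functional_syntax(compiled))

        release = refs.merge(compiled)
        result = classify(release)
        taxonomy_lines = ["child\tparent"]
        for child in sorted(result.direct_parents, key=str):
            if child.prefix != root.prefix:
                continue
            for parent in sorted(result.direct_parents[child], key=str):
                taxonomy_lines.append(f"{child}\t{parent}")
        (out_dir / "taxonomy.tsv").write_text(
            "\n".join(taxonomy_lines) + "\n")
        manifest["stages"]["classify"] = {
            "classes": len(result.subsumers),
            "equivalence_classes": len(result.equivalence_classes)}

        roles = [parse_curie(r, prefixes) for r in cfg.roles]
        edges = materialize(release, result, roles)
        (out_dir / "edges.tsv").write_text(write_edges_tsv(edges))
        (out_dir / "obograph.json").write_text(
            write_obograph_json(release, sorted(edges)))
        manifest["stages"]["relation_graph"] = {
            "edges": len(edges),
            "nonredundant": len(nonredundant(edges, result))}

        if cfg.phenotype_path:
            pheno = load_ontology(cfg.phenotype_path, prefixes)
            rows, summary = link_phenotypes(release, pheno)
            (out_dir / "links.sssom.tsv").write_text(write_sssom(
                rows, metadata={"mapping_set_id": "eqtraits-links"}))
            manifest["stages"]["link"] = {
                "links": summary.links,
                "classes_under_root": summary.classes_under_root,
                "unmapped": [str(c) for c in summary.unmapped]}

        if cfg.external_path:
            external = load_ontology(cfg.external_path, prefixes)
            patterns = [load_pattern(Path(p).read_text(), refs.prefixes)
                        for p, _ in cfg.pattern_tables]
            candidates = match_and_decompose(
                external, release, ref_onts, patterns,
                stoplist=set(cfg.stoplist))
            (out_dir / "candidates.tsv").write_text(
                write_candidates_tsv(candidates))
            manifest["stages"]["match"] = {
                "candidates": len(candidates),
                "exact": sum(c.kind.startswith("EXACT")
                             for c in candidates),
                "decomposition": sum(c.kind == "DECOMPOSITION"
                                     for c in candidates)}

        violations = qc_mod.run_qc(release, result, root)
        (out_dir / "qc_report.json").write_text(json.dumps(
            qc_mod.violations_as_dicts(violations), indent=2) + "\n")
        manifest["stages"]["qc"] = {
            "violations": len(violations),
            "errors": sum(v.severity == "ERROR" for v in violations)}
        if qc_mod.has_errors(violations):
            logger.error("QC reported errors; failing the release")
            return finish(EXIT_QC_ERROR)
        return finish(EXIT_CLEAN)
    except OntologyError as exc:
        logger.error("pipeline failed: %s", exc)
        manifest["error"] = str(exc)
        return finish(EXIT_INPUT_ERROR)
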