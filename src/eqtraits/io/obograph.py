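"""OBO Graph JSON writer (nodes-and-edges view of an ontology)."""

from __future__ import annotations

import json
from typing import TYPE_CHECKING, Iterable

from ..model import Ontology

if TYPE_CHECKING:  # pragma: no cover
    from ..relgraph import RelationEdge


def write_obograph_json(ont: Ontology,
                        edges: Iterable["RelationEdge"] = ()) -> str:
    """Serialise terms plus materialised relation edges as OBO Graph JSON.

    Nodes carry id, label and a deprecated flag; edges carry sub/pred/obj.
    Ordering is deterministic (sorted by identifier).
    """
    nodes = []
    for cid in sorted(ont.terms, key=str):
        rec = ont.terms[cid]
        node: dict = {"id": str(cid), "lbl": rec.label}
        if rec.deprecated:
            node["meta"] = {"deprecated": True}
        nodes.append(node)
    edge_objs = sorted(
        ({"sub": str(e.subject), "pred": str(e.predicate),
          "obj": str(e.object)} for e in edges),
        key=lambda d: (d["sub"], d["pred"], d["obj"]))
    return json.dumps({"nodes": nodes, "edges": edge_objs},
                      indent=2, sort_keys=True) + "\n"
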