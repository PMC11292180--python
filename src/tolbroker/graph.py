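"""Specimen/sample relationship graph.

Each genetic individual (specimen) becomes one specimen-level node;
every manifest row becomes a sample-level node joined to its specimen by
exactly one typed edge:

* ``SAME_AS`` (1:1) — the tube holds the whole organism;
* ``SAMPLE_DERIVED_FROM`` (many:1) — an organism part;
* ``SAMPLE_SYMBIONT_OF`` (many:1) — a symbiont co-collected with the
  host specimen.

This is the shape under which the public archive registers one
BioSample per specimen and per child sample.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .errors import GraphConstraintError
from .manifest import Manifest

SAMPLE_KEY_SEPARATOR = "/"

EDGE_KINDS = ("SAME_AS", "SAMPLE_DERIVED_FROM", "SAMPLE_SYMBIONT_OF")

#: XML attribute tag for each edge kind (archive convention).
EDGE_TAGS = {
    "SAME_AS": "sample same as",
    "SAMPLE_DERIVED_FROM": "sample derived from",
    "SAMPLE_SYMBIONT_OF": "sample symbiont of",
}


@dataclass
class SampleNode:
    level: str                      # SPECIMEN | SAMPLE
    specimen_id: str
    sample_key: str | None = None   # rack/plate + "/" + tube/well; SAMPLE only
    organism_part: str = ""
    env_sample_id: str | None = None
    metadata: dict = dc_field(default_factory=dict)

    @property
    def identifier(self) -> str:
        """Stable alias: the sample key, or the specimen id itself."""
        return self.sample_key if self.level == "SAMPLE" else self.specimen_id


@dataclass
class RelationshipEdge:
    kind: str            # one of EDGE_KINDS
    child: SampleNode    # SAMPLE-level
    parent: SampleNode   # SPECIMEN-level


@dataclass
class SampleGraph:
    nodes: list[SampleNode] = dc_field(default_factory=list)
    edges: list[RelationshipEdge] = dc_field(default_factory=list)

    def specimen_nodes(self) -> list[SampleNode]:
        return [n for n in self.nodes if n.level == "SPECIMEN"]

    def sample_nodes(self) -> list[SampleNode]:
        return [n for n in self.nodes if n.level == "SAMPLE"]

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "level": n.level,
                    "specimen_id": n.specimen_id,
                    "sample_key": n.sample_key,
                    "organism_part": n.organism_part,
                    "env_sample_id": n.env_sample_id,
                    "metadata": n.metadata,
                }
                for n in self.nodes
            ],
            "edges": [
                {
                    "kind": e.kind,
                    "child": e.child.identifier,
                    "parent": e.parent.identifier,
                }
                for e in self.edges
            ],
        }


def make_sample_key(rack_or_plate_id: str, tube_or_well_id: str) -> str:
    """Sample identity: rack/plate id + separator + tube/well id."""
    for part in (rack_or_plate_id, tube_or_well_id):
        if SAMPLE_KEY_SEPARATOR in part:
            raise GraphConstraintError(
                f"identifier {part!r} contains the reserved separator "
                f"{SAMPLE_KEY_SEPARATOR!r}"
            )
    return f"{rack_or_plate_id}{SAMPLE_KEY_SEPARATOR}{tube_or_well_id}"


def build_graph(manifest: Manifest,
                symbiont_flag_field: str = "SYMBIONT") -> SampleGraph:
    """Build the relationship graph from a validated manifest.

    Edge kind per row: flagged symbiont -> SAMPLE_SYMBIONT_OF;
    ORGANISM_PART == WHOLE_ORGANISM -> SAME_AS; otherwise
    SAMPLE_DERIVED_FROM.  As defence in depth the whole-organism
    uniqueness rule is re-checked here even though validation enforces
    it upstream.
    """
    graph = SampleGraph()
    specimens: dict[str, SampleNode] = {}
    for record in manifest.records:
        spid = record.get("SPECIMEN_ID")
        specimen = specimens.get(spid)
        if specimen is None:
            specimen = SampleNode(
                level="SPECIMEN", specimen_id=spid,
                metadata=dict(record.values),
            )
            specimens[spid] = specimen
            graph.nodes.append(specimen)
        sample = SampleNode(
            level="SAMPLE",
            specimen_id=spid,
            sample_key=make_sample_key(record.get("RACK_OR_PLATE_ID"),
                                       record.get("TUBE_OR_WELL_ID")),
            organism_part=record.get("ORGANISM_PART"),
            env_sample_id=record.get("ENV_SAMPLE_ID") or None,
            metadata=dict(record.values),
        )
        graph.nodes.append(sample)
        if record.get(symbiont_flag_field) == "SYMBIONT":
            kind = "SAMPLE_SYMBIONT_OF"
        elif record.get("ORGANISM_PART") == "WHOLE_ORGANISM":
            kind = "SAME_AS"
        else:
            kind = "SAMPLE_DERIVED_FROM"
        graph.edges.append(RelationshipEdge(kind, sample, specimen))

    for spid, specimen in specimens.items():
        children = [e for e in graph.edges if e.parent is specimen]
        if len(children) > 1 and any(e.kind == "SAME_AS" for e in children):
            raise GraphConstraintError(
                f"specimen {spid} has a whole-organism sample plus "
                f"{len(children) - 1} other sample(s)"
            )
    return graph


def check_graph(graph: SampleGraph) -> list[str]:
    """Re-derive every structural invariant by brute force.

    Returns an empty list iff the graph is valid; otherwise one message
    per broken rule, naming the node or edge involved.
    """
    violations: list[str] = []
    specimen_ids: dict[str, int] = {}
    for node in graph.nodes:
        if node.level == "SPECIMEN":
            specimen_ids[node.specimen_id] = \
                specimen_ids.get(node.specimen_id, 0) + 1
            if node.sample_key:
                violations.append(
                    f"specimen node {node.specimen_id} has a sample_key")
        elif node.level == "SAMPLE":
            if not node.sample_key:
                violations.append(
                    f"sample node for {node.specimen_id} lacks a sample_key")
        else:
            violations.append(f"node with unknown level {node.level!r}")
    for spid, count in specimen_ids.items():
        if count > 1:
            violations.append(
                f"{count} specimen nodes for SPECIMEN_ID {spid}")

    for edge in graph.edges:
        if edge.kind not in EDGE_KINDS:
            violations.append(f"edge with unknown kind {edge.kind!r}")
        if edge.parent.level != "SPECIMEN":
            violations.append(
                f"edge {edge.kind} parent {edge.parent.identifier} is not "
                "specimen-level")
        if edge.child.level != "SAMPLE":
            violations.append(
                f"edge {edge.kind} child {edge.child.identifier} is not "
                "sample-level")

    for node in graph.sample_nodes():
        attached = [e for e in graph.edges if e.child is node]
        if len(attached) != 1:
            violations.append(
                f"sample node {node.identifier} has {len(attached)} edges "
                "(expected exactly 1)")

    for specimen in graph.specimen_nodes():
        same_as = [e for e in graph.edges
                   if e.parent is specimen and e.kind == "SAME_AS"]
        if len(same_as) > 1:
            violations.append(
                f"specimen {specimen.specimen_id} has {len(same_as)} "
                "SAME_AS children (1:1 relationship)")
        if same_as and len([e for e in graph.edges
                            if e.parent is specimen]) > len(same_as):
            violations.append(
                f"specimen {specimen.specimen_id} mixes SAME_AS with other "
                "edges")
    return violations
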