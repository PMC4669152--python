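"""SWC skeleton input/output and validation.

Neuron skeletons are exchanged in the SWC format: one node per line with
seven whitespace-separated fields (id, structure code, x, y, z, radius,
parent id), ``#`` comment lines, ids 1-based, parent ``-1`` for the root.
Structure codes are restricted to 1 (soma) and 3 (dendrite); unknown codes
are preserved on read but reported as warnings by :func:`validate_skeleton`.

Coordinates are in micrometres and assumed registered so that +x is the
animal's anterior direction (skeletons traced from straightened images).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "ArborNode",
    "ArborSkeleton",
    "SwcParseError",
    "SkeletonValidationError",
    "read_swc",
    "write_swc",
    "validate_skeleton",
]

SOMA = 1
DENDRITE = 3
KNOWN_CODES = {SOMA, DENDRITE}


class SwcParseError(ValueError):
    """A line of an SWC file could not be parsed."""


class SkeletonValidationError(ValueError):
    """A skeleton violates a structural invariant."""


@dataclass(frozen=True)
class ArborNode:
    """One skeleton node: position in μm, SWC structure code, parent link."""

    id: int
    structure_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def position(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class ArborSkeleton:
    """A rooted geometric tree of :class:`ArborNode` for one PVD neuron.

    ``metadata`` carries free-form labels (genotype, larval stage,
    animal id) written as a key=value header comment on export.
    """

    nodes: list[ArborNode]
    soma_id: int
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {n.id: n for n in self.nodes}
        self._children: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1 and n.parent_id in self._children:
                self._children[n.parent_id].append(n.id)

    def node(self, node_id: int) -> ArborNode:
        return self._by_id[node_id]

    def children(self, node_id: int) -> list[int]:
        return self._children[node_id]

    def tips(self) -> list[int]:
        return [i for i, ch in self._children.items() if not ch]

    def __len__(self) -> int:
        return len(self.nodes)

    def validate(self) -> None:
        """Raise :class:`SkeletonValidationError` on the first violation."""
        report = validate_skeleton(self)
        errors = [v for v in report if not v.startswith("warning:")]
        if errors:
            raise SkeletonValidationError("; ".join(errors))


def validate_skeleton(arbor: ArborSkeleton) -> list[str]:
    """Check every skeleton invariant; return a list of violation strings.

    An empty list means the skeleton is valid. Violations are data, not
    exceptions; entries prefixed ``warning:`` (unknown structure codes) do
    not invalidate the skeleton.
    """
    report: list[str] = []
    seen: set[int] = set()
    for n in arbor.nodes:
        if n.id in seen:
            report.append(f"duplicate id {n.id}")
        seen.add(n.id)
        for coord, name in ((n.x, "x"), (n.y, "y"), (n.z, "z")):
            if not math.isfinite(coord):
                report.append(f"non-finite {name} coordinate at node {n.id}")
        if n.structure_code not in KNOWN_CODES:
            report.append(f"warning: unknown structure code {n.structure_code} at node {n.id}")

    roots = [n for n in arbor.nodes if n.parent_id == -1]
    for n in arbor.nodes:
        if n.parent_id != -1 and n.parent_id not in seen:
            report.append(f"unknown parent {n.parent_id} at node {n.id}")
    if len(roots) == 0:
        report.append("no root node (parent_id -1)")
    elif len(roots) > 1:
        report.append(f"multiple roots: {sorted(n.id for n in roots)}")

    if arbor.soma_id not in seen:
        report.append(f"soma id {arbor.soma_id} not among node ids")
    else:
        soma = arbor.node(arbor.soma_id)
        if soma.structure_code != SOMA:
            report.append(f"soma node {arbor.soma_id} has structure code {soma.structure_code}, expected {SOMA}")

    # connectivity / acyclicity on the undirected parent graph
    g = nx.Graph()
    g.add_nodes_from(n.id for n in arbor.nodes)
    g.add_edges_from(
        (n.id, n.parent_id) for n in arbor.nodes if n.parent_id != -1 and n.parent_id in seen
    )
    if len(arbor.nodes) and not nx.is_connected(g):
        report.append("skeleton is disconnected")
    if g.number_of_edges() >= g.number_of_nodes() and len(arbor.nodes):
        report.append("skeleton contains a cycle")
    elif len(arbor.nodes) and not nx.is_forest(g):
        report.append("skeleton contains a cycle")
    return report


def read_swc(path) -> ArborSkeleton:
    """Read an SWC file into a validated :class:`ArborSkeleton`.

    Node order and 1-based ids are preserved verbatim. Header comments of
    the form ``# key=value`` populate the skeleton metadata.

    Raises
    ------
    SwcParseError
        On a malformed line, naming the line number.
    SkeletonValidationError
        If the node table violates a tree invariant.
    """
    nodes: list[ArborNode] = []
    metadata: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                for token in body.split():
                    if "=" in token:
                        key, _, value = token.partition("=")
                        metadata[key.strip()] = value.strip()
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SwcParseError(f"line {lineno}: expected 7 fields, got {len(fields)}")
            try:
                nodes.append(
                    ArborNode(
                        id=int(fields[0]),
                        structure_code=int(fields[1]),
                        x=float(fields[2]),
                        y=float(fields[3]),
                        z=float(fields[4]),
                        radius=float(fields[5]),
                        parent_id=int(fields[6]),
                    )
                )
            except ValueError as exc:
                raise SwcParseError(f"line {lineno}: {exc}") from None
    if not nodes:
        raise SwcParseError("file contains no SWC node lines")
    soma_candidates = [n.id for n in nodes if n.structure_code == SOMA]
    soma_id = soma_candidates[0] if soma_candidates else -1
    arbor = ArborSkeleton(nodes=nodes, soma_id=soma_id, metadata=metadata)
    arbor.validate()
    return arbor


def write_swc(arbor: ArborSkeleton, path) -> None:
    """Write a skeleton as standard 7-column SWC with a metadata header."""
    with open(path, "w") as fh:
        if arbor.metadata:
            pairs = " ".join(f"{k}={v}" for k, v in sorted(arbor.metadata.items()))
            fh.write(f"# {pairs}\n")
        for n in arbor.nodes:
            # repr of a float is its shortest exact representation, so
            # write→read round-trips node tables bit-for-bit
            fh.write(
                f"{n.id} {n.structure_code} {n.x!r} {n.y!r} {n.z!r} "
                f"{n.radius!r} {n.parent_id}\n"
            )
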