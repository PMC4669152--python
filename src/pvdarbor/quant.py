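"""Branch-order classification and per-region morphometry of PVD arbors.

The PVD dendritic arbor is organized into repeating "menorah" units: a
secondary (2°) stem protruding from the primary (1°) dendrite, tertiary
(3°) arms running along the anterior–posterior (A-P) body axis, and
quaternary (4°) twigs rising orthogonally from the tertiaries. This module
extracts the primary path, classifies every branch into orders 1°–4°,
partitions the primary into four A-P regions (-1 posterior of the soma,
+1/+2/+3 equal-length anterior thirds), counts branches per region, and
computes the branch complexity index (BCI).

Classification rules
--------------------
* Any protrusion from the primary dendrite is a secondary, regardless of
  its length or orientation.
* A child of a secondary whose chord lies within ``theta_t`` of the A-P
  axis is a tertiary.
* A child of a tertiary deviating from the A-P axis by more than
  ``theta_q`` is a correctly-oriented quaternary; A-P-trending children
  of a tertiary either continue the tertiary (the child best aligned with
  the parent) or are labelled order 4 but flagged mis-oriented and
  excluded from the quaternary count.
* Quaternaries (and tertiaries) are assigned to the region containing the
  base of the secondary stem of their menorah, not their own position.

The branch complexity index per region averages three equally-weighted
components, each normalized to an "ideal" fully-formed segment::

    bci = ( n2/n2_star  +  n2_with3/n2  +  (n4/n3)/q_star ) / 3

so that a segment with the ideal secondary count, every secondary bearing
a tertiary, and the ideal quaternaries-per-tertiary ratio scores exactly 1.
Components are deliberately not clipped at 1: mutants with an anterior
shift of branching activity exceed the wild-type ideal in the distal
region, and clipping would erase that signal. Empty segments score 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ArborSkeleton

__all__ = [
    "REGIONS",
    "REGION_LABELS",
    "PrimaryPath",
    "Branch",
    "ClassifiedArbor",
    "RegionPartition",
    "RegionCounts",
    "ComplexityIndex",
    "ClassificationParams",
    "DegeneratePathError",
    "extract_primary",
    "classify_branch_orders",
    "segment_regions",
    "count_by_region",
    "branch_complexity",
    "count_filopodia",
    "quantify_arbor",
    "cohort_table",
]

#: Region keys in anatomical order: posterior of soma, then proximal,
#: middle and distal anterior thirds.
REGIONS = (-1, 1, 2, 3)
REGION_LABELS = {-1: "-1", 1: "+1", 2: "+2", 3: "+3"}


class DegeneratePathError(ValueError):
    """The skeleton lacks a posterior (or anterior) primary arm.

    ``partial`` carries the best single-arm path found.
    """

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


@dataclass
class PrimaryPath:
    """The 1° dendrite: posterior tip → soma → anterior tip.

    Arc length is signed: 0 at the soma, positive anterior.
    """

    node_ids: list[int]
    soma_id: int
    arc_length: dict[int, float]

    @property
    def anterior_extent(self) -> float:
        return max(self.arc_length.values())

    @property
    def posterior_extent(self) -> float:
        return -min(self.arc_length.values())

    def arc_length_of(self, node_id: int) -> float:
        return self.arc_length[node_id]


@dataclass
class Branch:
    """A maximal unbranched chain of non-primary nodes.

    ``is_unit_root`` marks the first chain of a branch *unit* (its parent
    chain has a lower order); continuations of the same unit share the
    unit root's base positions. Counting is over unit roots, so a tertiary
    arm split into segments by quaternary attachment points still counts
    as one tertiary.
    """

    nodes: list[int]
    order: int
    base_node: int
    base_position: float
    base_secondary_position: float
    length: float
    mean_direction: np.ndarray
    parent_index: int | None
    secondary_root: int  # index of the order-2 unit root this belongs to
    is_unit_root: bool = True
    correctly_oriented: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass
class ClassifiedArbor:
    skeleton: ArborSkeleton
    primary: PrimaryPath
    branches: list[Branch]

    def unit_roots(self, order: int) -> list[Branch]:
        return [b for b in self.branches if b.order == order and b.is_unit_root]


@dataclass(frozen=True)
class ClassificationParams:
    """Orientation thresholds (degrees from the A-P axis).

    ``theta_t``: a child of a 2° within this angle of the A-P axis is a 3°.
    ``theta_q``: a child of a 3° deviating by more than this is a 4°.
    Defaults reflect the orthogonal menorah geometry.
    """

    theta_t: float = 45.0
    theta_q: float = 45.0
    #: a chain is split where successive edges turn by more than this,
    #: so order transitions without a bifurcation node (e.g. a stem whose
    #: single surviving tertiary arm turns 90°) are still detected
    split_angle: float = 60.0


@dataclass
class RegionPartition:
    """Half-open A-P intervals: -1 = [-L_p, 0), +k = anterior thirds.

    Bases landing exactly on a boundary go to the more anterior region.
    """

    anterior_extent: float
    posterior_extent: float

    @property
    def boundaries(self) -> tuple[float, float, float]:
        la = self.anterior_extent
        return (0.0, la / 3.0, 2.0 * la / 3.0)

    def region_of(self, s: float) -> int:
        if s < 0.0:
            return -1
        la = self.anterior_extent
        if s < la / 3.0:
            return 1
        if s < 2.0 * la / 3.0:
            return 2
        return 3

    def interval(self, region: int) -> tuple[float, float]:
        la = self.anterior_extent
        return {
            -1: (-self.posterior_extent, 0.0),
            1: (0.0, la / 3.0),
            2: (la / 3.0, 2.0 * la / 3.0),
            3: (2.0 * la / 3.0, la),
        }[region]


@dataclass
class RegionCounts:
    """Per-region branch counts: 2°, 2°-bearing-3°, 3°, 4°."""

    n2: dict[int, int]
    n2_with3: dict[int, int]
    n3: dict[int, int]
    n4: dict[int, int]

    @staticmethod
    def zeros() -> "RegionCounts":
        z = lambda: {r: 0 for r in REGIONS}  # noqa: E731
        return RegionCounts(z(), z(), z(), z())

    @property
    def total_n2(self) -> int:
        return sum(self.n2.values())

    @property
    def total_n3(self) -> int:
        return sum(self.n3.values())

    @property
    def total_n4(self) -> int:
        return sum(self.n4.values())


@dataclass
class ComplexityIndex:
    """Per-region BCI and its three components."""

    c_n2: dict[int, float]
    c_p3: dict[int, float]
    c_q4: dict[int, float]
    bci: dict[int, float]
    n2_star: dict[int, float]
    q_star: float


def _chord_direction(skeleton: ArborSkeleton, base: int, tip: int) -> np.ndarray:
    p0 = np.asarray(skeleton.node(base).position)
    p1 = np.asarray(skeleton.node(tip).position)
    d = p1 - p0
    n = np.linalg.norm(d)
    return d / n if n > 0 else d


def _ap_angle_deg(direction: np.ndarray) -> float:
    """Angle (deg) between a direction and the A-P (x) axis, in [0, 90]."""
    n = np.linalg.norm(direction)
    if n == 0:
        return 90.0
    return math.degrees(math.acos(min(1.0, abs(float(direction[0])) / n)))


def extract_primary(arbor: ArborSkeleton) -> PrimaryPath:
    """Extract the 1° dendrite as the tip-to-tip path through the soma
    spanning the greatest anterior–posterior extent.

    One arm must trend anterior (+x of the soma) and one posterior; the
    span criterion (rather than raw arc length) keeps long tertiary arms
    of posterior menorahs from hijacking the path. Arc length is signed
    with the soma at 0 and anterior positive.

    Raises
    ------
    DegeneratePathError
        If every tip lies anterior (or posterior) of the soma; the error
        carries the best single-arm path as ``partial``.
    """
    soma = arbor.node(arbor.soma_id)
    if len(arbor.tips()) < 2:
        raise DegeneratePathError("skeleton has fewer than two tips")

    # one candidate arm per soma neighbor: the subtree tip with extreme x
    best_ant: dict[int, tuple[float, float, list[int]]] = {}
    best_post: dict[int, tuple[float, float, list[int]]] = {}
    neighbors = list(arbor.children(arbor.soma_id))
    if soma.parent_id != -1:
        neighbors.append(soma.parent_id)

    for nb in neighbors:
        # DFS over the subtree reached through this neighbor
        stack = [(nb, arbor.soma_id, [arbor.soma_id, nb])]
        while stack:
            u, prev, path = stack.pop()
            adjacent = list(arbor.children(u))
            pu = arbor.node(u).parent_id
            if pu != -1:
                adjacent.append(pu)
            nxt = [v for v in adjacent if v != prev]
            if not nxt:  # tip
                x = arbor.node(u).x
                length = _path_length(arbor, path)
                if x > soma.x:
                    cur = best_ant.get(nb)
                    if cur is None or (x, length) > (cur[0], cur[1]):
                        best_ant[nb] = (x, length, path)
                if x < soma.x:
                    cur = best_post.get(nb)
                    if cur is None or (-x, length) > (-cur[0], cur[1]):
                        best_post[nb] = (x, length, path)
            for v in nxt:
                stack.append((v, u, path + [v]))

    if not best_ant or not best_post:
        partial = None
        pool = best_ant or best_post
        if pool:
            partial = max(pool.values(), key=lambda t: t[1])[2]
        side = "posterior" if not best_post else "anterior"
        raise DegeneratePathError(f"no {side} arm: all tips lie on one side of the soma", partial=partial)

    best = None
    for nb_a, (xa, la, path_a) in best_ant.items():
        for nb_p, (xp, lp, path_p) in best_post.items():
            if nb_a == nb_p:
                continue
            key = (xa - xp, la + lp)
            if best is None or key > best[0]:
                best = (key, path_a, path_p)
    if best is None:
        raise DegeneratePathError("anterior and posterior arms share the soma neighbor")

    _, path_a, path_p = best
    # posterior tip ... soma ... anterior tip
    node_ids = list(reversed(path_p)) + path_a[1:]
    arc = _signed_arc_lengths(arbor, node_ids, arbor.soma_id)
    return PrimaryPath(node_ids=node_ids, soma_id=arbor.soma_id, arc_length=arc)


def _path_length(arbor: ArborSkeleton, path: list[int]) -> float:
    total = 0.0
    for a, b in zip(path, path[1:]):
        pa, pb = arbor.node(a).position, arbor.node(b).position
        total += math.dist(pa, pb)
    return total


def _signed_arc_lengths(arbor: ArborSkeleton, node_ids: list[int], soma_id: int) -> dict[int, float]:
    cum = [0.0]
    for a, b in zip(node_ids, node_ids[1:]):
        cum.append(cum[-1] + math.dist(arbor.node(a).position, arbor.node(b).position))
    s0 = cum[node_ids.index(soma_id)]
    return {nid: c - s0 for nid, c in zip(node_ids, cum)}


def classify_branch_orders(
    arbor: ArborSkeleton,
    primary: PrimaryPath,
    params: ClassificationParams = ClassificationParams(),
) -> ClassifiedArbor:
    """Label every non-primary branch chain with an order 1°–4°.

    Branch chains deeper than 4° are labelled order 4 and flagged
    ``beyond_quaternary`` (a warning condition, not an error).
    """
    primary_set = set(primary.node_ids)
    branches: list[Branch] = []

    # each entry: (first_node, attachment_node, parent_branch_index)
    work: list[tuple[int, int, int | None]] = []
    for u in primary.node_ids:
        for c in arbor.children(u):
            if c not in primary_set:
                work.append((c, u, None))

    while work:
        first, attach, parent_idx = work.pop(0)
        chain, next_children = _walk_chain(arbor, first, attach, params)
        direction = _chord_direction(arbor, attach, chain[-1])
        length = _path_length(arbor, [attach] + chain)
        ap = _ap_angle_deg(direction)

        if parent_idx is None:
            order, unit_root, correct = 2, True, True
            base_pos = primary.arc_length_of(attach)
            sec_pos = base_pos
            flags: list[str] = []
            secondary_root = len(branches)
        else:
            parent = branches[parent_idx]
            base_pos = parent.base_position
            sec_pos = parent.base_secondary_position
            secondary_root = parent.secondary_root
            flags = []
            if parent.order == 2:
                if ap <= params.theta_t:
                    order, unit_root, correct = 3, True, True
                else:
                    order, unit_root, correct = 2, False, True
                    flags.append("secondary_fork")
            elif parent.order == 3:
                if ap > params.theta_q:
                    order, unit_root, correct = 4, True, True
                else:
                    # A-P-trending child of a tertiary: the sibling best
                    # aligned with the parent chord continues the unit,
                    # any other is a mis-oriented quaternary
                    if _is_continuation(arbor, branches, parent_idx, attach, chain, params):
                        order, unit_root, correct = 3, False, True
                    else:
                        order, unit_root, correct = 4, True, False
                        flags.append("not_correctly_oriented")
            else:  # parent order 4 (or beyond)
                order, unit_root, correct = 4, False, True
                flags.append("beyond_quaternary")

        branches.append(
            Branch(
                nodes=chain,
                order=order,
                base_node=attach,
                base_position=base_pos,
                base_secondary_position=sec_pos,
                length=length,
                mean_direction=direction,
                parent_index=parent_idx,
                secondary_root=secondary_root,
                is_unit_root=unit_root,
                correctly_oriented=correct,
                flags=flags,
            )
        )
        this_idx = len(branches) - 1
        for c in next_children:
            work.append((c, chain[-1], this_idx))

    return ClassifiedArbor(skeleton=arbor, primary=primary, branches=branches)


def _walk_chain(
    arbor: ArborSkeleton,
    first: int,
    attach: int,
    params: ClassificationParams,
) -> tuple[list[int], list[int]]:
    """Follow single-child nodes from ``first``, stopping at a bifurcation,
    a tip, or a kink sharper than ``params.split_angle``.

    Returns the chain and the child nodes where successor branches start.
    """
    chain = [first]
    prev_edge = _chord_direction(arbor, attach, first)
    cur = first
    while True:
        ch = arbor.children(cur)
        if len(ch) != 1:
            return chain, list(ch)
        nxt = ch[0]
        edge = _chord_direction(arbor, cur, nxt)
        cosang = float(np.clip(np.dot(prev_edge, edge), -1.0, 1.0))
        if math.degrees(math.acos(cosang)) > params.split_angle:
            return chain, [nxt]
        chain.append(nxt)
        prev_edge = edge
        cur = nxt


def _is_continuation(
    arbor: ArborSkeleton,
    branches: list[Branch],
    parent_idx: int,
    attach: int,
    chain: list[int],
    params: ClassificationParams,
) -> bool:
    """Among A-P-trending siblings at a tertiary split, only the child most
    parallel to the parent chord is the continuation of the tertiary."""
    parent = branches[parent_idx]
    sibs = []
    for c in arbor.children(attach):
        sib_chain, _ = _walk_chain(arbor, c, attach, params)
        d = _chord_direction(arbor, attach, sib_chain[-1])
        if _ap_angle_deg(d) <= params.theta_q:
            sibs.append((c, float(np.dot(d, parent.mean_direction))))
    if not sibs:
        return False
    best = max(sibs, key=lambda t: t[1])[0]
    return best == chain[0]


def segment_regions(primary: PrimaryPath) -> RegionPartition:
    """Partition the primary path into regions -1 / +1 / +2 / +3.

    The anterior extent [0, L_a] is cut into three equal-length thirds;
    whatever posterior extent exists forms region -1 (it is not
    length-matched to the anterior thirds).
    """
    la = primary.anterior_extent
    lp = primary.posterior_extent
    if la <= 0:
        raise ValueError("primary path has zero anterior extent")
    return RegionPartition(anterior_extent=la, posterior_extent=lp)


def count_by_region(classified: ClassifiedArbor, partition: RegionPartition) -> RegionCounts:
    """Count 2°/3°/4° branch units per region.

    Secondaries are assigned by the position of their base on the primary;
    tertiaries and quaternaries by the base of the secondary stem of their
    menorah, even when their own extent crosses a region boundary.
    """
    counts = RegionCounts.zeros()
    sec_regions: dict[int, int] = {}
    sec_has3: dict[int, bool] = {}
    for i, b in enumerate(classified.branches):
        if b.order == 2 and b.is_unit_root:
            r = partition.region_of(b.base_position)
            counts.n2[r] += 1
            sec_regions[i] = r
            sec_has3.setdefault(i, False)
    for b in classified.branches:
        r = partition.region_of(b.base_secondary_position)
        if b.order == 3 and b.is_unit_root:
            counts.n3[r] += 1
            sec_has3[b.secondary_root] = True
        elif b.order == 4 and b.is_unit_root and b.correctly_oriented:
            counts.n4[r] += 1
    for i, has3 in sec_has3.items():
        if has3:
            counts.n2_with3[sec_regions[i]] += 1
    return counts


def branch_complexity(
    counts: RegionCounts,
    n2_star: float | dict[int, float],
    q_star: float,
) -> ComplexityIndex:
    """Compute the branch complexity index per region.

    Parameters
    ----------
    n2_star
        Ideal secondary count per region (scalar, or mapping per region).
    q_star
        Ideal number of quaternaries per tertiary.
    """
    if isinstance(n2_star, (int, float)):
        n2_star = {r: float(n2_star) for r in REGIONS}
    if any(v <= 0 for v in n2_star.values()) or q_star <= 0:
        raise ValueError("ideal-segment parameters n2_star and q_star must be positive")
    c_n2, c_p3, c_q4, bci = {}, {}, {}, {}
    for r in REGIONS:
        c_n2[r] = counts.n2[r] / n2_star[r]
        c_p3[r] = counts.n2_with3[r] / counts.n2[r] if counts.n2[r] > 0 else 0.0
        c_q4[r] = (counts.n4[r] / counts.n3[r]) / q_star if counts.n3[r] > 0 else 0.0
        bci[r] = (c_n2[r] + c_p3[r] + c_q4[r]) / 3.0
    return ComplexityIndex(c_n2=c_n2, c_p3=c_p3, c_q4=c_q4, bci=bci, n2_star=dict(n2_star), q_star=q_star)


def count_filopodia(classified: ClassifiedArbor, stage: str) -> int:
    """Total 2° protrusion count over the whole arbor (L2/L3 animals only).

    At these stages the arbor has not yet elaborated into regions worth
    splitting, so only the whole-arbor secondary count is tabulated.
    """
    if stage not in ("L2", "L3"):
        raise ValueError(f"stage {stage!r}: filopodia are counted at L2/L3 only; use count_by_region for L4")
    return sum(1 for b in classified.branches if b.order == 2 and b.is_unit_root)


def quantify_arbor(
    arbor: ArborSkeleton,
    params: ClassificationParams = ClassificationParams(),
    n2_star: float | dict[int, float] = 14.0,
    q_star: float = 5.0,
):
    """Run the full per-arbor pipeline; returns (classified, partition, counts, complexity)."""
    primary = extract_primary(arbor)
    classified = classify_branch_orders(arbor, primary, params)
    partition = segment_regions(primary)
    counts = count_by_region(classified, partition)
    cx = branch_complexity(counts, n2_star=n2_star, q_star=q_star)
    return classified, partition, counts, cx


def cohort_table(
    arbors,
    params: ClassificationParams = ClassificationParams(),
    n2_star: float | dict[int, float] = 14.0,
    q_star: float = 5.0,
) -> pd.DataFrame:
    """Quantify a cohort into a tidy table: one row per (animal, region).

    Columns: genotype, animal_id, region, n2, n2_with3, n3, n4,
    c_n2, c_p3, c_q4, bci. Genotype and animal id come from skeleton
    metadata (empty string if absent).
    """
    rows = []
    for k, arbor in enumerate(arbors):
        _, _, counts, cx = quantify_arbor(arbor, params=params, n2_star=n2_star, q_star=q_star)
        meta = arbor.metadata
        for r in REGIONS:
            rows.append(
                {
                    "genotype": meta.get("genotype", ""),
                    "animal_id": meta.get("animal_id", str(k)),
                    "region": REGION_LABELS[r],
                    "n2": counts.n2[r],
                    "n2_with3": counts.n2_with3[r],
                    "n3": counts.n3[r],
                    "n4": counts.n4[r],
                    "c_n2": cx.c_n2[r],
                    "c_p3": cx.c_p3[r],
                    "c_q4": cx.c_q4[r],
                    "bci": cx.bci[r],
                }
            )
    return pd.DataFrame(rows)
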