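"""Per-cluster UPGMA trees, patristic medoids, and representative selection.

Each subfamily is summarised by representatives chosen for synthesis: the
medoid (the member with the smallest summed patristic distance to all other
members on the cluster's UPGMA tree) plus, for clusters of more than 100
members, additional sequences spread evenly along the bit-score axis so that
every representative covers between 50 and 100 members.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import p_distance
from .errors import DataError, ParseError
from .family_mining import SequenceRecord


# ---------------------------------------------------------------------------
# Distance matrix


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DataError("distance matrix shape does not match labels")
        if np.isnan(self.d).any():
            raise DataError("distance matrix contains NaN")
        if (self.d < 0).any():
            raise DataError("distances must be non-negative")
        if not np.allclose(self.d, self.d.T):
            raise DataError("distance matrix must be symmetric")
        if not np.allclose(np.diagonal(self.d), 0):
            raise DataError("distance matrix diagonal must be zero")


def pairwise_distances(records: list[SequenceRecord]) -> DistanceMatrix:
    """All-pairs p-distances (1 - identity over aligned length) from global
    pairwise alignments."""
    if len(records) < 2:
        raise DataError("need at least 2 records for a distance matrix")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(records[i].residues, records[j].residues)
    return DistanceMatrix(labels=[r.id for r in records], d=d)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    branch_length: float = 0.0
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Rooted tree with branch lengths; serialises losslessly to Newick."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths."""
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            acc += node.branch_length
            if node.is_leaf:
                depths[node.label] = acc
            for child in node.children:
                walk(child, acc)

        walk(self.root, -self.root.branch_length)  # root's own length excluded
        return depths


def _fmt_length(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree: Tree) -> str:
    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.label}:{_fmt_length(node.branch_length)}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{_fmt_length(node.branch_length)}"

    return render(tree.root) + ";"


def read_newick(text: str) -> Tree:
    """Parse a Newick string with branch lengths into a Tree.

    Raises :class:`ParseError` with the character position for unbalanced
    parentheses or a missing semicolon.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise ParseError(f"missing semicolon at position {len(text)}")
    s = text[:-1]
    pos = 0

    def error(msg: str):
        raise ParseError(f"{msg} at position {pos}")

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                error(f"unexpected character {s[pos]!r}")
        # label
        start = pos
        while pos < len(s) and s[pos] not in ":,();":
            pos += 1
        label = s[start:pos].strip()
        if label:
            node.label = label
        # branch length
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            try:
                node.branch_length = float(s[start:pos])
            except ValueError:
                error(f"bad branch length {s[start:pos]!r}")
        return node

    root = parse_node()
    if pos != len(s):
        error("unbalanced parentheses or trailing text")
    labels = [leaf.label for leaf in Tree(root).leaves()]
    if any(lbl is None for lbl in labels):
        raise ParseError("leaf without a label")
    if len(set(labels)) != len(labels):
        raise ParseError("duplicate leaf labels")
    return Tree(root)


# ---------------------------------------------------------------------------
# UPGMA


def upgma(matrix: DistanceMatrix) -> Tree:
    """Size-weighted average-linkage agglomeration into an ultrametric tree.

    The closest pair of clusters is merged at height d/2; inter-cluster
    distances are updated as the size-weighted arithmetic mean; ties are
    broken by the smallest (row, column) index pair in the current working
    matrix.  The merged cluster takes the row of its first member, keeping
    index order stable for deterministic tie-breaking.
    """
    n = len(matrix.labels)
    if n < 2:
        raise DataError("UPGMA needs at least 2 leaves")
    nodes = [TreeNode(label=lbl) for lbl in matrix.labels]
    heights = [0.0] * n
    sizes = [1] * n
    work = matrix.d.copy()
    active = list(range(n))

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                dij = work[active[ai], active[aj]]
                if best is None or dij < best[0]:
                    best = (dij, ai, aj)
        dmin, ai, aj = best
        i, j = active[ai], active[aj]
        height = dmin / 2.0
        nodes[i].branch_length = height - heights[i]
        nodes[j].branch_length = height - heights[j]
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # merged cluster reuses slot i
        for ak in active:
            if ak in (i, j):
                continue
            dnew = (sizes[i] * work[i, ak] + sizes[j] * work[j, ak]) / (
                sizes[i] + sizes[j]
            )
            work[i, ak] = work[ak, i] = dnew
        nodes[i] = parent
        heights[i] = height
        sizes[i] += sizes[j]
        active.pop(aj)

    root = nodes[active[0]]
    root.branch_length = 0.0
    return Tree(root)


# ---------------------------------------------------------------------------
# Patristic distances and medoids


def patristic_sums(tree: Tree) -> dict[str, float]:
    """For each leaf, the summed path length to all other leaves.

    Linear-time: an edge with s leaves below it lies on the path from a leaf
    under it to each of the (n - s) leaves outside, and vice versa, so
    sum(leaf) = sum_e bl_e * s_e + sum_{e above leaf} bl_e * (n - 2 s_e).
    """
    leaves = tree.leaves()
    n = len(leaves)
    if n < 2:
        raise DataError("patristic sums need at least 2 leaves")

    below: dict[int, int] = {}

    def count(node: TreeNode) -> int:
        s = 1 if node.is_leaf else sum(count(c) for c in node.children)
        below[id(node)] = s
        return s

    count(tree.root)
    base = 0.0

    def collect_base(node: TreeNode) -> None:
        nonlocal base
        if node is not tree.root:
            base += node.branch_length * below[id(node)]
        for c in node.children:
            collect_base(c)

    collect_base(tree.root)

    sums: dict[str, float] = {}

    def walk(node: TreeNode, acc: float) -> None:
        if node is not tree.root:
            acc += node.branch_length * (n - 2 * below[id(node)])
        if node.is_leaf:
            sums[node.label] = base + acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, 0.0)
    return sums


def patristic_matrix(tree: Tree) -> DistanceMatrix:
    """All-pairs leaf-to-leaf path lengths (quadratic; used for checks)."""
    paths: dict[str, list[tuple[TreeNode, float]]] = {}

    def walk(node: TreeNode, trail: list[tuple[TreeNode, float]]) -> None:
        trail = trail + [(node, node.branch_length if node is not tree.root else 0.0)]
        if node.is_leaf:
            paths[node.label] = trail
        for c in node.children:
            walk(c, trail)

    walk(tree.root, [])
    labels = sorted(paths)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = paths[labels[i]]
            b = paths[labels[j]]
            shared = 0
            for (na, _), (nb, _) in zip(a, b):
                if na is nb:
                    shared += 1
                else:
                    break
            dist = sum(bl for _, bl in a[shared:]) + sum(bl for _, bl in b[shared:])
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=labels, d=d)


def select_medoid(sums: dict[str, float]) -> str:
    """Leaf with the minimal summed patristic distance; ties break to the
    lexicographically smallest id."""
    if not sums:
        raise DataError("empty patristic sums")
    return min(sums, key=lambda k: (sums[k], k))


# ---------------------------------------------------------------------------
# Representative assignment


@dataclass
class RepresentativeAssignment:
    cluster_id: str
    representatives: list[str]  # medoid first
    membership: dict[str, str]  # member -> representative
    scores: dict[str, float]  # member -> bit score to medoid
    within_bounds: bool = True
    relaxed: bool = False

    @property
    def medoid(self) -> str:
        return self.representatives[0]

    def loads(self) -> dict[str, int]:
        out = {rep: 0 for rep in self.representatives}
        for rep in self.membership.values():
            out[rep] += 1
        return out


def select_additional_representatives(
    member_ids: list[str],
    medoid: str,
    bitscores_to_medoid: dict[str, float],
    min_size: int = 50,
    max_size: int = 100,
    cluster_id: str = "",
    load_tolerance: int = 10,
) -> RepresentativeAssignment:
    """Choose representatives so each covers at most ``max_size`` members.

    For N <= max_size the medoid covers everyone.  Otherwise k = ceil(N /
    max_size) representatives are used: the medoid plus k-1 members whose bit
    scores to the medoid are nearest to k-1 evenly spaced target values
    strictly between the observed minimum and maximum score (ties break to
    the lexicographically smaller id).  Members are then assigned along the
    bit-score axis: sorted by score, they are split into k contiguous
    near-equal blocks, one per representative in score order, so every
    representative's load is floor(N/k) or ceil(N/k).  The medoid is always
    assigned to itself (shifting at most one load by one).  Assigning each
    member instead to the representative with the literally closest score
    would let the medoid's extremal self-score starve one block and push
    another past ``max_size``, defeating the 50-100 coverage rule the
    representatives exist to satisfy.
    """
    if len(set(member_ids)) != len(member_ids):
        raise DataError("duplicate member ids")
    if medoid not in member_ids:
        raise DataError("medoid must be a cluster member")
    missing = [m for m in member_ids if m not in bitscores_to_medoid]
    if missing:
        raise DataError(f"missing bit scores for {missing[:5]}")

    n = len(member_ids)
    if n <= max_size:
        return RepresentativeAssignment(
            cluster_id=cluster_id,
            representatives=[medoid],
            membership={m: medoid for m in member_ids},
            scores=dict(bitscores_to_medoid),
        )

    k = math.ceil(n / max_size)
    others = [m for m in member_ids if m != medoid]
    lo = min(bitscores_to_medoid[m] for m in member_ids)
    hi = max(bitscores_to_medoid[m] for m in member_ids)
    reps = [medoid]
    pool = set(others)
    for j in range(1, k):
        target = lo + j * (hi - lo) / k
        pick = min(
            pool, key=lambda m: (abs(bitscores_to_medoid[m] - target), m)
        )
        reps.append(pick)
        pool.discard(pick)

    ordered = sorted(member_ids, key=lambda m: (bitscores_to_medoid[m], m))
    reps_by_score = sorted(reps, key=lambda m: (bitscores_to_medoid[m], m))
    base, extra = divmod(n, k)
    membership: dict[str, str] = {}
    cursor = 0
    for block_idx, rep in enumerate(reps_by_score):
        size = base + (1 if block_idx < extra else 0)
        for m in ordered[cursor : cursor + size]:
            membership[m] = rep
        cursor += size
    membership[medoid] = medoid
    for rep in reps:
        membership[rep] = rep

    assignment = RepresentativeAssignment(
        cluster_id=cluster_id,
        representatives=reps,
        membership=membership,
        scores=dict(bitscores_to_medoid),
    )
    loads = assignment.loads().values()
    assignment.within_bounds = all(min_size <= l <= max_size for l in loads)
    if not assignment.within_bounds:
        relaxed_min = max(0, n // k - load_tolerance)
        assignment.relaxed = all(relaxed_min <= l <= max_size for l in loads)
    return assignment


def write_representatives(
    assignments: list[RepresentativeAssignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("cluster\trep_id\tmember_id\tbitscore\n")
        for a in assignments:
            for member in sorted(a.membership):
                fh.write(
                    f"{a.cluster_id}\t{a.membership[member]}\t{member}\t"
                    f"{a.scores.get(member, float('nan')):.6g}\n"
                )


def assignment_to_json(assignment: RepresentativeAssignment) -> str:
    return json.dumps(
        {
            "cluster": assignment.cluster_id,
            "representatives": assignment.representatives,
            "membership": assignment.membership,
            "within_bounds": assignment.within_bounds,
            "relaxed": assignment.relaxed,
        },
        indent=2,
    )
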