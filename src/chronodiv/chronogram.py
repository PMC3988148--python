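"""Chronogram container, Newick I/O, and the summaries downstream methods consume.

A chronogram is a rooted, strictly binary, ultrametric tree whose branch
lengths are in absolute time (Ma, millions of years).  Node ages are measured
backward from the present: every tip sits at age 0 and the crown (root) node
is the oldest point.  All temporal diversification statistics in this package
operate on the vector of internal-node ages (:class:`BranchingTimes`); the
topology-based ones operate on the per-node split sizes
(:class:`SplitRecord`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "BranchingTimes",
    "SplitRecord",
    "ChronogramError",
    "parse_chronogram",
    "write_chronogram",
    "branching_times",
    "split_records",
]

#: relative tolerance (w.r.t. crown age) for root-to-tip path equality
ULTRAMETRIC_RTOL = 1e-6


class ChronogramError(ValueError):
    """Raised for malformed or invalid input trees."""


@dataclass(frozen=True)
class BranchingTimes:
    """Internal-node ages of a chronogram, sorted oldest first.

    ``ages[0]`` is the crown age; the vector has ``n_tips - 1`` entries and
    is the sufficient statistic for every temporal method here.
    """

    ages: np.ndarray
    n_tips: int

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        object.__setattr__(self, "ages", ages)
        if ages.ndim != 1 or len(ages) != self.n_tips - 1:
            raise ChronogramError(
                f"expected {self.n_tips - 1} branching times, got {len(ages)}"
            )
        if np.any(ages <= 0):
            raise ChronogramError("branching times must be strictly positive")
        if np.any(np.diff(ages) > 0):
            raise ChronogramError("branching times must be sorted descending")

    @property
    def crown_age(self) -> float:
        return float(self.ages[0])

    def rescaled(self, crown_age: float) -> "BranchingTimes":
        """Return a copy linearly rescaled to the given crown age."""
        return BranchingTimes(self.ages * (crown_age / self.crown_age), self.n_tips)


@dataclass(frozen=True)
class SplitRecord:
    """Tip counts on either side of one internal node."""

    node_id: int
    left_tips: int
    right_tips: int
    subtree_age: float

    @property
    def size(self) -> int:
        return self.left_tips + self.right_tips


class Chronogram:
    """Rooted, binary, ultrametric time tree.

    Stored as flat parent/child arrays; index 0 is the root.  Tips carry
    unique labels; internal labels are ignored on read and omitted on write.
    """

    def __init__(
        self,
        parent: np.ndarray,
        children: list[tuple[int, int] | None],
        brlen: np.ndarray,
        labels: list[str | None],
    ):
        self.parent = np.asarray(parent, dtype=int)
        self.children = children
        self.brlen = np.asarray(brlen, dtype=float)
        self.labels = labels
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Chronogram":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise ChronogramError(f"Newick parse failure: {exc}") from exc
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        brlen = np.zeros(n, dtype=float)
        children: list[tuple[int, int] | None] = [None] * n
        labels: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            ch = nd.child_nodes()
            if len(ch) == 0:
                if nd.taxon is None or not nd.taxon.label:
                    raise ChronogramError("unlabeled tip")
                labels[i] = nd.taxon.label
            elif len(ch) == 2:
                children[i] = (index[id(ch[0])], index[id(ch[1])])
            else:
                raise ChronogramError(
                    f"tree is not strictly binary (node with {len(ch)} children)"
                )
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise ChronogramError("missing branch length")
                brlen[i] = float(nd.edge.length)
        return cls(parent, children, brlen, labels)

    def _validate(self) -> None:
        n = len(self.parent)
        tips = [i for i in range(n) if self.children[i] is None]
        self.tip_indices = np.array(tips, dtype=int)
        self.n_tips = len(tips)
        if self.n_tips < 2:
            raise ChronogramError("a chronogram needs at least 2 tips")
        tip_labels = [self.labels[i] for i in tips]
        if len(set(tip_labels)) != len(tip_labels):
            raise ChronogramError("duplicate tip labels")
        if np.any(self.brlen[1:] <= 0):
            raise ChronogramError("all branch lengths must be strictly positive")
        # depths from root, preorder (parents precede children by construction)
        depth = np.zeros(n, dtype=float)
        for i in range(1, n):
            depth[i] = depth[self.parent[i]] + self.brlen[i]
        crown = depth[self.tip_indices].max()
        tip_depths = depth[self.tip_indices]
        if crown <= 0:
            raise ChronogramError("zero-depth tree")
        if np.any(np.abs(tip_depths - crown) > ULTRAMETRIC_RTOL * crown):
            worst = float(np.max(np.abs(tip_depths - crown)))
            raise ChronogramError(
                f"tree is not ultrametric (max tip-depth deviation {worst:g} "
                f"vs crown {crown:g})"
            )
        age = crown - depth
        age[self.tip_indices] = 0.0  # snap rounding noise to exactly the present
        self.age = age
        self.crown_age = float(crown)

    # -- derived summaries --------------------------------------------

    def branching_times(self) -> BranchingTimes:
        internal = [i for i in range(len(self.parent)) if self.children[i] is not None]
        ages = np.sort(self.age[internal], kind="stable")[::-1]
        return BranchingTimes(ages, self.n_tips)

    def _subtree_tip_counts(self) -> np.ndarray:
        n = len(self.parent)
        counts = np.zeros(n, dtype=int)
        for i in range(n - 1, -1, -1):  # postorder over the preorder layout
            ch = self.children[i]
            if ch is None:
                counts[i] = 1
            else:
                counts[i] = counts[ch[0]] + counts[ch[1]]
        return counts

    def split_records(self) -> list[SplitRecord]:
        counts = self._subtree_tip_counts()
        out = []
        for i in range(len(self.parent)):
            ch = self.children[i]
            if ch is not None:
                out.append(
                    SplitRecord(i, int(counts[ch[0]]), int(counts[ch[1]]), float(self.age[i]))
                )
        return out

    # -- manipulation --------------------------------------------------

    def rescaled(self, crown_age: float) -> "Chronogram":
        """Linearly rescale all branch lengths so the crown sits at *crown_age*."""
        f = crown_age / self.crown_age
        return Chronogram(
            self.parent.copy(), list(self.children), self.brlen * f, list(self.labels)
        )

    def pruned_to(self, keep_labels) -> "Chronogram":
        """Restrict to a subset of tips, suppressing unifurcations.

        The result is the induced subtree on *keep_labels*: removed tips'
        branches are deleted and pass-through nodes merged, so remaining
        node ages are unchanged (this is uniform-sampling semantics).
        """
        keep = set(keep_labels)
        missing = keep - {self.labels[i] for i in self.tip_indices}
        if missing:
            raise ChronogramError(f"labels not in tree: {sorted(missing)[:5]}")
        if len(keep) < 2:
            raise ChronogramError("need at least 2 tips after pruning")
        n = len(self.parent)
        alive = np.zeros(n, dtype=bool)
        for i in self.tip_indices:
            if self.labels[i] in keep:
                alive[i] = True
        for i in range(n - 1, 0, -1):
            if alive[i]:
                alive[self.parent[i]] = True
        # a surviving internal node is a pass-through if only one child survives
        newick = self._write_pruned(alive)
        return Chronogram.from_newick(newick)

    def _write_pruned(self, alive: np.ndarray) -> str:
        # iterative writer over the surviving induced subtree
        def surviving_children(i: int) -> list[int]:
            ch = self.children[i]
            if ch is None:
                return []
            return [c for c in ch if alive[c]]

        # find new root: descend while a single child survives
        root = 0
        while True:
            sc = surviving_children(root)
            if len(sc) == 1:
                root = sc[0]
            else:
                break
        out = io.StringIO()
        # stack entries: (node, edge_len_accum, state)
        stack: list[list] = [[root, 0.0, 0]]
        while stack:
            frame = stack[-1]
            i, extra, state = frame
            sc = surviving_children(i)
            while len(sc) == 1:  # pass-through: merge branch lengths
                extra += self.brlen[sc[0]]
                i = sc[0]
                sc = surviving_children(i)
                frame[0], frame[1] = i, extra
            if not sc:
                lab = self.labels[i] or ""
                out.write(_quote(lab))
                if len(stack) > 1:
                    out.write(f":{self.brlen[i] + extra:.12g}")
                stack.pop()
                _close(out, stack)
                continue
            if state == 0:
                out.write("(")
                frame[2] = 1
                stack.append([sc[0], 0.0, 0])
            elif state == 1:
                out.write(",")
                frame[2] = 2
                stack.append([sc[1], 0.0, 0])
            else:
                out.write(")")
                if len(stack) > 1:
                    out.write(f":{self.brlen[i] + extra:.12g}")
                stack.pop()
                _close(out, stack)
        out.write(";")
        return out.getvalue()

    def to_newick(self) -> str:
        return self._write_pruned(np.ones(len(self.parent), dtype=bool))

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Chronogram n_tips={self.n_tips} crown_age={self.crown_age:.4g} Ma>"


def _quote(label: str) -> str:
    if any(c in label for c in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _close(out: io.StringIO, stack: list) -> None:
    # no-op hook kept for symmetry; closing punctuation is emitted by parents
    return None


# -- module-level functional surface ----------------------------------


def parse_chronogram(text: str) -> Chronogram:
    """Parse and validate a Newick chronogram string."""
    return Chronogram.from_newick(text)


def write_chronogram(tree: Chronogram) -> str:
    """Serialize a chronogram to Newick (decimal Ma branch lengths)."""
    return tree.to_newick()


def branching_times(tree: Chronogram) -> BranchingTimes:
    """All internal-node ages, descending (crown age first)."""
    return tree.branching_times()


def split_records(tree: Chronogram) -> list[SplitRecord]:
    """One (left, right) tip-count record per internal node."""
    return tree.split_records()
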