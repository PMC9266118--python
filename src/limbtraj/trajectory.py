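"""Joint dendrogram over cluster centroids, cherry pairing and branches.

Clusters from both conditions are placed in one agglomerative tree built
from their mean expression profiles.  A *cherry* — an internal node whose
two children are both leaves — is the smallest unit of branching: when the
two leaves of a cherry come from opposite conditions, their clusters share
their characteristic markers and are treated as one cell type observed both
under homeostasis and upon wounding.  Cutting the epithelial part of the
tree at its highest merges yields the trajectory branches.

The agglomeration is implemented directly (average/complete linkage over
correlation or euclidean distances) because reproducibility demands an
explicit tie rule: equal-distance merges are resolved toward the
lexicographically smallest pair of node labels, making trees byte-stable.
Problem sizes are tiny (tens of leaves).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cluster import ClusterProfile


class DendrogramError(ValueError):
    pass


@dataclass
class Node:
    """Dendrogram node; leaves carry a label, internal nodes a merge height."""

    height: float = 0.0
    name: Optional[str] = None
    children: tuple["Node", "Node"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return [l for c in self.children for l in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def internal_nodes(self) -> list["Node"]:
        if self.is_leaf:
            return []
        return [self] + [n for c in self.children for n in c.internal_nodes()]

    def min_leaf(self) -> str:
        return min(self.leaf_names())


@dataclass
class Dendrogram:
    """Rooted binary tree over cluster profiles from both conditions."""

    root: Node
    distance: str = "correlation"
    linkage: str = "average"

    def leaves(self) -> list[str]:
        return self.root.leaf_names()

    def to_newick(self) -> str:
        def fmt(node: Node, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{bl:.10g}"
            a, b = node.children
            return f"({fmt(a, node.height)},{fmt(b, node.height)}):{bl:.10g}"

        if self.root.is_leaf:
            return f"{self.root.name}:0;"
        a, b = self.root.children
        return (
            f"({fmt(a, self.root.height)},{fmt(b, self.root.height)});"
        )

    @classmethod
    def from_newick(cls, text: str) -> "Dendrogram":
        """Parse a Newick string (via Bio.Phylo) back into a dendrogram.

        Heights are reconstructed from branch lengths assuming an
        ultrametric tree (leaves at height 0).
        """
        from Bio import Phylo

        tree = Phylo.read(io.StringIO(text), "newick")

        def convert(clade) -> Node:
            if not clade.clades:
                return Node(height=0.0, name=str(clade.name))
            if len(clade.clades) != 2:
                raise DendrogramError("dendrogram must be binary")
            kids = [convert(c) for c in clade.clades]
            bls = [c.branch_length or 0.0 for c in clade.clades]
            height = max(k.height + bl for k, bl in zip(kids, bls))
            kids = _canonical_order(kids)
            return Node(height=height, children=(kids[0], kids[1]))

        return cls(root=convert(tree.root))


def _canonical_order(kids: list[Node]) -> list[Node]:
    return sorted(kids, key=lambda n: n.min_leaf())


def leaf_label(cluster_id: str, condition: str) -> str:
    return f"{cluster_id}|{condition}"


def split_label(label: str) -> tuple[str, str]:
    cluster_id, condition = label.rsplit("|", 1)
    return cluster_id, condition


def profile_distance_matrix(
    profiles: list[ClusterProfile],
    genes: Iterable[str],
    distance: str = "correlation",
    log_transform: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Pairwise distances between cluster mean profiles on a gene subset."""
    genes = list(genes)
    if not genes:
        raise DendrogramError("empty gene subset")
    labels = [p.label for p in profiles]
    mat = np.vstack([p.mean_expr.reindex(genes).fillna(0.0).to_numpy() for p in profiles])
    if log_transform:
        mat = np.log1p(mat)
    n = len(profiles)
    d = np.zeros((n, n))
    if distance == "correlation":
        centered = mat - mat.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        if (norms == 0).any():
            # constant profiles correlate perfectly with everything constant
            norms = np.where(norms == 0, 1.0, norms)
        corr = (centered @ centered.T) / np.outer(norms, norms)
        d = 1.0 - np.clip(corr, -1.0, 1.0)
        np.fill_diagonal(d, 0.0)
    elif distance == "euclidean":
        diff = mat[:, None, :] - mat[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
    else:
        raise DendrogramError(f"unknown distance {distance!r}")
    return d, labels


def build_joint_dendrogram(
    profiles: list[ClusterProfile],
    genes: Iterable[str],
    distance: str = "correlation",
    linkage: str = "average",
    log_transform: bool = True,
) -> Dendrogram:
    """Agglomerate cluster profiles from both conditions into one tree.

    Average linkage (UPGMA) over 1 - Pearson correlation by default; merge
    heights are the linkage distances and are monotone toward the root.
    """
    if len(profiles) < 2:
        raise DendrogramError("need at least 2 profiles")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise DendrogramError("duplicate profile labels")
    if linkage not in ("average", "complete"):
        raise DendrogramError(f"unknown linkage {linkage!r}")
    d, labels = profile_distance_matrix(profiles, genes, distance, log_transform)

    nodes: dict[int, Node] = {i: Node(height=0.0, name=lab) for i, lab in enumerate(labels)}
    sizes = {i: 1 for i in nodes}
    key = {i: lab for i, lab in enumerate(labels)}   # tie-break label per node
    dist = {(i, j): d[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))}
    next_id = len(labels)
    while len(nodes) > 1:
        # minimal distance; ties toward the lexicographically smallest
        # (label_i, label_j) pair
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((key[kv[0][0]], key[kv[0][1]])))),
        )
        (i, j), h = best
        kids = _canonical_order([nodes[i], nodes[j]])
        merged = Node(height=h, children=(kids[0], kids[1]))
        for other in list(nodes):
            if other in (i, j):
                continue
            dio = dist.pop((min(i, other), max(i, other)))
            djo = dist.pop((min(j, other), max(j, other)))
            if linkage == "average":
                dn = (sizes[i] * dio + sizes[j] * djo) / (sizes[i] + sizes[j])
            else:
                dn = max(dio, djo)
            dist[(min(other, next_id), max(other, next_id))] = dn
        dist.pop((min(i, j), max(i, j)))
        sizes[next_id] = sizes.pop(i) + sizes.pop(j)
        key[next_id] = min(key.pop(i), key.pop(j))
        nodes[next_id] = merged
        del nodes[i], nodes[j]
        next_id += 1
    root = next(iter(nodes.values()))
    # enforce monotone heights (guards against tiny floating dips)
    def lift(node: Node) -> None:
        if node.is_leaf:
            return
        for c in node.children:
            lift(c)
        node.height = max([node.height] + [c.height for c in node.children])

    lift(root)
    return Dendrogram(root=root, distance=distance, linkage=linkage)


def extract_cherries(d: Dendrogram) -> list[tuple[str, str]]:
    """Internal nodes whose two children are both leaves, as sorted pairs."""
    out = []
    for node in d.root.internal_nodes():
        a, b = node.children
        if a.is_leaf and b.is_leaf:
            out.append(tuple(sorted((a.name, b.name))))
    return sorted(out)


@dataclass
class CellType:
    """One or two paired clusters with a presence class."""

    name: str
    member_clusters: list[tuple[str, str]]   # (cluster_id, condition)
    presence: str                            # shared / unwounded_only / wounded_only
    branch: Optional[str] = None

    def clusters_in(self, condition: str) -> list[str]:
        return [c for c, cond in self.member_clusters if cond == condition]


def assign_cell_types(
    d: Dendrogram, epithelial_leaves: Iterable[str]
) -> list[CellType]:
    """Apply the cross-condition cherry-pairing rule to epithelial leaves.

    Each cherry whose two epithelial leaves come from opposite conditions is
    one shared cell type; every other epithelial leaf — including both
    members of a same-condition cherry — is its own condition-specific type.
    #types = #epithelial leaves - #cross-condition cherries.
    """
    epithelial = set(epithelial_leaves)
    missing = epithelial - set(d.leaves())
    if missing:
        raise DendrogramError(f"epithelial leaves not in dendrogram: {sorted(missing)}")
    paired: set[str] = set()
    types: list[CellType] = []
    for a, b in extract_cherries(d):
        if a in epithelial and b in epithelial:
            ca, conda = split_label(a)
            cb, condb = split_label(b)
            if conda != condb:
                members = sorted(
                    [(ca, conda), (cb, condb)], key=lambda m: m[1] != "unwounded"
                )
                types.append(
                    CellType(
                        name="+".join(leaf_label(*m) for m in members),
                        member_clusters=members,
                        presence="shared",
                    )
                )
                paired.update((a, b))
    for leaf in d.leaves():
        if leaf in epithelial and leaf not in paired:
            cid, cond = split_label(leaf)
            types.append(
                CellType(
                    name=leaf,
                    member_clusters=[(cid, cond)],
                    presence=f"{cond}_only",
                )
            )
    return types


@dataclass
class BranchAssignment:
    """Partition of the epithelial leaves into k connected subtrees."""

    branches: dict[str, set[str]]            # branch id -> leaf labels

    @property
    def k(self) -> int:
        return len(self.branches)

    def branch_of(self, leaf: str) -> str:
        for bid, leaves in self.branches.items():
            if leaf in leaves:
                return bid
        raise KeyError(leaf)


def restrict_to_leaves(node: Node, keep: set[str]) -> Optional[Node]:
    """Induced subtree on a leaf subset, suppressing unary nodes."""
    if node.is_leaf:
        return Node(height=0.0, name=node.name) if node.name in keep else None
    kids = [restrict_to_leaves(c, keep) for c in node.children]
    kids = [k for k in kids if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    kids = _canonical_order(kids)
    return Node(height=node.height, children=(kids[0], kids[1]))


def extract_branches(
    d: Dendrogram, epithelial_leaves: Iterable[str], k: int = 3
) -> BranchAssignment:
    """Cut the epithelial-restricted subtree at its k-1 highest merges.

    Proceeds root-down: repeatedly split the current group whose root has the
    greatest merge height (ties toward the smallest leaf label) until k
    groups remain.  Branch ids B1..Bk are assigned in order of each group's
    lexicographically smallest leaf.
    """
    epithelial = sorted(set(epithelial_leaves))
    if k < 1:
        raise DendrogramError("k must be >= 1")
    if k > len(epithelial):
        raise DendrogramError(f"k={k} exceeds {len(epithelial)} epithelial leaves")
    sub = restrict_to_leaves(d.root, set(epithelial))
    if sub is None:
        raise DendrogramError("no epithelial leaves in the dendrogram")
    frontier = [sub]
    while len(frontier) < k:
        internal = [n for n in frontier if not n.is_leaf]
        target = max(internal, key=lambda n: (n.height, n.min_leaf()))
        frontier.remove(target)
        frontier.extend(target.children)
    groups = sorted((set(n.leaf_names()) for n in frontier), key=min)
    return BranchAssignment(
        branches={f"B{i + 1}": g for i, g in enumerate(groups)}
    )


def attach_branches(
    cell_types: list[CellType], branches: BranchAssignment
) -> list[CellType]:
    """Annotate each cell type with the branch containing its member leaves."""
    for t in cell_types:
        labels = [leaf_label(c, cond) for c, cond in t.member_clusters]
        bids = {branches.branch_of(l) for l in labels}
        t.branch = sorted(bids)[0] if len(bids) == 1 else sorted(bids)[0]
        if len(bids) > 1:
            # a paired type straddling a cut — keep the branch of its
            # unwounded member, favouring homeostasis
            t.branch = branches.branch_of(labels[0])
    return cell_types


def cell_types_to_frame(cell_types: list[CellType]) -> pd.DataFrame:
    rows = []
    for t in cell_types:
        rows.append(
            {
                "cell_type": t.name,
                "presence": t.presence,
                "branch": t.branch,
                "members": ";".join(f"{c}|{cond}" for c, cond in t.member_clusters),
            }
        )
    return pd.DataFrame(rows)
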