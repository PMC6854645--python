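"""Gene-duplication timing from rooted gene-tree topology.

Two topological models distinguish when a pair (or more) of guayule
(*Parthenium*) paralogs arose, given sampled homologs from sunflower
(*Helianthus*), lettuce (*Lactuca*) and the Arabidopsis outgroup:

* **Asteraceae event** — each guayule paralog is immediately sister to a
  sunflower gene: the duplication predates the guayule/sunflower split
  (the shared whole-genome triplication at the base of the family).
* **Lineage (AZ-3) event** — the guayule paralogs are sister to one
  another first, then to a sunflower gene: the duplication happened in
  the guayule accession's own lineage (its recent polyploidy).

Classification operates per query tip with a cluster-level roll-up, and
is gated by bootstrap support at the decisive guayule-sunflower node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .io_formats import GeneTree, TreeNode

__all__ = [
    "EventClass",
    "ClusterClass",
    "DuplicationCall",
    "root_on_outgroup",
    "classify_duplication",
    "truth_table",
    "enumerate_rooted_topologies",
]

DEFAULT_OUTGROUP = "Arabidopsis"
DEFAULT_SISTER = "Helianthus"
DEFAULT_SUPPORT_MIN = 70.0


class EventClass(str, Enum):
    ASTERACEAE = "ASTERACEAE"
    LINEAGE = "LINEAGE"
    UNRESOLVED = "UNRESOLVED"


class ClusterClass(str, Enum):
    ASTERACEAE = "ASTERACEAE"
    LINEAGE = "LINEAGE"
    BOTH = "BOTH"
    UNRESOLVED = "UNRESOLVED"


@dataclass
class DuplicationCall:
    cluster_id: str
    assignments: dict[str, EventClass]
    cluster_class: ClusterClass
    node_supports: dict[str, float | None]
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Rooting


def _clone(node: TreeNode) -> TreeNode:
    return TreeNode(
        children=[_clone(c) for c in node.children],
        tip_id=node.tip_id,
        species=node.species,
        support=node.support,
        length=node.length,
    )


def _collect_bipartition_supports(root: TreeNode) -> dict[frozenset[str], float]:
    """Supports keyed by the tip-set bipartition they subtend (either side)."""
    all_tips = root.tip_ids()
    table: dict[frozenset[str], float] = {}
    for node in root.walk():
        if not node.is_tip and node.support is not None:
            side = node.tip_ids()
            table[side] = node.support
            table[all_tips - side] = node.support
    return table


def _restore_supports(root: TreeNode, table: Mapping[frozenset[str], float]) -> None:
    for node in root.walk():
        if not node.is_tip:
            node.support = table.get(node.tip_ids())


def _parent_map(root: TreeNode) -> dict[int, TreeNode]:
    parents: dict[int, TreeNode] = {}
    for node in root.walk():
        for c in node.children:
            parents[id(c)] = node
    return parents


def _reroot_at_edge(root: TreeNode, child: TreeNode) -> TreeNode:
    """Re-root on the edge above ``child``: new root has ``child`` and
    the remainder of the tree as its two children."""
    parents = _parent_map(root)
    path: list[TreeNode] = [child]
    node = child
    while id(node) in parents:
        node = parents[id(node)]
        path.append(node)
    # path: child .. old root; rebuild by hanging each ancestor off the next
    new_sibling = None
    for i in range(len(path) - 1, 0, -1):
        ancestor = path[i]
        towards = path[i - 1]
        rest = [c for c in ancestor.children if c is not towards]
        if new_sibling is not None:
            rest.append(new_sibling)
        if len(rest) == 1:
            new_sibling = rest[0]  # suppress the degree-two node
        else:
            new_sibling = TreeNode(children=rest)
    new_root = TreeNode(children=[child, new_sibling])
    return new_root


def _mrca(root: TreeNode, tip_ids: frozenset[str]) -> TreeNode:
    best = root
    changed = True
    while changed:
        changed = False
        for c in best.children:
            if tip_ids <= c.tip_ids():
                best = c
                changed = True
                break
    return best


def root_on_outgroup(tree: GeneTree, outgroup_species: str = DEFAULT_OUTGROUP) -> GeneTree:
    """Root on the branch subtending the outgroup tip(s).

    With several outgroup tips the root goes on their MRCA branch when
    they are monophyletic (in the unrooted sense); otherwise a warning is
    emitted and the first-listed outgroup tip anchors the root. Supports
    are carried across the re-rooting by bipartition, not by node.
    """
    out_tips = [t for t in tree.tips() if t.species == outgroup_species]
    if not out_tips:
        raise ValueError(f"no tip of outgroup species {outgroup_species!r}")
    root = _clone(tree.root)
    supports = _collect_bipartition_supports(root)
    all_tips = root.tip_ids()
    target_ids = frozenset(t.tip_id for t in out_tips)

    if len(out_tips) == 1:
        target = next(t for t in root.tips() if t.tip_id in target_ids)
    else:
        mrca = _mrca(root, target_ids)
        if mrca.tip_ids() == target_ids:
            target = mrca
        else:
            # unrooted monophyly: the complement side may be the clade
            comp = all_tips - target_ids
            comp_mrca = _mrca(root, comp)
            if comp_mrca.tip_ids() == comp and comp_mrca is not root:
                target = comp_mrca  # rooting on the complement edge is the same edge
            else:
                warnings.warn(
                    f"outgroup tips {sorted(target_ids)} not monophyletic; rooting on first tip",
                    stacklevel=2,
                )
                first = sorted(target_ids)[0]
                target = next(t for t in root.tips() if t.tip_id == first)

    if target is root:
        raise ValueError("cannot root on the whole tree")
    parents = _parent_map(root)
    parent = parents.get(id(target))
    if parent is root and len(root.children) == 2:
        new_root = root  # already rooted on this edge
    else:
        new_root = _reroot_at_edge(root, target)
    _restore_supports(new_root, supports)
    return GeneTree(root=new_root, unrooted_source=False)


# ---------------------------------------------------------------------------
# Classification


def classify_duplication(
    tree: GeneTree,
    query_tips: Sequence[str],
    support_min: float = DEFAULT_SUPPORT_MIN,
    sister_species: str = DEFAULT_SISTER,
    cluster_id: str = "cluster",
) -> DuplicationCall:
    """Classify the duplication timing of a paralog cluster.

    Algorithm, on the rooted tree:

    1. find the maximal clades consisting only of query tips; each such
       clade of size >= 2 is a candidate lineage-specific duplication
       group;
    2. inspect each group's (or singleton query tip's) sister clade: a
       sister containing at least one *sister-species* tip and no query
       tip licenses ASTERACEAE for singletons and LINEAGE for groups;
       any other sister composition leaves the tips UNRESOLVED with a
       note;
    3. the decisive node is the group's parent (the guayule-sunflower
       node); a present support below ``support_min`` there demotes the
       assignment to UNRESOLVED (absent support passes);
    4. roll up: all resolved tips of one kind give that kind; a mixture
       gives BOTH; no resolved tip gives UNRESOLVED.
    """
    query = set(query_tips)
    tip_ids = tree.tip_ids
    missing = query - set(tip_ids)
    if missing:
        raise ValueError(f"query tips absent from tree: {sorted(missing)}")
    if len(query) < 2:
        raise ValueError("need >= 2 query tips")

    root = tree.root
    parents = _parent_map(root)

    # maximal query-only clades (clades may be single tips)
    groups: list[TreeNode] = []

    def visit(node: TreeNode) -> None:
        if node.tip_ids() <= query:
            groups.append(node)
            return
        for c in node.children:
            visit(c)

    visit(root)

    assignments: dict[str, EventClass] = {}
    node_supports: dict[str, float | None] = {}
    notes: list[str] = []

    for g in groups:
        g_tips = sorted(g.tip_ids())
        label = "+".join(g_tips)
        parent = parents.get(id(g))
        if parent is None:
            assignments.update({t: EventClass.UNRESOLVED for t in g_tips})
            notes.append(f"{label}: query group spans the whole tree")
            continue
        if len(parent.children) != 2:
            assignments.update({t: EventClass.UNRESOLVED for t in g_tips})
            notes.append(f"{label}: decisive node is a polytomy")
            node_supports[label] = parent.support
            continue
        sister = next(c for c in parent.children if c is not g)
        sister_tipset = sister.tip_ids()
        sister_species_set = {tree.species_of(t) for t in sister_tipset}
        node_supports[label] = parent.support

        if sister_tipset & query:
            # cannot happen for maximal query-only clades unless mixed clade
            assignments.update({t: EventClass.UNRESOLVED for t in g_tips})
            notes.append(f"{label}: sister clade mixes query and non-query tips")
            continue
        if sister_species not in sister_species_set:
            assignments.update({t: EventClass.UNRESOLVED for t in g_tips})
            notes.append(
                f"{label}: sister clade lacks {sister_species} "
                f"(contains {sorted(sister_species_set)})"
            )
            continue
        if parent.support is not None and parent.support < support_min:
            assignments.update({t: EventClass.UNRESOLVED for t in g_tips})
            notes.append(f"{label}: support {parent.support:g} below {support_min:g}")
            continue
        kind = EventClass.LINEAGE if len(g_tips) >= 2 else EventClass.ASTERACEAE
        assignments.update({t: kind for t in g_tips})

    resolved = {k for k in assignments.values() if k is not EventClass.UNRESOLVED}
    if not resolved:
        cluster_class = ClusterClass.UNRESOLVED
    elif resolved == {EventClass.ASTERACEAE}:
        cluster_class = ClusterClass.ASTERACEAE
    elif resolved == {EventClass.LINEAGE}:
        cluster_class = ClusterClass.LINEAGE
    else:
        cluster_class = ClusterClass.BOTH
    unresolved_tips = sorted(t for t, k in assignments.items() if k is EventClass.UNRESOLVED)
    if unresolved_tips and resolved:
        notes.append(f"unresolved tips ignored in roll-up: {unresolved_tips}")
    return DuplicationCall(
        cluster_id=cluster_id,
        assignments=assignments,
        cluster_class=cluster_class,
        node_supports=node_supports,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Exhaustive verification harness


def enumerate_rooted_topologies(tip_labels: Sequence[str]) -> list[TreeNode]:
    """All rooted binary topologies on a labelled tip set ((2n-3)!! trees).

    Built by sequential tip insertion onto every edge (including the
    root edge), which enumerates each topology exactly once.
    """
    labels = list(tip_labels)
    if len(labels) > 7:
        raise ValueError("tip count too large for exhaustive enumeration")
    trees: list[TreeNode] = [TreeNode(tip_id=labels[0])]
    for label in labels[1:]:
        new_trees: list[TreeNode] = []
        for t in trees:
            n_edges = sum(1 for _ in t.walk())  # every node subtends an edge incl. root edge
            for e in range(n_edges):
                clone = _clone(t)
                nodes = list(clone.walk())
                target = nodes[e]
                new_tip = TreeNode(tip_id=label)
                if target is clone:
                    clone = TreeNode(children=[clone, new_tip])
                else:
                    parent = _parent_map(clone)[id(target)]
                    idx = parent.children.index(target)
                    parent.children[idx] = TreeNode(children=[target, new_tip])
                new_trees.append(clone)
        trees = new_trees
    return trees


def truth_table(
    n_query: int = 2,
    n_sister: int = 2,
    species_map: Mapping[str, str] | None = None,
) -> dict[str, ClusterClass]:
    """Classify every rooted binary topology on the small labelled tip set.

    Tips are ``g1..gN`` (query, Parthenium), ``h1..hM`` (Helianthus) and
    ``at`` (Arabidopsis). Each enumerated topology is outgroup-rooted and
    classified; the result maps a canonical newick string to the cluster
    class. Intended for comparison against a hand-derived oracle.
    """
    if n_query + n_sister + 1 > 7:
        raise ValueError("tip count too large")
    labels = [f"g{i+1}" for i in range(n_query)] + [f"h{i+1}" for i in range(n_sister)] + ["at"]
    if species_map is None:
        species_map = {"g": "Parthenium", "h": "Helianthus", "at": "Arabidopsis"}

    def assign_species(node: TreeNode) -> None:
        for t in node.tips():
            if t.tip_id in species_map:
                t.species = species_map[t.tip_id]
            else:
                key = max((k for k in species_map if t.tip_id.startswith(k)), key=len)
                t.species = species_map[key]

    out: dict[str, ClusterClass] = {}
    query = [l for l in labels if l.startswith("g")]
    for top in enumerate_rooted_topologies(labels):
        assign_species(top)
        tree = GeneTree(root=top)
        rooted = root_on_outgroup(tree)
        call = classify_duplication(rooted, query)
        out[canonical_newick(top)] = call.cluster_class
    return out


def canonical_newick(node: TreeNode) -> str:
    """Rotation-invariant newick string (children sorted by tip content)."""
    if node.is_tip:
        return node.tip_id
    parts = sorted(canonical_newick(c) for c in node.children)
    return "(" + ",".join(parts) + ")"
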