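"""Minimal rooted-tree container for neighbor-joining output.

Trees are stored rooted for traversal convenience; an unrooted NJ tree is
represented with a trifurcating root. Bootstrap supports (0-100) live on
internal nodes and refer to the bipartition induced by the edge above the
node.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Node:
    name: str | None = None
    length: float | None = None  # branch length of the edge above this node
    support: float | None = None  # bootstrap %, internal nodes only
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def iter_nodes(self):
        yield self
        for c in self.children:
            yield from c.iter_nodes()

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial splits, each as the leaf set under an internal edge."""
        all_leaves = frozenset(self.leaf_names())
        splits: set[frozenset[str]] = set()
        for node in self.iter_nodes():
            if node is self or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if 1 < len(side) < len(all_leaves) - 1:
                # canonical orientation: the side not containing the
                # lexicographically smallest taxon
                anchor = min(all_leaves)
                splits.add(side if anchor not in side else all_leaves - side)
        return splits


def find_node(root: Node, leaf_name: str) -> Node | None:
    for node in root.iter_nodes():
        if node.is_leaf and node.name == leaf_name:
            return node
    return None


def _leaf_depths(node: Node, depth: float = 0.0):
    if node.is_leaf:
        yield node.name, depth
    for c in node.children:
        yield from _leaf_depths(c, depth + (c.length or 0.0))


def midpoint_root(root: Node) -> Node:
    """Re-root a copy of the tree at the midpoint of its longest
    leaf-to-leaf path; the input tree is left untouched."""
    import copy

    root = copy.deepcopy(root)
    parents: dict[int, Node | None] = {id(root): None}
    for node in root.iter_nodes():
        for c in node.children:
            parents[id(c)] = node

    leaves = root.leaves()
    # distance from every leaf to every node via parent walks
    def path_to_root(n: Node):
        path = []
        while n is not None:
            path.append(n)
            n = parents[id(n)]
        return path

    best = (-1.0, None, None)
    paths = {id(l): path_to_root(l) for l in leaves}
    for i, a in enumerate(leaves):
        pa = paths[id(a)]
        seta = {id(n): k for k, n in enumerate(pa)}
        for b in leaves[i + 1:]:
            pb = paths[id(b)]
            # lowest common ancestor
            for n in pb:
                if id(n) in seta:
                    lca = n
                    break
            d = 0.0
            for n in pa[:seta[id(lca)]]:
                d += n.length or 0.0
            for n in pb:
                if n is lca:
                    break
                d += n.length or 0.0
            if d > best[0]:
                best = (d, a, b)
    diameter, a, b = best
    if a is None or diameter <= 0:
        return root
    # walk from a toward b until half the diameter is consumed
    pa = paths[id(a)]
    seta = {id(n): k for k, n in enumerate(pa)}
    pb = paths[id(b)]
    for n in pb:
        if id(n) in seta:
            lca = n
            break
    route = pa[:seta[id(lca)] + 1] + list(reversed(pb[:next(
        k for k, n in enumerate(pb) if n is lca)]))
    half = diameter / 2.0
    consumed = 0.0
    for k in range(len(route) - 1):
        below, above = route[k], route[k + 1]
        # edge between below/above: length is on whichever is the child
        child = below if parents[id(below)] is above else above
        elen = child.length or 0.0
        if consumed + elen >= half or k == len(route) - 2:
            # distance from the near (route[k]) end of the edge
            near = 0.0 if elen == 0 else (half - consumed) / elen
            # frac is measured from the child's end of the edge
            frac = near if child is below else 1.0 - near
            frac = min(max(frac, 0.0), 1.0)
            return _reroot_on_edge(root, parents, child, frac)
        consumed += elen
    return root


def _reroot_on_edge(root: Node, parents, child: Node, frac: float) -> Node:
    """Root on the edge above `child`, `frac` of the way from child's end."""
    parent = parents[id(child)]
    elen = child.length or 0.0
    new_root = Node()
    # detach child from parent
    parent.children = [c for c in parent.children if c is not child]
    child_part = Node(name=child.name, length=elen * frac,
                      support=child.support, children=child.children)
    # invert path parent -> old root
    path = [parent]
    n = parent
    while parents[id(n)] is not None:
        n = parents[id(n)]
        path.append(n)
    # flip edges along path
    for k in range(len(path) - 1):
        lower, upper = path[k], path[k + 1]
        upper.children = [c for c in upper.children if c is not lower]
        lower.children.append(upper)
        upper.length, lower.support = lower.length, lower.support
    parent_part_len = elen * (1 - frac)
    parent.length = parent_part_len
    # collapse a now-degenerate old root with a single child
    new_root.children = [child_part, parent]
    _suppress_unary(new_root)
    return new_root


def _suppress_unary(node: Node) -> None:
    for c in list(node.children):
        _suppress_unary(c)
    new_children = []
    for c in node.children:
        if not c.is_leaf and len(c.children) == 1:
            g = c.children[0]
            g.length = (g.length or 0.0) + (c.length or 0.0)
            new_children.append(g)
        else:
            new_children.append(c)
    node.children = new_children
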