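"""Subfamily (A-E) assignment from the phylogeny and roster assembly.

A query is labeled with the majority group of the references in the
smallest midpoint-rooted clade that contains it together with at least one
reference. The T-loop type is a consistency check only: a TDY loop implies
group D unless the clade places the gene in group E (the AcMAPK18-like
case); on conflict the clade label wins and a warning is recorded.
"""

from __future__ import annotations

import warnings

from .gene_annotation import protein_properties
from .io_formats import FamilyTableRow, GeneModel
from .phylotree import Node, find_node, midpoint_root


def assign_subfamily(query_leaf: str, tree: Node, tloop: str,
                     panel: dict[str, str], rooted: bool = False) -> str:
    """Group in {A..E} for one query leaf; `panel` maps ref leaf -> group."""
    if not panel:
        raise ValueError("empty reference panel")
    rooted_tree = tree if rooted else midpoint_root(tree)
    node = find_node(rooted_tree, query_leaf)
    if node is None:
        raise ValueError(f"query {query_leaf} absent from tree")
    parents = {id(rooted_tree): None}
    for n in rooted_tree.iter_nodes():
        for c in n.children:
            parents[id(c)] = n
    group = None
    while node is not None:
        labels = [panel[l] for l in node.leaf_names() if l in panel]
        if labels:
            counts = {g: labels.count(g) for g in set(labels)}
            group = min(sorted(counts), key=lambda g: -counts[g])
            break
        node = parents[id(node)]
    if group is None:
        raise ValueError("tree contains no reference leaves")
    if tloop == "TDY" and group not in ("D", "E"):
        warnings.warn(f"{query_leaf}: TDY loop but clade says group {group}; "
                      "keeping the clade label")
    if tloop == "TDY" and group == "E":
        warnings.warn(f"{query_leaf}: TDY loop inside the group E clade")
    return group


def assign_all(tree: Node, tloops: dict[str, str],
               panel: dict[str, str]) -> dict[str, str]:
    """Subfamily per query leaf (every non-reference leaf of the tree)."""
    rooted = midpoint_root(tree)
    return {leaf: assign_subfamily(leaf, rooted, tloops.get(leaf, "none"),
                                   panel, rooted=True)
            for leaf in tree.leaf_names() if leaf not in panel}


def build_family_table(accepted: list[str],
                       annotations: dict[str, GeneModel],
                       proteins: dict[str, str],
                       tloops: dict[str, str],
                       groups: dict[str, str],
                       names: dict[str, str] | None = None
                       ) -> list[FamilyTableRow]:
    """Assemble the family roster for the accepted genes, sorted by id."""
    rows = []
    for gid in sorted(accepted):
        if gid not in annotations:
            raise ValueError(f"missing annotation for accepted gene {gid}")
        gene = annotations[gid]
        protein = proteins[gid]
        props = protein_properties(protein)
        rows.append(FamilyTableRow(
            name=(names or {}).get(gid, gid), gene_id=gid,
            chromosome=gene.chromosome, aa_length=props.length,
            cds_length_bp=gene.cds_length,
            mw_kda=round(props.mw_da / 1000, 2), pi=round(props.pi, 2),
            exon_count=gene.exon_count, tloop=tloops[gid],
            group=groups.get(gid)))
    return rows
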