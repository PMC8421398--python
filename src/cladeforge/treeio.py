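"""Phylogeny I/O with dual node-support annotations.

Trees are :class:`dendropy.Tree` objects. Each node additionally carries

``node_id``
    a stable string identifier (``"L:<leaf name>"`` for leaves, ``"N<k>"``
    in preorder for internal nodes), assigned at read time and preserved by
    :func:`clone_tree`. All downstream per-node tables key on it.
``ufboot`` / ``shalrt``
    ultrafast-bootstrap and SH-aLRT support percentages (``None`` when
    absent). Internal Newick labels of the form ``"x/y"`` hold both values;
    which comes first is tool-version dependent, so the order is an explicit
    argument. The default matches IQ-Tree run with ``-bb 1000 -alrt 1000``,
    which writes SH-aLRT first.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable

import dendropy

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "read_newick",
    "write_newick",
    "clone_tree",
    "root_by_outgroup",
    "leaf_names",
    "total_length",
    "assign_node_ids",
]

SUPPORT_DIALECTS = ("slash_pair", "single", "none")


class NewickParseError(ValueError):
    """Raised when the input is not syntactically valid Newick."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def total_length(tree: dendropy.Tree) -> float:
    return sum(nd.edge.length or 0.0 for nd in tree.preorder_node_iter())


def assign_node_ids(tree: dendropy.Tree) -> None:
    """Assign stable ``node_id`` strings (preorder for internal nodes)."""
    k = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd.node_id = f"L:{nd.taxon.label}"
        else:
            nd.node_id = f"N{k}"
            k += 1


def _parse_support_label(label: str, dialect: str, ufboot_first: bool):
    """Return (ufboot, shalrt) parsed from an internal-node label."""
    if dialect == "none" or label is None or label == "":
        return None, None
    try:
        if dialect == "slash_pair":
            a_str, b_str = label.split("/")
            a, b = float(a_str), float(b_str)
            return (a, b) if ufboot_first else (b, a)
        if dialect == "single":
            return float(label), None
    except ValueError as exc:
        raise TreeValidationError(
            f"cannot parse internal node label {label!r} under dialect "
            f"{dialect!r}"
        ) from exc
    raise ValueError(f"unknown support dialect {dialect!r}; expected one of {SUPPORT_DIALECTS}")


def _validate(tree: dendropy.Tree) -> None:
    names = leaf_names(tree)
    if any(n is None or n == "" for n in names):
        raise TreeValidationError("empty leaf name")
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise TreeValidationError(f"duplicate leaf names: {sorted(dupes)}")
    for nd in tree.preorder_node_iter():
        if nd is not tree.seed_node:
            if nd.edge.length is None:
                warnings.warn("missing branch length set to 0", stacklevel=3)
                nd.edge.length = 0.0
            if nd.edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length {nd.edge.length} above node "
                    f"{getattr(nd, 'node_id', '?')}"
                )
        for v in (getattr(nd, "ufboot", None), getattr(nd, "shalrt", None)):
            if v is not None and not (0.0 <= v <= 100.0):
                raise TreeValidationError(f"support value {v} outside [0, 100]")


def read_newick(
    text: str,
    support_dialect: str = "slash_pair",
    ufboot_first: bool = False,
) -> dendropy.Tree:
    """Parse a Newick string into an annotated, validated tree.

    Parameters
    ----------
    text
        Newick string; internal node labels may carry supports.
    support_dialect
        ``"slash_pair"`` (labels like ``"95/80"`` holding both supports),
        ``"single"`` (one value, stored as UFBOOT), or ``"none"``.
    ufboot_first
        Order of the slash pair. Default ``False``: the label reads
        SH-aLRT/UFBOOT, as IQ-Tree writes for ``-bb 1000 -alrt 1000``.
    """
    if support_dialect not in SUPPORT_DIALECTS:
        raise ValueError(
            f"unknown support dialect {support_dialect!r}; expected one of {SUPPORT_DIALECTS}"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd.ufboot, nd.shalrt = None, None
        else:
            nd.ufboot, nd.shalrt = _parse_support_label(
                nd.label, support_dialect, ufboot_first
            )
    assign_node_ids(tree)
    _validate(tree)
    return tree


def _format_length(x: float) -> str:
    return format(float(x), ".9g")


def write_newick(
    tree: dendropy.Tree,
    support_dialect: str = "slash_pair",
    ufboot_first: bool = False,
) -> str:
    """Serialize to Newick with 9 significant digits of branch length.

    Internal support pairs are re-encoded as labels in the same dialect
    conventions accepted by :func:`read_newick`.
    """

    def fmt(nd: dendropy.Node) -> str:
        if nd.is_leaf():
            body = nd.taxon.label
        else:
            body = "(" + ",".join(fmt(c) for c in nd.child_nodes()) + ")"
            u, s = getattr(nd, "ufboot", None), getattr(nd, "shalrt", None)
            if support_dialect == "slash_pair" and u is not None and s is not None:
                pair = (u, s) if ufboot_first else (s, u)
                body += f"{pair[0]:g}/{pair[1]:g}"
            elif support_dialect == "single" and u is not None:
                body += f"{u:g}"
        if nd.edge.length is not None and nd is not tree.seed_node:
            body += ":" + _format_length(nd.edge.length)
        elif nd is tree.seed_node and nd.edge.length:
            body += ":" + _format_length(nd.edge.length)
        return body

    return fmt(tree.seed_node) + ";"


def clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep structural copy preserving lengths, supports and node ids."""
    namespace = dendropy.TaxonNamespace()

    def copy_node(nd: dendropy.Node) -> dendropy.Node:
        new = dendropy.Node()
        if nd.is_leaf():
            new.taxon = namespace.require_taxon(label=nd.taxon.label)
        new.edge.length = nd.edge.length
        new.ufboot = getattr(nd, "ufboot", None)
        new.shalrt = getattr(nd, "shalrt", None)
        new.node_id = getattr(nd, "node_id", None)
        for c in nd.child_nodes():
            new.add_child(copy_node(c))
        return new

    out = dendropy.Tree(taxon_namespace=namespace)
    out.seed_node = copy_node(tree.seed_node)
    out.is_rooted = True
    return out


def _leafset_map(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    out: dict[dendropy.Node, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            out[nd] = frozenset([nd.taxon.label])
        else:
            out[nd] = frozenset().union(*(out[c] for c in nd.child_nodes()))
    return out


def root_by_outgroup(tree: dendropy.Tree, outgroup_leaves: Iterable[str]) -> dendropy.Tree:
    """Root on the branch separating the outgroup from the ingroup.

    The rooted branch is split in half; total tree length and all leaf
    pairwise path distances are conserved. The outgroup must be non-empty,
    a proper subset of the leaves, and monophyletic in the unrooted
    topology.
    """
    og = frozenset(outgroup_leaves)
    all_leaves = frozenset(leaf_names(tree))
    if not og:
        raise ValueError("outgroup is empty")
    if not og <= all_leaves:
        raise ValueError(f"outgroup leaves not in tree: {sorted(og - all_leaves)}")
    if og == all_leaves:
        raise ValueError("outgroup equals the full leaf set; nothing to root against")

    work = clone_tree(tree)
    leafsets = _leafset_map(work)
    target = None
    for nd in work.preorder_node_iter():
        if nd is work.seed_node:
            continue
        ls = leafsets[nd]
        if ls == og or ls == all_leaves - og:
            target = nd
            break
    if target is None:
        # name the leaves breaking monophyly: extras under the tightest clade
        best = min(
            (ls for ls in leafsets.values() if og <= ls),
            key=len,
            default=all_leaves,
        )
        raise ValueError(
            "outgroup is not monophyletic in the unrooted topology; "
            f"smallest containing clade also holds {sorted(best - og)}"
        )

    half = (target.edge.length or 0.0) / 2.0
    work.reroot_at_edge(target.edge, length1=half, length2=half)
    work.suppress_unifurcations()
    work.is_rooted = True
    # make the outgroup side the first child, for deterministic layout
    leafsets = _leafset_map(work)
    kids = work.seed_node.child_nodes()
    if len(kids) == 2 and leafsets[kids[1]] == og:
        work.seed_node.set_child_nodes([kids[1], kids[0]])
    assign_node_ids(work)
    _validate(work)
    return work
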