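"""Subgroup delineation on RED-annotated trees.

A subgroup is a maximal internal clade whose monophyly is well supported
(UFBOOT >= 95 and SH-aLRT >= 80 by default) and whose RED value and stem
length on the unit-depth ultrametric tree both strictly exceed 0.4 (a
per-clade RED override accommodates deep, long-isolated lineages, e.g. a
0.3 floor). Selection is maximal: a qualifying node is chosen only when no
ancestor already qualified, so subgroups are disjoint by construction.
Leaves outside every selected clade are labeled UNGROUPED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import pandas as pd

from .redcore import RedAnnotatedTree

__all__ = [
    "UNGROUPED",
    "DelineationParams",
    "Subgroup",
    "SubgroupAssignment",
    "delineate_subgroups",
    "map_to_16s_clusters",
]

UNGROUPED = "UNGROUPED"
# guard for strict > comparisons: representation noise (e.g. 0.8 - 0.4)
# must not push a value exactly at the threshold over it
_EPS = 1e-12
_LABELS = [chr(c) for c in range(ord("A"), ord("Z") + 1)]


@dataclass
class DelineationParams:
    red_min: float = 0.4          # strict >
    stem_min: float = 0.4         # strict >, unit-depth ultrametric scale
    ufboot_min: float = 95.0      # >=
    shalrt_min: float = 80.0      # >=
    # anchor leaf set -> relaxed red_min; applies to any clade containing the anchor
    overrides: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.red_min <= 1.0 and 0.0 <= self.stem_min <= 1.0):
            raise ValueError("red_min and stem_min must lie in [0, 1]")
        if not (0.0 <= self.ufboot_min <= 100.0 and 0.0 <= self.shalrt_min <= 100.0):
            raise ValueError("support thresholds must lie in [0, 100]")
        self.overrides = {frozenset(k): float(v) for k, v in self.overrides.items()}

    def red_min_for(self, leafset: frozenset) -> float:
        vals = [v for k, v in self.overrides.items() if k <= leafset]
        return min(vals) if vals else self.red_min


@dataclass
class Subgroup:
    label: str
    node_id: str
    leaves: frozenset
    red: float
    stem_length: float
    ufboot: float
    shalrt: float

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


@dataclass
class SubgroupAssignment:
    leaf_to_label: dict[str, str]
    subgroups: list[Subgroup]

    def partition(self) -> set[frozenset]:
        return {sg.leaves for sg in self.subgroups}

    def ungrouped(self) -> set[str]:
        return {lf for lf, lab in self.leaf_to_label.items() if lab == UNGROUPED}

    def genomes_in(self, label: str) -> list[str]:
        return sorted(lf for lf, lab in self.leaf_to_label.items() if lab == label)

    def labels(self) -> list[str]:
        return [sg.label for sg in self.subgroups]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.leaf_to_label.items()), columns=["leaf", "subgroup"]
        )


def _label_for(i: int) -> str:
    if i < len(_LABELS):
        return _LABELS[i]
    return _LABELS[i // 26 - 1] + _LABELS[i % 26]


def delineate_subgroups(
    red_tree: RedAnnotatedTree,
    params: DelineationParams | None = None,
    outgroup: Iterable[str] = (),
) -> SubgroupAssignment:
    """Select maximal well-supported clades passing RED and stem thresholds.

    Traversal is preorder with children visited in order of their
    lexicographically smallest descendant leaf, which fixes the A, B, C...
    label order deterministically. Nodes lacking either support value fail
    the support gate. Leaves named in ``outgroup`` are excluded entirely:
    clades containing them are never candidates and they receive no label.
    """
    params = params or DelineationParams()
    if not red_tree.red:
        raise ValueError("RED annotation missing")
    og = frozenset(outgroup)
    tree = red_tree.tree
    stems = red_tree.stem_lengths()

    leafsets: dict[dendropy.Node, frozenset] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            leafsets[nd] = frozenset([nd.taxon.label])
        else:
            leafsets[nd] = frozenset().union(*(leafsets[c] for c in nd.child_nodes()))
    ingroup_leaves = leafsets[tree.seed_node] - og
    if not ingroup_leaves:
        raise ValueError("empty ingroup: every leaf is in the outgroup")

    subgroups: list[Subgroup] = []
    leaf_to_label = {lf: UNGROUPED for lf in ingroup_leaves}

    def visit(nd: dendropy.Node) -> None:
        if leafsets[nd] & og:
            # root or outgroup side: descend only into outgroup-free children
            for c in sorted(nd.child_nodes(), key=lambda c: min(leafsets[c])):
                if leafsets[c] <= og:
                    continue
                visit(c)
            return
        if not nd.is_leaf() and nd is not tree.seed_node:
            u = getattr(nd, "ufboot", None)
            s = getattr(nd, "shalrt", None)
            red = red_tree.red[nd.node_id]
            stem = stems.get(nd.node_id, 0.0)
            ok_support = u is not None and s is not None and u >= params.ufboot_min and s >= params.shalrt_min
            if (
                ok_support
                and red > params.red_min_for(leafsets[nd]) + _EPS
                and stem > params.stem_min + _EPS
            ):
                label = _label_for(len(subgroups))
                subgroups.append(
                    Subgroup(
                        label=label,
                        node_id=nd.node_id,
                        leaves=leafsets[nd],
                        red=red,
                        stem_length=stem,
                        ufboot=u,
                        shalrt=s,
                    )
                )
                for lf in leafsets[nd]:
                    leaf_to_label[lf] = label
                return  # maximality: never select inside a selected clade
        for c in sorted(nd.child_nodes(), key=lambda c: min(leafsets[c])):
            visit(c)

    visit(tree.seed_node)
    return SubgroupAssignment(leaf_to_label=leaf_to_label, subgroups=subgroups)


def map_to_16s_clusters(
    assignment: SubgroupAssignment,
    leaf_to_cluster: Mapping[str, str] | Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Cross-tabulate subgroups against externally defined 16S clusters.

    ``leaf_to_cluster`` may cover any subset of leaves but must be
    single-valued. Returns one row per (subgroup, cluster) pair sharing at
    least one leaf, ordered by subgroup then cluster.
    """
    if isinstance(leaf_to_cluster, Mapping):
        pairs = list(leaf_to_cluster.items())
    else:
        pairs = list(leaf_to_cluster)
    mapping: dict[str, str] = {}
    for leaf, cluster in pairs:
        if leaf in mapping and mapping[leaf] != cluster:
            raise ValueError(
                f"leaf {leaf!r} mapped to both {mapping[leaf]!r} and {cluster!r}; "
                "the 16S cluster mapping must be single-valued"
            )
        mapping[leaf] = cluster

    counts: dict[tuple[str, str], int] = {}
    for leaf, cluster in mapping.items():
        label = assignment.leaf_to_label.get(leaf)
        if label is None:
            continue
        counts[(label, cluster)] = counts.get((label, cluster), 0) + 1
    rows = [
        {"subgroup": sg, "cluster": cl, "n_shared_leaves": n}
        for (sg, cl), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["subgroup", "cluster", "n_shared_leaves"])
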