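"""Dollo-parsimony mapping of gene losses onto a rooted phylogeny.

Under Dollo parsimony a gene is gained at most once (here: on the root
edge, reflecting a complete ancestral complex) and may only be lost along
any root-to-tip path.  With presence forced wherever a descendant retains
the gene, the minimal reconstruction is unique: an internal node is present
iff its subtree contains at least one present tip, and every
parent-present/child-absent edge is one independent loss event.

Unknown tip states are unconstrained — they never force presence, so they
are absorbed into whichever ancestral labeling minimizes losses — and are
flagged in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

from .model import Phylogeny, TipStateMatrix

ROOT_EDGE = ("<root>",)


def _edge_key(node: dendropy.Node) -> tuple[str, ...]:
    """Stable edge identifier: the sorted leaf set below the child node."""
    return tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))


@dataclass(frozen=True)
class LossMap:
    gene: str
    ancestral_state: dict[tuple[str, ...], str]  # clade leafset -> state
    loss_edges: tuple[tuple[str, ...], ...]
    unknown_tips: tuple[str, ...] = ()

    @property
    def n_independent_losses(self) -> int:
        return len(self.loss_edges)

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "n_independent_losses": self.n_independent_losses,
            "loss_edges": ["|".join(e) for e in self.loss_edges],
            "unknown_tips": list(self.unknown_tips),
        }


def dollo_loss_map(tree: Phylogeny, states: TipStateMatrix, gene: str,
                   assume_ancestral_present: bool = True) -> LossMap:
    """Minimal Dollo loss reconstruction for one gene.

    Raises KeyError if a leaf of the tree has no state in the matrix.  When
    every (constraining) tip is absent, the result is a single loss on the
    root edge if ``assume_ancestral_present``, else zero losses with an
    absent ancestor.
    """
    if gene not in states.genes:
        raise KeyError(f"gene {gene!r} not in state matrix")
    tip_state: dict[str, str] = {}
    unknown: list[str] = []
    for leaf in tree.tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in states.taxa:
            raise KeyError(f"leaf {label!r} has no row in the state matrix")
        st = states[(label, gene)]
        tip_state[label] = st
        if st == "unknown":
            unknown.append(label)

    # which subtrees are constrained by a known present / known absent tip
    has_present: dict[int, bool] = {}
    has_absent: dict[int, bool] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            st = tip_state[node.taxon.label]
            has_present[id(node)] = st == "present"
            has_absent[id(node)] = st == "absent"
        else:
            kids = node.child_nodes()
            has_present[id(node)] = any(has_present[id(c)] for c in kids)
            has_absent[id(node)] = any(has_absent[id(c)] for c in kids)

    # minimal labeling: presence is forced wherever a known present tip
    # sits below; an absence flip is spent only on the highest node whose
    # subtree holds a known absent tip and no known present tip (unknown
    # tips simply follow their parent, never costing a loss)
    root = tree.tree.seed_node
    ancestral: dict[tuple[str, ...], str] = {}
    losses: list[tuple[str, ...]] = []
    if not has_present[id(root)]:
        root_state = "present" if assume_ancestral_present else "absent"
        if has_absent[id(root)]:
            root_state = "absent"
            if assume_ancestral_present:
                losses.append(ROOT_EDGE)
                ancestral[ROOT_EDGE] = "absent"
        for node in tree.tree.preorder_node_iter():
            ancestral[_edge_key(node)] = root_state
    else:
        label: dict[int, str] = {id(root): "present"}
        for node in tree.tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                ancestral[_edge_key(node)] = "present"
                continue
            if label[id(parent)] == "absent":
                label[id(node)] = "absent"
            elif not has_present[id(node)] and has_absent[id(node)]:
                label[id(node)] = "absent"
                losses.append(_edge_key(node))
            else:
                label[id(node)] = "present"
            ancestral[_edge_key(node)] = label[id(node)]
    return LossMap(
        gene=gene,
        ancestral_state=ancestral,
        loss_edges=tuple(sorted(losses)),
        unknown_tips=tuple(unknown),
    )


def loss_summary(tree: Phylogeny, states: TipStateMatrix,
                 assume_ancestral_present: bool = True
                 ) -> tuple[dict[str, LossMap], pd.DataFrame]:
    """One LossMap per gene plus a tidy per-gene summary table."""
    maps = {
        gene: dollo_loss_map(tree, states, gene, assume_ancestral_present)
        for gene in states.genes
    }
    table = pd.DataFrame(
        {
            "gene": list(maps),
            "n_independent_losses": [m.n_independent_losses
                                     for m in maps.values()],
            "loss_edges": ["; ".join("|".join(e) for e in m.loss_edges)
                           for m in maps.values()],
            "unknown_tips": ["; ".join(m.unknown_tips)
                             for m in maps.values()],
        }
    )
    return maps, table


def annotated_newick(tree: Phylogeny, loss_map: LossMap) -> str:
    """Newick with comment tags marking loss edges for tree viewers."""
    work = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                             rooting="force-rooted")
    loss_set = set(loss_map.loss_edges)
    for node in work.preorder_node_iter():
        key = tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))
        if key in loss_set:
            node.annotations.add_new("loss", loss_map.gene)
    return work.as_string(schema="newick", suppress_rooting=True,
                          suppress_edge_lengths=True,
                          suppress_annotations=False).strip()
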