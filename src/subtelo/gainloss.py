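"""Dollo-parsimony annotation of gene-family gains and losses.

Under Dollo parsimony a family arises exactly once — on the branch to the
most recent common ancestor of the taxa that carry it — and can only be
lost thereafter. The minimal loss set consists of the branches to the
maximal subtrees under the gain node that contain no present taxon.
Multifurcating trees are supported; families present in every taxon are
gained on the root branch ("ancestral" content).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .core import PresenceAbsenceMatrix, SpeciesTree

log = logging.getLogger("subtelo")


@dataclass
class GainLossAnnotation:
    family_id: str
    gain_node: str  # node label (branch above this node carries the gain)
    loss_branches: set[str]  # labels of nodes whose parent branch lost the family
    singleton: bool = False  # present in exactly one taxon


def dollo_annotate(
    tree: SpeciesTree, presence: Mapping[str, int], family_id: str = ""
) -> Optional[GainLossAnnotation]:
    """Single-gain, minimal-loss annotation of one presence/absence row.

    Returns None (logged) for an all-absent family.
    """
    present = {t for t, v in presence.items() if v}
    if not present:
        log.debug("family %r absent from every taxon; no annotation", family_id)
        return None
    gain = tree.mrca(present)
    losses: set[str] = set()

    def visit(node) -> None:
        for child in node.child_nodes():
            under = tree.leaves_under(child)
            if under & present:
                visit(child)
            else:
                losses.add(tree.label(child))

    visit(gain)
    return GainLossAnnotation(
        family_id=family_id,
        gain_node=tree.label(gain),
        loss_branches=losses,
        singleton=len(present) == 1,
    )


def annotate_matrix(
    tree: SpeciesTree, matrix: PresenceAbsenceMatrix
) -> list[GainLossAnnotation]:
    matrix.validate_against(tree)
    out = []
    for fam in matrix.families:
        ann = dollo_annotate(tree, matrix.row(fam), fam)
        if ann is not None:
            out.append(ann)
    return out


def aggregate_gainloss(
    annotations: Iterable[GainLossAnnotation], tree: SpeciesTree
) -> pd.DataFrame:
    """Per-branch gain and loss totals (branch named by its child node).

    The sum of gains equals the number of annotated families; root-branch
    gains are the families inferred as ancestral to the whole tree.
    """
    labels = [tree.label(n) for n in tree.tree.preorder_node_iter()]
    gains = {lab: 0 for lab in labels}
    losses = {lab: 0 for lab in labels}
    for ann in annotations:
        gains[ann.gain_node] += 1
        for b in ann.loss_branches:
            losses[b] += 1
    return pd.DataFrame(
        {"branch": labels, "n_gains": [gains[l] for l in labels],
         "n_losses": [losses[l] for l in labels]}
    ).set_index("branch")
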