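"""Neighbour-joining trees, column bootstrap, and query placement.

The phylogeny serves as a corroborative check on distance-based
identification: queries are added to the reference distance matrix, a
neighbour-joining (NJ) tree is built, clade support is assessed by
resampling alignment columns with replacement, and each query's placement
(its sister group and the support of the smallest clade joining it to a
reference) is reported.  Support is conventionally read as weak at 50-74%
and strong at 75-100%.

The NJ agglomeration is deterministic: ties in the Q criterion are broken
toward the lexicographically smallest pair of subtree labels, so the tree
does not depend on taxon input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import BarcodekitError, ReferenceLibrary
from .distances import (
    DEFAULT_MIN_OVERLAP,
    DistanceMatrix,
    encode,
    matrix_from_encoded,
)

logger = logging.getLogger("barcodekit")

WEAK_SUPPORT = (50.0, 74.0)
STRONG_SUPPORT = (75.0, 100.0)


def support_class(support: float | None) -> str | None:
    """Classify a bootstrap percentage as 'strong' (75-100), 'weak' (50-74),
    or 'unsupported' (<50)."""
    if support is None:
        return None
    if support >= STRONG_SUPPORT[0]:
        return "strong"
    if support >= WEAK_SUPPORT[0]:
        return "weak"
    return "unsupported"


def nj_build(m: DistanceMatrix) -> TreeNode:
    """Neighbour-joining tree from a complete distance matrix.

    Standard Saitou-Nei agglomeration; negative limb estimates are clamped
    to zero.  The final three lineages are joined at a trifurcating root,
    which represents the unrooted topology exactly (patristic distances on
    an additive input reproduce the input).
    """
    n = len(m)
    if n < 3:
        raise BarcodekitError("nj_build: need at least 3 taxa")
    if not m.is_complete():
        raise BarcodekitError(
            f"nj_build: {m.n_missing_pairs} MISSING pair(s); impute or drop "
            "records with insufficient overlap first"
        )
    D = m.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in m.labels]
    # canonical key per active node = smallest tip label in its subtree
    keys: list[str] = list(m.labels)

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        pairs = {(min(i, j), max(i, j)) for i, j in cand}
        i, j = min(pairs, key=lambda p: tuple(sorted((keys[p[0]], keys[p[1]]))))
        limb_i = 0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        limb_j = D[i, j] - limb_i
        nodes[i].length = max(limb_i, 0.0)
        nodes[j].length = max(limb_j, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        du = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        newD = np.zeros((r - 1, r - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = du[keep]
        D = newD
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]

    # join the final three lineages at the (trifurcating) root
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    limbs = [0.5 * (d01 + d02 - d12), 0.5 * (d01 + d12 - d02), 0.5 * (d02 + d12 - d01)]
    for node, limb in zip(nodes, limbs):
        node.length = max(limb, 0.0)
    root = TreeNode(children=list(nodes))
    return root


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length distances of a tree."""
    dm = tree.tip_tip_distances()
    return DistanceMatrix(list(dm.ids), dm.data)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def _bipartitions(tree: TreeNode, ref_tip: str) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical tip sets (side not containing
    ``ref_tip``)."""
    all_tips = frozenset(t.name for t in tree.tips())
    n = len(all_tips)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= n - 1:
            continue
        if ref_tip in side:
            side = all_tips - side
        parts.add(side)
    return parts


def bootstrap_support(
    lib: ReferenceLibrary,
    n_reps: int = 100,
    seed: int = 0,
    model: str = "k2p",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> TreeNode:
    """NJ tree with bootstrap percentages on internal nodes.

    Alignment columns are resampled with replacement ``n_reps`` times;
    replicate r uses RNG seed ``seed + r`` so any single replicate can be
    reproduced.  Support = percent of replicate trees containing the node's
    bipartition, stored on ``node.support`` and as the internal node name.
    """
    if n_reps < 1:
        raise BarcodekitError("bootstrap_support: n_reps must be >= 1")
    enc = np.vstack([encode(r.sequence) for r in lib.records])
    labels = lib.ids
    original = matrix_from_encoded(enc, labels, model=model, min_overlap=min_overlap)
    tree = nj_build(original)
    ref_tip = min(labels)
    counts: dict[frozenset[str], int] = {p: 0 for p in _bipartitions(tree, ref_tip)}
    L = enc.shape[1]
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        cols = rng.integers(0, L, size=L)
        rep_m = matrix_from_encoded(
            enc[:, cols], labels, model=model, min_overlap=min_overlap
        )
        rep_parts = _bipartitions(nj_build(rep_m), ref_tip)
        for part in counts:
            if part in rep_parts:
                counts[part] += 1
    all_tips = frozenset(labels)
    n = len(all_tips)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= n - 1:
            node.support = None
            continue
        key = side if ref_tip not in side else all_tips - side
        node.support = 100.0 * counts.get(key, 0) / n_reps
        node.name = f"{node.support:g}"
    return tree


@dataclass(frozen=True)
class QueryPlacement:
    query_id: str
    sister_species: tuple[str, ...]
    placed_with: str | None
    resolved: bool
    support: float | None
    support_class: str | None


def annotate_queries(
    tree: TreeNode,
    query_ids: Iterable[str],
    species_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Placement report for query tips on a (bootstrapped) tree.

    For each query: the species set of its sister group in the smallest
    clade joining the query to at least one reference tip, the bootstrap
    support of that clade, and whether the placement is resolved (the
    sister set is monospecific, giving a 'placed-with' species).
    """
    query_ids = list(query_ids)
    query_set = set(query_ids)
    all_tips = frozenset(t.name for t in tree.tips())
    if query_ids:
        ref_tip = min(all_tips - query_set) if all_tips - query_set else None
        # canonical bipartition -> bootstrap support, for clade lookup
        support_map: dict[frozenset[str], float | None] = {}
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref_tip is not None and ref_tip in side:
                side = all_tips - side
            support_map[side] = getattr(node, "support", None)
    rows = []
    for qid in query_ids:
        if qid not in all_tips:
            raise BarcodekitError(f"annotate_queries: query {qid!r} not in tree")
        tip = next(t for t in tree.tips() if t.name == qid)
        parent = tip.parent
        # neighbour subtrees at the attachment node, rooting-independent:
        # the other children plus, if the parent is not the root, the
        # complement of the parent's clade
        neighbours: list[frozenset[str]] = [
            frozenset(t.name for t in child.tips()) or frozenset({child.name})
            for child in parent.children
            if child is not tip
        ]
        if parent.parent is not None:
            parent_tips = frozenset(t.name for t in parent.tips())
            neighbours.append(all_tips - parent_tips)
        candidates = [s for s in neighbours if s - query_set]
        if not candidates:  # no reference tips anywhere
            rows.append(QueryPlacement(qid, (), None, False, None, None))
            continue
        sisters = min(candidates, key=lambda s: (len(s), sorted(s)))
        if species_of is None:
            species = sorted(sisters - query_set)
        else:
            species = sorted(
                {species_of[s] for s in sisters if s in species_of and s not in query_set}
            )
        clade = sisters | {qid}
        if ref_tip is not None and ref_tip in clade:
            clade = all_tips - clade
        support = support_map.get(clade)
        resolved = len(species) == 1
        rows.append(
            QueryPlacement(
                qid,
                tuple(species),
                species[0] if resolved else None,
                resolved,
                support,
                support_class(support),
            )
        )
    return pd.DataFrame(
        [
            {
                "query_id": p.query_id,
                "sister_species": ";".join(p.sister_species),
                "placed_with": p.placed_with,
                "resolved": p.resolved,
                "support": p.support,
                "support_class": p.support_class,
            }
            for p in rows
        ],
        columns=[
            "query_id",
            "sister_species",
            "placed_with",
            "resolved",
            "support",
            "support_class",
        ],
    )
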