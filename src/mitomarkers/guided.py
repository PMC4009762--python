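"""Annotation-guided marker detection.

Every leaf of the truncated tree accumulates, per (gene, strand), the summed
nucleotide overlap of all occurrences of its window with the annotated gene
intervals; internal nodes receive the entrywise sum of their children.  A
node is a marker node when a single gene key accounts for strictly more than
a threshold fraction (default 0.95) of its total score, and the emitted
marker is the shortest word reaching that node from its parent: the parent's
label plus the first symbol of the connecting edge.  Subtrees below marker
nodes, below words seen only once, and below repetitive words are never
searched.

Annotations are given in forward-genome coordinates.  On the
reverse-complement copy of a genome they are projected with mirrored
coordinates and flipped strand, so an occurrence on the RC copy over a
``g+`` region scores toward ``g-``.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .filters import RepeatParams, reduce_marker_set, repeat_onsets
from .gst import TruncatedGST
from .model import (FORWARD, GeneAnnotation, GeneKey, Marker, Occurrence,
                    flip_strand)

DOMINANCE_THRESHOLD = 0.95


def overlap(occ: Occurrence, ann: GeneAnnotation) -> int:
    """Number of shared nucleotide positions of an occurrence interval and an
    annotated interval on the same genome copy."""
    return max(0, min(occ.end, ann.end) - max(occ.start, ann.start))


def project_annotations(
    tree: TruncatedGST, annotations: Sequence[GeneAnnotation]
) -> List[List[Tuple[int, int, GeneKey]]]:
    """Per indexed sequence, the annotation intervals in that copy's own
    coordinates, keyed by (gene, strand as seen from that copy)."""
    by_source: Dict[str, List[GeneAnnotation]] = {}
    for ann in annotations:
        by_source.setdefault(ann.source_id, []).append(ann)
    known = {s.source_id for s in tree.sequences}
    unknown = set(by_source) - known
    if unknown:
        raise ValueError(f"annotations reference unknown source ids: {sorted(unknown)}")
    projected: List[List[Tuple[int, int, GeneKey]]] = []
    for seq in tree.sequences:
        entries = []
        for ann in by_source.get(seq.source_id, []):
            if seq.strand == FORWARD:
                entries.append((ann.start, ann.end, ann.key))
            else:
                L = seq.length
                entries.append((L - ann.end, L - ann.start, ann.key.flipped()))
        projected.append(entries)
    return projected


def score_leaves(tree: TruncatedGST, annotations: Sequence[GeneAnnotation]) -> TruncatedGST:
    """Fill the per-leaf gene score tables (summed occurrence overlaps).

    Scores are exact integers (nucleotide counts).  They are stored as a
    dense (leaves x gene keys) matrix on the tree; :func:`scores_table`
    exposes the per-node mapping view.
    """
    projected = project_annotations(tree, annotations)
    keys = sorted({key for entries in projected for _, _, key in entries})
    key_index = {key: i for i, key in enumerate(keys)}
    n_leaves = tree.n_leaves
    leaf_scores = np.zeros((n_leaves, len(keys)), dtype=np.int64)

    # leaf ordinal and window length for every indexed position, grouped by sequence
    counts = tree._counts
    leaf_of_sorted = np.repeat(np.arange(n_leaves, dtype=np.int64), counts)
    gp = tree._sorted_pos
    seq_of = np.searchsorted(tree._offsets, gp, side="right") - 1
    local = gp - tree._offsets[seq_of]
    win_len = tree._real_len[leaf_of_sorted]
    order = np.argsort(seq_of, kind="stable")
    bounds = np.concatenate(
        [np.zeros(1, dtype=np.int64),
         np.cumsum(np.bincount(seq_of, minlength=len(tree.sequences)))]
    )
    for si, entries in enumerate(projected):
        sel = order[bounds[si]: bounds[si + 1]]
        if not len(sel) or not entries:
            continue
        p = local[sel]
        wl = win_len[sel]
        leaves = leaf_of_sorted[sel]
        ends = p + wl
        for start, end, key in entries:
            ov = np.minimum(ends, end) - np.maximum(p, start)
            mask = ov > 0
            if mask.any():
                leaf_scores[:, key_index[key]] += np.bincount(
                    leaves[mask], weights=ov[mask], minlength=n_leaves
                ).astype(np.int64)
    tree.gene_keys = keys
    tree._leaf_scores = leaf_scores
    tree._node_scores = None
    return tree


def propagate_scores(tree: TruncatedGST) -> TruncatedGST:
    """Bottom-up sum: every internal node's table is the entrywise sum of its
    children's tables.  Because each node's leaves form a contiguous run in
    sorted-leaf order, the sums are interval sums over leaf prefix sums."""
    if getattr(tree, "_leaf_scores", None) is None:
        raise ValueError("leaves are not scored; call score_leaves first")
    prefix = np.zeros((tree.n_leaves + 1, tree._leaf_scores.shape[1]), dtype=np.int64)
    np.cumsum(tree._leaf_scores, axis=0, out=prefix[1:])
    los = np.fromiter((n.lo for n in tree.nodes), count=tree.n_nodes, dtype=np.int64)
    his = np.fromiter((n.hi for n in tree.nodes), count=tree.n_nodes, dtype=np.int64)
    tree._node_scores = prefix[his] - prefix[los]
    return tree


def scores_table(tree: TruncatedGST, node_id: int) -> Dict[GeneKey, int]:
    """The gene score table of a node as a mapping (zero entries omitted)."""
    if getattr(tree, "_node_scores", None) is None:
        raise ValueError("scores are not propagated; call propagate_scores first")
    row = tree._node_scores[tree.node(node_id).node_id]
    return {key: int(v) for key, v in zip(tree.gene_keys, row) if v}


def dominant_gene(
    scores: Mapping[GeneKey, float], threshold: float = DOMINANCE_THRESHOLD
) -> Optional[GeneKey]:
    """The argmax gene key iff it holds strictly more than ``threshold`` of
    the total score and the total is positive; ``None`` otherwise."""
    total = sum(scores.values())
    if total <= 0:
        return None
    best_key = max(scores, key=lambda k: (scores[k], k))
    if scores[best_key] / total > threshold:
        return best_key
    return None


def detect_guided(
    tree: TruncatedGST,
    annotations: Sequence[GeneAnnotation],
    repeat_params: RepeatParams = RepeatParams(),
    threshold: float = DOMINANCE_THRESHOLD,
    min_support: int = 2,
) -> Set[Marker]:
    """Run the annotation-guided detection over a (scored) tree.

    Depth-first search from the root; at each node the word is dismissed
    with its whole subtree when it occurs fewer than ``min_support`` times or
    already contains a disqualifying repeat.  At the shallowest node whose
    score table is dominated by one gene key, the marker (parent label plus
    one symbol) is emitted and the subtree skipped.  The candidate set is
    finally reduced to a substring antichain.
    """
    if not annotations:
        raise ValueError("guided method requires annotations")
    if getattr(tree, "_node_scores", None) is None:
        score_leaves(tree, annotations)
        propagate_scores(tree)
    scores = tree._node_scores
    totals = scores.sum(axis=1)
    best = scores.max(axis=1) if scores.shape[1] else np.zeros(len(scores))
    arg = scores.argmax(axis=1) if scores.shape[1] else np.zeros(len(scores), dtype=int)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(totals > 0, best / np.maximum(totals, 1), 0.0)
    dominant = (totals > 0) & (ratio > threshold)
    onsets = repeat_onsets(tree._U, tree._real_len, repeat_params)

    candidates: List[Marker] = []
    nodes = tree.nodes
    stack = list(nodes[tree.root].children.values())
    while stack:
        nid = stack.pop()
        node = nodes[nid]
        if node.count < min_support:
            continue
        rd = tree.real_depth(nid)
        if onsets[node.lo] <= rd:
            continue  # repetitive path label: dismiss the whole subtree
        if dominant[nid]:
            if tree.has_sentinel(nid):
                continue  # sentinel-terminated labels never become markers
            parent_depth = nodes[node.parent].depth
            word = tree.path_label(nid)[: parent_depth + 1]
            key = tree.gene_keys[arg[nid]]
            candidates.append(
                Marker(
                    word,
                    "guided",
                    key,
                    int(node.count),
                    {
                        "dominance": float(ratio[nid]),
                        "node_depth": rd,
                    },
                )
            )
            continue
        stack.extend(node.children.values())
    return reduce_marker_set(candidates, tree)
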