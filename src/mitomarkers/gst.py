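"""k-truncated generalized suffix tree with per-node occurrence counts.

The tree indexes, for every start position of every input sequence, the
window of length ``k`` beginning there (or the shorter suffix followed by a
terminal sentinel ``$`` when fewer than ``k`` symbols remain).  It therefore
contains exactly the substrings of the inputs up to length ``k`` plus the
sentinel-terminated short suffixes, and every node knows how often its path
label occurs.

Construction enumerates all windows, sorts them, and folds the sorted unique
words into a compressed trie using longest-common-prefix intervals — the
classical suffix-array-to-suffix-tree transformation.  The heavy lifting
(window extraction, sorting, de-duplication, LCPs) is vectorized with numpy;
only the final fold over unique words is a Python loop.  The resulting tree
is identical, node for node and count for count, to one built by online
insertion; the per-node leaf intervals it yields double as the occurrence
index used for multi-pattern search.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .model import DNA_ALPHABET, IUPAC_EXTRA, IndexedSequence, Occurrence

SENTINEL = "$"

# symbol codes: sentinel/pad = 0, A..T = 1..4, tolerated ambiguity codes = 5,
# anything else = 255 (a hard error).
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate(DNA_ALPHABET):
    _CODE[ord(_ch)] = _i + 1
for _ch in IUPAC_EXTRA:
    _CODE[ord(_ch)] = 5
_DECODE = SENTINEL + DNA_ALPHABET


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes (A..T -> 1..4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class TreeNode:
    """A node of the truncated tree.

    ``depth`` is the path-label length in symbols, counting the terminal
    sentinel for sentinel-terminated leaves.  ``children`` maps the first
    symbol code of each outgoing edge to a child id.  ``lo``/``hi`` delimit
    the contiguous run of (sorted) leaf ordinals below the node; ``lo`` is
    also the representative leaf whose word spells the node's path label.
    ``suffix_link`` is kept for API completeness; the offline construction
    used here does not need it and leaves it unset.
    """

    __slots__ = ("node_id", "parent", "depth", "children", "suffix_link",
                 "count", "lo", "hi")

    def __init__(self, node_id: int, parent: Optional[int], depth: int) -> None:
        self.node_id = node_id
        self.parent = parent
        self.depth = depth
        self.children: Dict[int, int] = {}
        self.suffix_link: Optional[int] = None
        self.count = 0
        self.lo = -1
        self.hi = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def edge_length(self) -> int:
        return self.depth  # refined by the tree, which knows the parent


class TruncatedGST:
    """The k-truncated generalized suffix tree over a set of sequences."""

    def __init__(self, sequences: Sequence[IndexedSequence], k: int) -> None:
        if k < 1:
            raise ValueError("truncation depth k must be >= 1")
        sequences = list(sequences)
        if not sequences:
            raise ValueError("no input")
        self.sequences = sequences
        self.k = k
        self._build()

    # -- construction ----------------------------------------------------

    def _build(self) -> None:
        k = self.k
        mats: List[np.ndarray] = []
        gpos: List[np.ndarray] = []
        offsets = np.zeros(len(self.sequences) + 1, dtype=np.int64)
        for si, s in enumerate(self.sequences):
            codes = encode(s.residues)
            bad = np.flatnonzero(codes == 255)
            if bad.size:
                pos = int(bad[0])
                raise ValueError(
                    f"invalid symbol {s.residues[pos]!r} in sequence "
                    f"{s.source_id} ({s.strand}) at position {pos}"
                )
            padded = np.zeros(len(codes) + k, dtype=np.uint8)
            padded[: len(codes)] = codes
            win = np.lib.stride_tricks.sliding_window_view(padded, k)[: len(codes) + 1]
            keep = ~(win == 5).any(axis=1)
            mats.append(np.ascontiguousarray(win[keep]))
            gpos.append(np.flatnonzero(keep) + offsets[si])
            offsets[si + 1] = offsets[si] + len(codes) + 1
        self._offsets = offsets

        W = np.concatenate(mats)
        positions = np.concatenate(gpos)
        void = W.view(np.dtype((np.void, k))).ravel()
        uniq, inverse, counts = np.unique(void, return_inverse=True, return_counts=True)
        U = uniq.view(np.uint8).reshape(-1, k)
        order = np.argsort(inverse, kind="stable")
        self._U = U
        self._counts = counts.astype(np.int64)
        self._sorted_pos = positions[order]
        self._leaf_starts = np.concatenate(
            [np.zeros(1, dtype=np.int64), np.cumsum(counts, dtype=np.int64)]
        )
        iszero = U == 0
        self._wordlen = np.where(iszero.any(axis=1), iszero.argmax(axis=1) + 1, k)
        self._real_len = self._wordlen - iszero.any(axis=1).astype(np.int64)

        if len(U) > 1:
            eq = U[1:] == U[:-1]
            lcp = np.where(eq.all(axis=1), k, (~eq).argmax(axis=1))
        else:
            lcp = np.zeros(0, dtype=np.int64)

        self._fold(U, lcp)
        self._accumulate()

    def _fold(self, U: np.ndarray, lcp: np.ndarray) -> None:
        """Fold the sorted unique words into a compressed trie."""
        root = TreeNode(0, None, 0)
        root.lo = 0
        nodes = [root]
        stack = [root]
        wordlen = self._wordlen
        for i in range(len(U)):
            depth_limit = int(lcp[i - 1]) if i > 0 else 0
            last: Optional[TreeNode] = None
            while stack[-1].depth > depth_limit:
                last = stack.pop()
            top = stack[-1]
            if top.depth < depth_limit:
                # split the edge to `last` with a new internal node
                assert last is not None
                mid = TreeNode(len(nodes), top.node_id, depth_limit)
                nodes.append(mid)
                mid.lo = last.lo
                top.children[int(U[last.lo, top.depth])] = mid.node_id
                mid.children[int(U[last.lo, depth_limit])] = last.node_id
                last.parent = mid.node_id
                stack.append(mid)
                top = mid
            leaf = TreeNode(len(nodes), top.node_id, int(wordlen[i]))
            nodes.append(leaf)
            leaf.lo = i
            leaf.hi = i + 1
            leaf.count = int(self._counts[i])
            top.children[int(U[i, top.depth])] = leaf.node_id
            stack.append(leaf)
        self.nodes = nodes
        self.root = 0

    def _accumulate(self) -> None:
        """Bottom-up pass: internal counts and leaf intervals."""
        nodes = self.nodes
        stack = [(0, False)]
        while stack:
            nid, seen = stack.pop()
            node = nodes[nid]
            if not node.children:
                continue
            if not seen:
                stack.append((nid, True))
                stack.extend((c, False) for c in node.children.values())
            else:
                node.count = sum(nodes[c].count for c in node.children.values())
                node.hi = max(nodes[c].hi for c in node.children.values())
                # lo was fixed at creation time and is the leftmost leaf

    # -- basic queries ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_leaves(self) -> int:
        return len(self._U)

    @property
    def total_symbols(self) -> int:
        """Summed length of all indexed sequences (the sample size N)."""
        return sum(s.length for s in self.sequences)

    def node(self, node_id: int) -> TreeNode:
        if not 0 <= node_id < len(self.nodes):
            raise KeyError(f"unknown node id {node_id}")
        return self.nodes[node_id]

    def iter_nodes(self) -> Iterable[TreeNode]:
        return iter(self.nodes)

    def real_depth(self, node_id: int) -> int:
        """Path-label length excluding a terminal sentinel."""
        node = self.node(node_id)
        if node.children:
            return node.depth
        return int(self._real_len[node.lo]) if node.depth == self._wordlen[node.lo] else node.depth

    def has_sentinel(self, node_id: int) -> bool:
        node = self.node(node_id)
        return not node.children and self._real_len[node.lo] < self._wordlen[node.lo]

    def label_codes(self, node_id: int) -> np.ndarray:
        node = self.node(node_id)
        return self._U[node.lo, : node.depth]

    def path_label(self, node_id: int) -> str:
        """Concatenated edge labels from the root, sentinel included."""
        return "".join(_DECODE[c] for c in self.label_codes(node_id))

    def node_word(self, node_id: int) -> str:
        """The path label with any terminal sentinel stripped."""
        label = self.path_label(node_id)
        return label[:-1] if label.endswith(SENTINEL) else label

    def edge_ref(self, node_id: int):
        """(seq_index, start, end) of a representative occurrence of the
        incoming edge label, in sequence-local coordinates."""
        node = self.node(node_id)
        if node.parent is None:
            raise ValueError("the root has no incoming edge")
        parent = self.nodes[node.parent]
        gp = int(self._sorted_pos[self._leaf_starts[node.lo]])
        si, local = self._locate_global(gp)
        end = min(local + node.depth, self.sequences[si].length)
        return si, local + parent.depth, end

    # -- occurrence machinery ---------------------------------------------

    def _locate_global(self, gpos: int):
        si = int(np.searchsorted(self._offsets, gpos, side="right")) - 1
        return si, gpos - int(self._offsets[si])

    def occurrence_positions(self, node_id: int):
        """Vectorized occurrence list: (seq_index array, local start array)."""
        node = self.node(node_id)
        gp = self._sorted_pos[self._leaf_starts[node.lo]: self._leaf_starts[node.hi]]
        si = np.searchsorted(self._offsets, gp, side="right") - 1
        return si, gp - self._offsets[si]

    def occurrences_of_node(self, node_id: int) -> List[Occurrence]:
        """All placements of the node's path label (sentinel stripped).

        Undefined for the root and for the bare-sentinel leaf, whose
        stripped labels are empty: zero-length matches are meaningless.
        """
        node = self.node(node_id)
        rd = self.real_depth(node_id)
        if rd == 0:
            raise ValueError("occurrences of a zero-length label are undefined")
        si, starts = self.occurrence_positions(node_id)
        return [Occurrence(int(s), int(p), int(p) + rd) for s, p in zip(si, starts)]

    def locate(self, pattern: str) -> Optional[int]:
        """Id of the shallowest node whose path label has ``pattern`` as a
        prefix, or ``None`` when the pattern does not occur."""
        if len(pattern) > self.k:
            raise ValueError(
                f"pattern of length {len(pattern)} exceeds truncation depth {self.k}"
            )
        pat = encode(pattern)
        if pat.size == 0:
            return self.root
        if ((pat < 1) | (pat > 4)).any():
            raise ValueError(f"pattern {pattern!r} contains non-ACGT symbols")
        node = self.nodes[self.root]
        d = 0
        while d < len(pat):
            child_id = node.children.get(int(pat[d]))
            if child_id is None:
                return None
            child = self.nodes[child_id]
            upto = min(len(pat), child.depth)
            if not np.array_equal(pat[d:upto], self._U[child.lo, d:upto]):
                return None
            node = child
            d = upto
        return node.node_id

    def find_all(self, patterns: Iterable[str]) -> Dict[str, List[Occurrence]]:
        """Exact placements of every pattern across the indexed sequences.

        Each lookup is a single root-to-node walk of the pattern followed by
        a slice of the precomputed position index, so total work is linear in
        summed pattern length plus output size.
        """
        result: Dict[str, List[Occurrence]] = {}
        for pattern in patterns:
            nid = self.locate(pattern)
            if nid is None or nid == self.root:
                result[pattern] = []
                continue
            si, starts = self.occurrence_positions(nid)
            m = len(pattern)
            result[pattern] = [
                Occurrence(int(s), int(p), int(p) + m) for s, p in zip(si, starts)
            ]
        return result

    def count_of(self, pattern: str) -> int:
        nid = self.locate(pattern)
        if nid is None:
            return 0
        return self.nodes[nid].count


def build_truncated_gst(sequences: Sequence[IndexedSequence], k: int) -> TruncatedGST:
    """Build the k-truncated generalized suffix tree with populated counts."""
    return TruncatedGST(sequences, k)
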