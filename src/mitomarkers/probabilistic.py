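"""Probability-based marker detection.

A third-order Markov chain fitted to the indexed sequences supplies a null
probability P(w) for every word; a word seen n(v) times in a text of N
symbols is compared against its expected count N*P(w) with the two-category
chi-square statistic

    U^2 = (n(v) - N * P(w))^2 / (N * P(w) * (1 - P(w)))

and declared significant when U^2 exceeds a user threshold ``z`` *and* the
word is over-represented (n(v) > N * P(w)).  The depth-first search over the
truncated tree emits, at every shallowest significant node, the shortest
prefix of the incoming edge word that is itself significant, then skips the
subtree.  Candidates are finally reduced to a substring antichain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set

import numpy as np

from .filters import RepeatParams, reduce_marker_set, repeat_onsets
from .gst import TruncatedGST, encode
from .model import DNA_ALPHABET, IndexedSequence, Marker

MAX_ORDER = 3


@dataclass
class MarkovModel3:
    """Order-3 Markov chain over {A,C,G,T}.

    ``context_tables[c]`` has shape ``(4**c, 4)``; row ``ctx`` is the
    conditional distribution of the next symbol after the length-``c``
    context whose base-4 code is ``ctx`` (first context symbol most
    significant).  ``trained_on_length`` is the summed length N of the
    training text, which doubles as the chi-square sample size.
    """

    context_tables: Dict[int, np.ndarray]
    pseudocount: float
    trained_on_length: int

    def prob(self, context: str, symbol: str) -> float:
        """P(symbol | up to the last three symbols of ``context``)."""
        c = min(len(context), MAX_ORDER)
        ctx = context[len(context) - c:]
        idx = 0
        for ch in ctx:
            idx = idx * 4 + DNA_ALPHABET.index(ch)
        return float(self.context_tables[c][idx, DNA_ALPHABET.index(symbol)])

    # -- plain-text persistence -------------------------------------------

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# order-3 markov model; pseudocount={self.pseudocount!r}; "
                     f"N={self.trained_on_length}\n")
            fh.write("context\tA\tC\tG\tT\n")
            for c in range(MAX_ORDER + 1):
                table = self.context_tables[c]
                for ctx in range(table.shape[0]):
                    name = _ctx_name(ctx, c)
                    probs = "\t".join(repr(float(p)) for p in table[ctx])
                    fh.write(f"{name}\t{probs}\n")

    @classmethod
    def load(cls, path) -> "MarkovModel3":
        tables = {c: np.zeros((4 ** c, 4)) for c in range(MAX_ORDER + 1)}
        pseudocount, n = 1.0, 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for part in line[1:].split(";"):
                        part = part.strip()
                        if part.startswith("pseudocount="):
                            pseudocount = float(part.split("=", 1)[1])
                        elif part.startswith("N="):
                            n = int(part.split("=", 1)[1])
                    continue
                if line.startswith("context") or not line.strip():
                    continue
                name, *probs = line.split()
                ctx_str = "" if name == "." else name
                c = len(ctx_str)
                idx = 0
                for ch in ctx_str:
                    idx = idx * 4 + DNA_ALPHABET.index(ch)
                tables[c][idx] = [float(p) for p in probs]
        return cls(tables, pseudocount, n)


def _ctx_name(idx: int, length: int) -> str:
    if length == 0:
        return "."
    out = []
    for _ in range(length):
        out.append(DNA_ALPHABET[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def fit_markov(
    sequences: Sequence[IndexedSequence], pseudocount: float = 1.0
) -> MarkovModel3:
    """Fit the order-0..3 conditional tables from {1,2,3,4}-mer counts.

    P(s, a) = (count(sa) + pseudocount) / (count(s*) + 4 * pseudocount),
    where count(s*) sums count(sa) over the four successors, so contexts at
    sequence ends without a successor do not contribute.  Ambiguous symbols
    break the k-mer windows just as they do in the tree.
    """
    sequences = list(sequences)
    total = sum(s.length for s in sequences)
    if total == 0:
        raise ValueError("cannot fit a Markov model on empty input")
    mer_counts = [np.zeros(4 ** m, dtype=np.int64) for m in range(MAX_ORDER + 2)]
    mults = [4 ** np.arange(m - 1, -1, -1, dtype=np.int64) for m in range(MAX_ORDER + 2)]
    for s in sequences:
        codes = encode(s.residues).astype(np.int64) - 1  # A..T -> 0..3, other < 0 or >= 4
        valid = (codes >= 0) & (codes <= 3)
        for m in range(1, MAX_ORDER + 2):
            if len(codes) < m:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes, m)
            ok = np.lib.stride_tricks.sliding_window_view(valid, m).all(axis=1)
            if ok.any():
                idx = win[ok] @ mults[m]
                mer_counts[m] += np.bincount(idx, minlength=4 ** m)
    tables: Dict[int, np.ndarray] = {}
    for c in range(MAX_ORDER + 1):
        succ = mer_counts[c + 1].reshape(4 ** c, 4).astype(float)
        denom = succ.sum(axis=1, keepdims=True) + 4.0 * pseudocount
        with np.errstate(invalid="ignore", divide="ignore"):
            table = (succ + pseudocount) / denom
        if pseudocount == 0:
            table[np.isnan(table)] = 0.0
        tables[c] = table
    return MarkovModel3(tables, pseudocount, total)


def word_probability(model: MarkovModel3, w: str) -> float:
    """Null probability of ``w``: the chained product
    P(w0) * P(w0, w1) * P(w0w1, w2) * prod P(w[i:i+3], w[i+3])."""
    if not w:
        raise ValueError("word must be non-empty")
    if any(ch not in DNA_ALPHABET for ch in w):
        raise ValueError(f"word {w!r} contains non-ACGT symbols")
    p = 1.0
    for i, ch in enumerate(w):
        p *= model.prob(w[max(0, i - MAX_ORDER): i], ch)
    return p


def chi_square_stat(n_v: float, N: float, p: float) -> float:
    """Closed two-category form of the chi-square score."""
    if not 0.0 < p < 1.0:
        raise ValueError("degenerate expectation: word probability must be in (0, 1)")
    return (n_v - N * p) ** 2 / (N * p * (1.0 - p))


@dataclass(frozen=True)
class SignificanceParams:
    """``z``: rejection threshold for U^2; ``min_support``: minimum number
    of occurrences a marker must have (words seen once are never markers)."""

    z: float = 50_000.0
    min_support: int = 2

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("significance threshold z must be > 0")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


def is_significant(
    n_v: float, N: float, p: float, params: SignificanceParams
) -> bool:
    """Over-representation test: z < U^2, n(v) > N*p, n(v) >= min_support.

    The chi-square statistic alone also grows for under-represented words;
    only words occurring more often than expected can serve as markers."""
    if n_v < params.min_support:
        return False
    if n_v <= N * p:
        return False
    return chi_square_stat(n_v, N, p) > params.z


def _leaf_prefix_probs(tree: TruncatedGST, model: MarkovModel3) -> np.ndarray:
    """cumP[i, d-1] = P(first d symbols of unique word i), vectorized.

    Positions past a word's real length hold ones so the cumulative product
    stays valid for shorter prefixes."""
    U = tree._U
    n, k = U.shape
    codes = U.astype(np.int64) - 1  # real symbols 0..3, sentinel/pad -> -1
    real = tree._real_len
    factors = np.ones((n, k))
    ctx = np.zeros(n, dtype=np.int64)
    for i in range(k):
        c = min(i, MAX_ORDER)
        table = model.context_tables[c]
        sym = codes[:, i]
        live = (sym >= 0) & (i < real)
        if live.any():
            factors[live, i] = table[ctx[live], sym[live]]
        # roll the context window (base-4, keep at most MAX_ORDER symbols)
        nxt = np.where(live, sym, 0)
        if i < MAX_ORDER:
            ctx = ctx * 4 + nxt
        else:
            ctx = (ctx % (4 ** (MAX_ORDER - 1))) * 4 + nxt
    return np.cumprod(factors, axis=1)


def detect_probabilistic(
    tree: TruncatedGST,
    model: Optional[MarkovModel3] = None,
    params: SignificanceParams = SignificanceParams(),
    repeat_params: RepeatParams = RepeatParams(),
) -> Set[Marker]:
    """Run the probability-based detection over a counted tree.

    When no model is given, one is fitted to the tree's own sequences with
    the default pseudocount.
    """
    if model is None:
        model = fit_markov(tree.sequences)
    N = float(model.trained_on_length)
    cumP = _leaf_prefix_probs(tree, model)
    onsets = repeat_onsets(tree._U, tree._real_len, repeat_params)

    nodes = tree.nodes
    n_nodes = tree.n_nodes
    node_count = np.fromiter((nd.count for nd in nodes), count=n_nodes, dtype=np.int64)
    node_lo = np.fromiter((nd.lo for nd in nodes), count=n_nodes, dtype=np.int64)
    node_rd = np.fromiter(
        (tree.real_depth(i) for i in range(n_nodes)), count=n_nodes, dtype=np.int64
    )
    safe_rd = np.maximum(node_rd, 1)
    p_full = cumP[node_lo, safe_rd - 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        u2 = (node_count - N * p_full) ** 2 / (N * p_full * (1.0 - p_full))
    usable = (node_rd > 0) & (p_full > 0.0) & (p_full < 1.0)
    significant = (
        usable
        & (node_count >= params.min_support)
        & (node_count > N * p_full)
        & (u2 > params.z)
    )

    candidates: List[Marker] = []
    stack = list(nodes[tree.root].children.values())
    while stack:
        nid = stack.pop()
        node = nodes[nid]
        if node.count < params.min_support:
            continue
        rd = int(node_rd[nid])
        if onsets[node.lo] <= rd:
            continue  # repetitive path label: dismiss the whole subtree
        if tree.has_sentinel(nid):
            continue  # sentinel-terminated labels never become markers
        if significant[nid]:
            parent_depth = nodes[node.parent].depth
            n_v = float(node.count)
            word_codes = tree._U[node.lo]
            # shortest significant prefix of the incoming edge word
            for d in range(parent_depth + 1, rd + 1):
                p_w = float(cumP[node.lo, d - 1])
                if not 0.0 < p_w < 1.0:
                    continue
                if is_significant(n_v, N, p_w, params):
                    word = "".join(DNA_ALPHABET[c - 1] for c in word_codes[:d])
                    candidates.append(
                        Marker(
                            word,
                            "probabilistic",
                            None,
                            int(n_v),
                            {
                                "u2": chi_square_stat(n_v, N, p_w),
                                "p_word": p_w,
                                "e1": N * p_w,
                            },
                        )
                    )
                    break
            continue
        stack.extend(node.children.values())
    return reduce_marker_set(candidates, tree)
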