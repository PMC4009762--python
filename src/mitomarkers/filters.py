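"""Marker filtering: short-tandem-repeat rejection and substring reduction.

A word is disqualified as a marker when it contains a tandem repeat of a
unit of at most ``l`` symbols repeated more than ``r`` times, detected by a
sliding-window scan that counts completed periods (more than ``r`` full
repetitions trigger rejection, so e.g. ``ATATATA`` at ``l=4, r=3`` — three
full ``AT`` periods — passes while ``ATATATAT`` does not).

The final marker set must be an antichain under the substring relation: no
marker may be a prefix, suffix, or infix of another.  Detection already
guarantees prefix-freeness (no node below an emitted node is ever tested),
so the reduction walks every proper suffix of each candidate through a trie
of all candidates and discards words that contain a shorter candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Set

import numpy as np

from .model import Marker

#: "infinite" onset: the word contains no disqualifying repeat
NO_REPEAT = np.iinfo(np.int64).max


@dataclass(frozen=True)
class RepeatParams:
    """``l``: maximum repeat-unit length; ``r``: repeat threshold (a word
    with a unit repeated more than ``r`` times is rejected)."""

    l: int = 4
    r: int = 3

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError("repeat unit length l must be >= 1")
        if self.r < 2:
            raise ValueError("repeat threshold r must be >= 2")


def contains_repeat(w: str, params: RepeatParams = RepeatParams()) -> bool:
    """True iff ``w`` contains a unit of length <= l repeated more than r times.

    Direct sliding-window period counting in O(l * |w|): for each unit length
    a window is shifted over the word, the repetition counter is reset at any
    mismatch between window ends, and incremented each time a full period
    passes cleanly.
    """
    n = len(w)
    for j in range(params.l):  # unit length j + 1
        offset = j
        count = 1
        for i in range(j + 1, n):
            if w[i] != w[i - j - 1]:
                count = 1
                offset = i % (j + 1)
            elif offset == i % (j + 1):
                count += 1
                if count > params.r:
                    return True
    return False


def repeat_onsets(codes: np.ndarray, real_len: np.ndarray,
                  params: RepeatParams = RepeatParams()) -> np.ndarray:
    """For each row of a code matrix, the shortest prefix length that already
    contains a disqualifying repeat (``NO_REPEAT`` when none does).

    A unit of length ``u`` repeated more than ``r`` times is equivalent to a
    run of at least ``r * u`` consecutive positions ``i`` with
    ``w[i] == w[i - u]``; the onset is where that run completes.  This is the
    vectorized counterpart of :func:`contains_repeat` applied to every prefix
    of every row at once, used to prune repetitive subtrees during detection.
    """
    n_rows, width = codes.shape
    onset = np.full(n_rows, NO_REPEAT, dtype=np.int64)
    for u in range(1, params.l + 1):
        if width <= u:
            break
        need = params.r * u
        idx = np.arange(width - u)
        # eq[:, i] compares position j = i + u with j - u, masked to real symbols
        eq = (codes[:, u:] == codes[:, :-u]) & ((idx + u) < real_len[:, None])
        last_false = np.where(eq, -1, idx)
        np.maximum.accumulate(last_false, axis=1, out=last_false)
        run = idx - last_false
        hit = run >= need
        any_hit = hit.any(axis=1)
        first = hit.argmax(axis=1)
        cand = np.where(any_hit, first + u + 1, NO_REPEAT)
        onset = np.minimum(onset, cand)
    return onset


def _trie_insert(trie: Dict, word: str) -> None:
    node = trie
    for ch in word:
        node = node.setdefault(ch, {})
    node["$"] = len(word)


def _contains_candidate(trie: Dict, word: str) -> bool:
    """True iff some candidate other than ``word`` itself is a prefix of a
    suffix of ``word`` (i.e. a prefix, suffix, or infix of it)."""
    n = len(word)
    for i in range(n):
        node = trie
        for j in range(i, n):
            node = node.get(word[j])
            if node is None:
                break
            if "$" in node:
                hit_len = node["$"]
                if not (i == 0 and hit_len == n):  # skip the word itself
                    return True
    return False


def reduce_marker_set(candidates: Iterable[Marker], tree) -> Set[Marker]:
    """Drop every candidate that contains another candidate as a substring.

    The shorter marker is always the one kept (a longer word "contains
    another marker").  The result is independent of input order: membership
    tests run against the trie of *all* candidates, so a word dropped for
    containing ``m`` cannot rescue any other word.  Each candidate must be a
    word of the tree.
    """
    by_word: Dict[str, Marker] = {}
    for m in sorted(candidates, key=lambda m: (m.word, m.method)):
        by_word.setdefault(m.word, m)
    trie: Dict = {}
    for word in by_word:
        if tree is not None:
            nid = tree.locate(word)
            if nid is None:
                raise ValueError(f"candidate {word!r} does not occur in the tree")
        _trie_insert(trie, word)
    return {m for w, m in by_word.items() if not _contains_candidate(trie, w)}
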