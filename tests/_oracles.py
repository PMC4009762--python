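"""Independent brute-force oracles used by the test suite.

Everything here works directly on plain strings with naive scanning —
deliberately sharing no code path with the package internals it checks.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple


def occurrences_in(word: str, s: str) -> List[int]:
    """Overlapping start positions of ``word`` in ``s``."""
    hits, p = [], s.find(word)
    while p != -1:
        hits.append(p)
        p = s.find(word, p + 1)
    return hits


def count_label(label: str, sequences: Sequence[str]) -> int:
    """Occurrences of a tree path label; a trailing ``$`` anchors the word to
    the end of a sequence, a bare ``$`` matches once per sequence."""
    total = 0
    for s in sequences:
        if label.endswith("$"):
            core = label[:-1]
            total += 1 if s.endswith(core) else 0
        else:
            total += len(occurrences_in(label, s))
    return total


def find_pattern(pattern: str, sequences: Sequence[str]) -> List[Tuple[int, int, int]]:
    """All (seq_index, start, end) placements by naive scanning."""
    hits = []
    for si, s in enumerate(sequences):
        for p in range(len(s) - len(pattern) + 1):
            if s[p:p + len(pattern)] == pattern:
                hits.append((si, p, p + len(pattern)))
    return hits


def all_substrings_upto(sequences: Sequence[str], k: int) -> set:
    subs = set()
    for s in sequences:
        for i in range(len(s)):
            for j in range(i + 1, min(i + k, len(s)) + 1):
                subs.add(s[i:j])
    return subs


def has_repeat(w: str, l: int, r: int) -> bool:
    """True iff some unit q with |q| <= l occurs repeated r+1 times in w."""
    for u in range(1, l + 1):
        span = u * (r + 1)
        for start in range(len(w) - span + 1):
            q = w[start:start + u]
            if w[start:start + span] == q * (r + 1):
                return True
    return False


def reduce_words(words: Sequence[str]) -> set:
    """Brute-force antichain reduction: drop any word with another word of
    the set as a proper substring."""
    ws = set(words)
    return {
        w for w in ws
        if not any(v != w and v in w for v in ws)
    }


def is_antichain(words: Sequence[str]) -> bool:
    ws = list(words)
    return not any(
        v != w and v in w for w in ws for v in ws
    )


def window_gene_scores(
    word: str,
    sequences: Sequence[str],
    annotations_per_seq: Sequence[Sequence[Tuple[int, int, object]]],
    k: int,
) -> Dict[object, int]:
    """Window-overlap score table of a word, recomputed from scratch.

    For every start of ``word`` in every sequence, the full indexing window
    [p, min(p+k, L)) is intersected with each annotated interval of that
    sequence and the shared positions are summed per gene key.
    """
    scores: Dict[object, int] = {}
    for si, s in enumerate(sequences):
        for p in occurrences_in(word, s):
            w_end = min(p + k, len(s))
            for start, end, key in annotations_per_seq[si]:
                ov = min(w_end, end) - max(p, start)
                if ov > 0:
                    scores[key] = scores.get(key, 0) + ov
    return scores


def dominance_ratio(scores: Dict[object, int]) -> float:
    total = sum(scores.values())
    return max(scores.values()) / total if total else 0.0
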