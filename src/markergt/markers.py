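"""Marker arrays in suffix-rank order, their sparse encoding, and the FL oracle.

The marker array MA permutes the dense marker map M into suffix-array order,
MA[i] = M[SA[i]].  Because suffixes beginning with the same allele cluster in
the suffix array, identical entries form runs, which the sparse S/E/X/B
encoding exploits: bitvectors S and E mark run starts and ends, X stores one
payload list per run, and B marks each run's first payload within X.

The augmented ("smeared") array MA^w additionally lists, at rank i, every
marker in the window of text positions SA[i]..SA[i]+w, clipped at the
document separator — a suffix near a document's end cannot overlap the next
haplotype.  MA^w is what lets the read scanner query markers only every w
backward-search steps instead of at every step.

The fully-sensitive alternative, :func:`fl_marker_query`, walks |q|-1 FL
steps from every row of a pattern's SA range, consulting M at each visited
position.  It is exact but costs O(|q| * occ); the scanner treats it as the
oracle its heuristic must stay within.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fmcore import FMIndexBundle, count_occurrences, fl_step
from .panel import SEPARATOR, ConcatenatedText, DenseMarkerMap

Payloads = Sequence[int]


class SparseMultimap:
    """Run-length encoding of a mostly-empty array of payload lists.

    ``S``/``E`` are bitvectors over the original array with 1s at the first
    and last position of each maximal run of identical non-empty entries;
    ``X`` flattens one payload list per run and ``B`` marks list boundaries
    in ``X``.  A[i] is non-empty iff S.rank1(i+1) > E.rank1(i), and then its
    payloads are the B-delimited slice of X for run E.rank1(i).
    """

    def __init__(self, s: np.ndarray, e: np.ndarray, x: np.ndarray, b: np.ndarray):
        if s.shape != e.shape or x.shape != b.shape:
            raise ValueError("inconsistent sparse-multimap component lengths")
        n_runs = int(s.sum())
        if n_runs != int(e.sum()) or n_runs != int(b.sum()):
            raise ValueError("popcount(S) = popcount(E) = popcount(B) violated")
        self.s = s
        self.e = e
        self.x = x
        self.b = b
        # prefix-sum rank over S and E; select over B
        self._s_rank = np.concatenate(([0], np.cumsum(s, dtype=np.int64)))
        self._e_rank = np.concatenate(([0], np.cumsum(e, dtype=np.int64)))
        self._b_sel = np.concatenate(
            (np.flatnonzero(b), [len(x)])
        )

    def __len__(self) -> int:
        return len(self.s)

    @property
    def n_runs(self) -> int:
        return len(self._b_sel) - 1

    def serialized_size_bytes(self) -> int:
        """Bytes of the on-disk form: packed S, E, B plus 64-bit X words."""
        bits = len(self.s)
        return 2 * ((bits + 7) // 8) + ((len(self.b) + 7) // 8) + 8 * len(self.x)


def sparse_encode(dense: Sequence[Payloads | None]) -> SparseMultimap:
    """Encode an array of optional payload lists; decodes back exactly.

    Adjacent entries merge into one run only when their full payload lists
    are equal element-wise.
    """
    n = len(dense)
    s = np.zeros(n, dtype=bool)
    e = np.zeros(n, dtype=bool)
    x: list[int] = []
    b: list[bool] = []
    prev: tuple[int, ...] | None = None
    for i, entry in enumerate(dense):
        cur = tuple(entry) if entry else None
        if cur != prev and prev is not None:
            e[i - 1] = True
        if cur is not None and cur != prev:
            s[i] = True
            x.extend(cur)
            b.extend([True] + [False] * (len(cur) - 1))
        prev = cur
    if prev is not None:
        e[n - 1] = True
    return SparseMultimap(s, e, np.asarray(x, dtype=np.uint64), np.asarray(b, dtype=bool))


def sparse_access(sm: SparseMultimap, i: int) -> list[int]:
    """A[i] recovered from the S/E/X/B structures (empty list if unmarked)."""
    if not 0 <= i < len(sm):
        raise IndexError(f"index {i} out of range for array of length {len(sm)}")
    run = int(sm._e_rank[i])
    if not int(sm._s_rank[i + 1]) > run:
        return []
    return [int(v) for v in sm.x[sm._b_sel[run] : sm._b_sel[run + 1]]]


@dataclass
class MarkerArray:
    """MA[i] = M[SA[i]], stored through the sparse multimap."""

    sparse: SparseMultimap

    def markers_at_rank(self, i: int) -> list[int]:
        return sparse_access(self.sparse, i)

    def __len__(self) -> int:
        return len(self.sparse)


@dataclass
class AugmentedMarkerArray:
    """MA^w[i] = markers of text positions SA[i]..SA[i]+w, offset-ordered."""

    w: int
    sparse: SparseMultimap

    def markers_at_rank(self, i: int) -> list[int]:
        return sparse_access(self.sparse, i)

    def __len__(self) -> int:
        return len(self.sparse)


def build_marker_array(m: DenseMarkerMap, sa: np.ndarray) -> MarkerArray:
    dense: list[list[int] | None] = [None] * len(sa)
    for i, pos in enumerate(sa):
        word = m.get(int(pos))
        if word is not None:
            dense[i] = [word]
    return MarkerArray(sparse_encode(dense))


def _separator_positions(text: ConcatenatedText | str) -> np.ndarray:
    seq = text.sequence if isinstance(text, ConcatenatedText) else text
    return np.flatnonzero(np.frombuffer(seq.encode("ascii"), np.uint8) == ord(SEPARATOR))


def build_augmented_marker_array(
    m: DenseMarkerMap,
    sa: np.ndarray,
    w: int,
    text: ConcatenatedText | str | None = None,
) -> AugmentedMarkerArray:
    """Smear each mark w positions to the left, never across a separator.

    ``text`` supplies separator positions for clipping; without it the whole
    text is treated as one document.
    """
    if w < 0:
        raise ValueError("window size w must be >= 0")
    n = len(sa)
    seps = _separator_positions(text) if text is not None else np.empty(0, np.int64)

    # invert: marker at text offset p is visible from offsets [p-w, p] within p's document
    visible: dict[int, list[int]] = {}
    for p in sorted(m.marks):
        word = m.marks[p]
        j = int(np.searchsorted(seps, p))
        doc_start = int(seps[j - 1]) + 1 if j > 0 else 0
        for q in range(max(p - w, doc_start), p + 1):
            visible.setdefault(q, []).append(word)

    dense: list[list[int] | None] = [None] * n
    for i in range(n):
        entry = visible.get(int(sa[i]))
        if entry:
            dense[i] = entry
    return AugmentedMarkerArray(w, sparse_encode(dense))


def fl_marker_query(
    index: FMIndexBundle, m: DenseMarkerMap, q: str
) -> set[tuple[int, int]]:
    """Every (text offset, marker) overlapped by any occurrence of ``q``.

    Walks |q|-1 FL steps from each row of q's SA range, consulting M at each
    visited rank.  Fully sensitive; used as the correctness oracle for the
    heuristic scanner.
    """
    occ, rng = count_occurrences(index, q)
    found: set[tuple[int, int]] = set()
    if occ == 0:
        return found
    for row in rng.rows():
        r = row
        for step in range(len(q)):
            off = int(index.sa[r])
            word = m.get(off)
            if word is not None:
                found.add((off, word))
            if step < len(q) - 1:
                r = fl_step(index, r)
    return found
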