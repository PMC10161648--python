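"""BWT/FM-index core: suffix array, backward search, LF and FL steps.

The index is built over the concatenated panel text (documents terminated by
a separator that sorts below all DNA symbols).  Construction uses
Manber-Myers prefix doubling on numpy arrays, which is exact and comfortably
fast at the scales this package targets; tests arbitrate against a naive
suffix sort.  Rank support is a plain per-symbol cumulative-count matrix and
select support a per-symbol position list — the contract here is query
semantics, not succinctness.  The full suffix array is retained as the
locate oracle that the marker-array query path is designed to make
unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def build_suffix_array(text: str) -> np.ndarray:
    """Exact suffix array by prefix doubling (O(n log^2 n) via lexsort)."""
    if not text:
        raise ValueError("cannot build a suffix array over empty text")
    a = np.frombuffer(text.encode("ascii"), dtype=np.uint8).astype(np.int64)
    n = a.size
    rank = np.unique(a, return_inverse=True)[1].astype(np.int64)
    k = 1
    sa = np.argsort(rank, kind="stable")
    while k < n:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1, r2 = rank[sa], key2[sa]
        new = np.empty(n, dtype=np.int64)
        new[0] = 0
        new[1:] = np.cumsum((r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1]))
        rank = np.empty(n, dtype=np.int64)
        rank[sa] = new
        if new[-1] == n - 1:
            break
        k *= 2
    return sa


@dataclass(frozen=True)
class SARange:
    """Inclusive range [lo, hi] of suffix-array rows; empty when lo > hi."""

    lo: int
    hi: int

    @property
    def empty(self) -> bool:
        return self.lo > self.hi

    def __len__(self) -> int:
        return 0 if self.empty else self.hi - self.lo + 1

    def rows(self) -> range:
        return range(self.lo, self.hi + 1)


EMPTY_RANGE = SARange(0, -1)


class FMIndexBundle:
    """Text, suffix array, BWT and rank/select support over one alphabet.

    ``occ[i, s]`` counts occurrences of symbol ``s`` in ``bwt[:i]``;
    ``c_counts[s]`` counts text symbols strictly smaller than ``s``.
    """

    def __init__(self, text: str, sa: np.ndarray, n_docs: int = 1):
        n = len(text)
        if sa.shape != (n,):
            raise ValueError("suffix array length does not match text")
        self.text = text
        self.sa = np.ascontiguousarray(sa, dtype=np.int64)
        self.n_docs = n_docs

        tbytes = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
        self.alphabet = [chr(b) for b in np.unique(tbytes)]
        self._sym_id = {c: i for i, c in enumerate(self.alphabet)}
        sigma = len(self.alphabet)

        code = np.zeros(256, dtype=np.int64)
        for c, i in self._sym_id.items():
            code[ord(c)] = i
        tcode = code[tbytes]

        bwt_code = tcode[(self.sa - 1) % n]
        self.bwt = "".join(self.alphabet[i] for i in bwt_code)
        self._bwt_code = bwt_code

        counts = np.bincount(tcode, minlength=sigma)
        self.c_counts = np.concatenate(([0], np.cumsum(counts)))[:sigma]

        # rank: cumulative counts; select: per-symbol occurrence positions
        onehot = np.zeros((n + 1, sigma), dtype=np.int64)
        onehot[np.arange(1, n + 1), bwt_code] = 1
        self._occ = np.cumsum(onehot, axis=0)
        self._positions = [np.flatnonzero(bwt_code == s) for s in range(sigma)]

        # F column symbol per row, recoverable from c_counts
        self._f_code = np.searchsorted(self.c_counts, np.arange(n), side="right") - 1

        run_break = np.flatnonzero(bwt_code[1:] != bwt_code[:-1]) + 1
        self.run_starts = np.concatenate(([0], run_break))

    @property
    def n(self) -> int:
        return len(self.text)

    @property
    def n_runs(self) -> int:
        """The BWT run count r."""
        return len(self.run_starts)

    def full_range(self) -> SARange:
        return SARange(0, self.n - 1)

    def rank(self, symbol: str, i: int) -> int:
        """Occurrences of ``symbol`` in bwt[0:i]."""
        return int(self._occ[i, self._sym_id[symbol]])

    def select(self, symbol: str, i: int) -> int:
        """Offset of the (i+1)-th occurrence of ``symbol`` in the BWT."""
        return int(self._positions[self._sym_id[symbol]][i])


def build_fm_index(text: str, sa: np.ndarray, n_docs: int = 1) -> FMIndexBundle:
    return FMIndexBundle(text, sa, n_docs=n_docs)


def backward_step(index: FMIndexBundle, rng: SARange, c: str) -> SARange:
    """Extend the pattern of ``rng`` leftward by symbol ``c``.

    Returns the maximal row range of suffixes prefixed by c.Q, or an empty
    range — including for symbols absent from the text's alphabet, so reads
    containing e.g. 'N' degrade gracefully rather than raising.
    """
    s = index._sym_id.get(c)
    if s is None or rng.empty:
        return EMPTY_RANGE
    base = int(index.c_counts[s])
    lo = base + int(index._occ[rng.lo, s])
    hi = base + int(index._occ[rng.hi + 1, s]) - 1
    return SARange(lo, hi) if lo <= hi else EMPTY_RANGE


def count_occurrences(index: FMIndexBundle, q: str) -> tuple[int, SARange]:
    """Number of occurrences of ``q`` in the text, with its SA row range."""
    if not q:
        raise ValueError("empty query")
    rng = index.full_range()
    for c in reversed(q):
        rng = backward_step(index, rng, c)
        if rng.empty:
            return 0, EMPTY_RANGE
    return len(rng), rng


def lf_step(index: FMIndexBundle, i: int) -> int:
    """Row of the text position one step left: LF(i) = C[L[i]] + rank_{L[i]}(i)."""
    s = int(index._bwt_code[i])
    return int(index.c_counts[s]) + int(index._occ[i, s])


def fl_step(index: FMIndexBundle, i: int) -> int:
    """Inverse of LF, a rightward text step: select_{F[i]}(i - C[F[i]])."""
    s = int(index._f_code[i])
    return int(index._positions[s][i - int(index.c_counts[s])])
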