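"""Local sequence alignment used for containment dereplication.

A plain Smith-Waterman (match +1, mismatch -1, linear gap -1) with full
traceback, JIT-compiled with numba.  For long sequence pairs the dynamic
programme is restricted to a window of the longer sequence anchored on
shared k-mers, so containment checks stay tractable without changing the
result for genuinely similar pairs (a >=90%-identity containment of a
>=1 kb sequence shares seed k-mers with overwhelming probability).

Identity is defined as matches / alignment columns (gap columns count),
coverage of a sequence as the aligned span on that sequence divided by its
length.  These definitions are part of the package contract: thresholds in
the catalog module are applied to exactly these quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP = -1

# beyond this many DP cells the target is windowed around seed k-mer hits
_MAX_FULL_DP_CELLS = 30_000_000
_SEED_K = 12
_WINDOW_PAD = 200

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_IUPAC = set("ACGTRYSWKMBDHVN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, name: str = "sequence") -> None:
    bad = set(seq.upper()) - _IUPAC
    if bad:
        raise ValueError(
            f"{name} contains non-IUPAC characters: {sorted(bad)!r}")


def _encode(seq: str) -> np.ndarray:
    # non-ACGT (ambiguity codes) encode to 4 and can never match
    table = np.full(256, 4, dtype=np.uint8)
    for i, base in enumerate("ACGT"):
        table[ord(base)] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=True)
def _sw_fill(a, b, match, mismatch, gap):  # pragma: no cover - compiled
    n = a.shape[0]
    m = b.shape[0]
    prev = np.zeros(m + 1, dtype=np.int32)
    curr = np.zeros(m + 1, dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 up, 3 left
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        curr[0] = 0
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai != 4) else mismatch
            h = prev[j - 1] + s
            p = 1
            up = prev[j] + gap
            if up > h:
                h = up
                p = 2
            left = curr[j - 1] + gap
            if left > h:
                h = left
                p = 3
            if h <= 0:
                h = 0
                p = 0
            curr[j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
        prev, curr = curr, prev
    return ptr, best, bi, bj


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    matches: int
    columns: int
    a_start: int
    a_end: int  # exclusive
    b_start: int
    b_end: int  # exclusive

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    def coverage_of(self, length: int, which: str) -> float:
        span = (self.a_end - self.a_start) if which == "a" else (self.b_end - self.b_start)
        return span / length if length else 0.0


def _traceback(ptr: np.ndarray, a: np.ndarray, b: np.ndarray,
               bi: int, bj: int, score: int) -> LocalAlignment:
    i, j = bi, bj
    matches = 0
    columns = 0
    while i > 0 and j > 0:
        p = ptr[i, j]
        if p == 0:
            break
        columns += 1
        if p == 1:
            if a[i - 1] == b[j - 1] and a[i - 1] != 4:
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return LocalAlignment(score=score, matches=matches, columns=columns,
                          a_start=i, a_end=bi, b_start=j, b_end=bj)


def smith_waterman(a: str, b: str) -> LocalAlignment:
    """Best local alignment of ``a`` against ``b`` (forward strands)."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    ea, eb = _encode(a.upper()), _encode(b.upper())
    ptr, best, bi, bj = _sw_fill(ea, eb, MATCH, MISMATCH, GAP)
    if best == 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0)
    return _traceback(ptr, ea, eb, bi, bj, best)


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        pos.setdefault(seq[i:i + k], []).append(i)
    return pos


def _seed_window(query: str, target: str, k: int = _SEED_K,
                 pad: int = _WINDOW_PAD) -> tuple[int, int] | None:
    """Target window covering all diagonals with seed k-mer matches."""
    tpos = _kmer_positions(target, k)
    lo, hi = None, None
    for i in range(len(query) - k + 1):
        hits = tpos.get(query[i:i + k])
        if not hits:
            continue
        for j in hits:
            d = j - i
            lo = d if lo is None or d < lo else lo
            hi = d if hi is None or d > hi else hi
    if lo is None:
        return None
    start = max(0, lo - pad)
    end = min(len(target), hi + len(query) + pad)
    return start, end


def align_containment(query: str, target: str) -> LocalAlignment | None:
    """Local alignment of the shorter ``query`` within ``target``.

    Windows the target around shared seed k-mers when the full dynamic
    programme would be too large; coordinates are reported on the original
    sequences.  Returns None when no seed k-mer is shared (the pair cannot
    reach containment-level similarity).
    """
    if len(query) * len(target) <= _MAX_FULL_DP_CELLS:
        aln = smith_waterman(query, target)
        return aln if aln.columns else None
    window = _seed_window(query, target)
    if window is None:
        return None
    start, end = window
    aln = smith_waterman(query, target[start:end])
    if not aln.columns:
        return None
    return LocalAlignment(aln.score, aln.matches, aln.columns,
                          aln.a_start, aln.a_end,
                          aln.b_start + start, aln.b_end + start)
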