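"""Low-level DNA utilities shared across the pipeline.

Sequences are plain uppercase Python strings over {A,C,G,T,N}. For numeric
work they are encoded as int8 arrays with A,C,G,T -> 0..3 and anything else
(N) -> -1; any comparison column involving a -1 counts as a mismatch.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

VALID_CHARS = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_arr(seq: str) -> np.ndarray:
    """Encode to int8 (A=0..T=3, N/other=-1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def arr_to_seq(arr: np.ndarray) -> str:
    out = np.where(arr >= 0, _DECODE[np.clip(arr, 0, 3)], ord("N"))
    return out.astype(np.uint8).tobytes().decode("ascii")


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Mismatch count between equal-length encoded arrays; N never matches."""
    if a.shape != b.shape:
        raise ValueError("hamming requires equal lengths")
    return int(((a != b) | (a < 0) | (b < 0)).sum())


def hamming_str(a: str, b: str) -> int:
    return hamming(seq_to_arr(a), seq_to_arr(b))


def count_overlapping(seq: str, motif: str) -> int:
    """Occurrences of motif in seq, overlaps allowed."""
    n, start = 0, 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def sliding_mismatches(target: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Mismatch count of query against every window of target (vectorized)."""
    m = query.size
    if target.size < m:
        return np.zeros(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(target, m)
    return ((win != query) | (win < 0) | (query < 0)).sum(axis=1)


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer codes (base-4) and validity mask (no N in window)."""
    n = arr.size - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    a64 = arr.astype(np.int64)
    for j in range(k):
        col = a64[j : j + n]
        codes = codes * 4 + np.clip(col, 0, 3)
        valid &= col >= 0
    return codes, valid


class KmerIndex:
    """Exact k-mer -> (target, position) lookup over forward strands.

    Postings are stored as code-sorted parallel arrays and queried by binary
    search, which keeps construction vectorized and lookups O(log n).
    """

    def __init__(self, targets: dict[str, str], k: int):
        if not targets:
            raise ValueError("k-mer index requires at least one target")
        self.k = k
        self.target_ids = list(targets)
        self.target_lengths = {tid: len(s) for tid, s in targets.items()}
        self.total_length = sum(self.target_lengths.values())
        self.target_arrays = {tid: seq_to_arr(s) for tid, s in targets.items()}
        code_parts, tid_parts, pos_parts = [], [], []
        for ti, (tid, seq) in enumerate(targets.items()):
            codes, valid = _kmer_codes(seq_to_arr(seq), k)
            pos = np.nonzero(valid)[0]
            code_parts.append(codes[pos])
            tid_parts.append(np.full(pos.size, ti, dtype=np.int32))
            pos_parts.append(pos.astype(np.int64))
        codes = np.concatenate(code_parts) if code_parts else np.zeros(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._tid = np.concatenate(tid_parts)[order] if tid_parts else np.zeros(0, np.int32)
        self._pos = np.concatenate(pos_parts)[order] if pos_parts else np.zeros(0, np.int64)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """All (target_id, start) postings for an exact k-mer; N-containing -> []."""
        if len(kmer) != self.k:
            raise ValueError(f"expected {self.k}-mer, got {len(kmer)} bases")
        arr = seq_to_arr(kmer)
        if (arr < 0).any():
            return []
        code = 0
        for v in arr:
            code = code * 4 + int(v)
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return [
            (self.target_ids[self._tid[i]], int(self._pos[i])) for i in range(lo, hi)
        ]
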