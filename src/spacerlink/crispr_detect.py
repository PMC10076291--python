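"""CRISPR array detection and spacer excision.

A CRISPR array is a run of near-identical direct repeats (21-48 bp by
default) separated by variable spacers (15-70 bp). Detection is a CRT-style
periodic-seed finder: exact seed k-mers recurring at array-like periods are
chained, each occurrence is extended column-by-column while the per-column
majority agreement across occurrences stays at or above 1 - 0.2, the
inter-repeat gaps become spacers, and candidates failing repeat/spacer
length bounds, consensus distance, or the tandem-repeat guard (any spacer
pair more than 60% identical) are rejected. Pre-annotated arrays can instead
be loaded from GFF3 (repeat_region / direct_repeat / spacer profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np

from ._dna import _kmer_codes, hamming_str, seq_to_arr
from .io_formats import GffFormatError, Scaffold, parse_gff3

FLANK_LEN = 200


class CoordinateError(ValueError):
    """A GFF3 feature lies outside its scaffold."""


@dataclass
class DetectParams:
    repeat_len: tuple[int, int] = (21, 48)
    spacer_len: tuple[int, int] = (15, 70)
    min_spacers: int = 2
    max_repeat_mismatch_frac: float = 0.2
    max_spacer_pair_identity: float = 0.6
    seed_k: int = 11

    def __post_init__(self) -> None:
        if self.repeat_len[0] > self.repeat_len[1] or self.spacer_len[0] > self.spacer_len[1]:
            raise ValueError("length ranges must be non-empty")
        if not 0.0 <= self.max_repeat_mismatch_frac <= 1.0:
            raise ValueError("max_repeat_mismatch_frac must be in [0,1]")
        if not 0.0 <= self.max_spacer_pair_identity <= 1.0:
            raise ValueError("max_spacer_pair_identity must be in [0,1]")


@dataclass
class CrisprArray:
    """A localized repeat-spacer structure: n_repeats == n_spacers + 1."""

    array_id: str
    scaffold_id: str
    interval: tuple[int, int]
    repeats: list[tuple[int, int]]
    consensus_repeat: str
    spacers: list[tuple[int, tuple[int, int], str]]  # (index, interval, seq)
    flank_5p: str = ""
    flank_3p: str = ""
    partial: bool = False

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    def validate(
        self,
        repeat_seqs: Sequence[str] | None = None,
        max_repeat_mismatch_frac: float = 0.2,
    ) -> None:
        """Structural invariants; with repeat_seqs also the consensus-distance rule."""
        if len(self.repeats) != len(self.spacers) + 1:
            raise ValueError(
                f"{self.array_id}: n_repeats ({len(self.repeats)}) != "
                f"n_spacers + 1 ({len(self.spacers) + 1})"
            )
        if len(self.spacers) < 2:
            raise ValueError(f"{self.array_id}: fewer than 2 spacers")
        intervals = []
        for i, rep in enumerate(self.repeats):
            intervals.append(rep)
            if i < len(self.spacers):
                intervals.append(self.spacers[i][1])
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(f"{self.array_id}: features not alternating/sorted")
        if repeat_seqs is not None:
            for r in repeat_seqs:
                if seq_identity(r, self.consensus_repeat) < 1.0 - max_repeat_mismatch_frac:
                    raise ValueError(
                        f"{self.array_id}: repeat {r!r} too far from consensus"
                    )


def seq_identity(a: str, b: str) -> float:
    """Global pairwise identity: 1 - edit_distance / max(len)."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def consensus_sequence(seqs: Sequence[str]) -> str:
    """Per-column majority base over equal-length sequences (ties: A<C<G<N<T)."""
    if not seqs:
        return ""
    L = len(seqs[0])
    cols = []
    for j in range(L):
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s[j]] = counts.get(s[j], 0) + 1
        cols.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(cols)


def _column_agreement(seq: str, positions: list[int]) -> float:
    """Fraction of occurrences agreeing with the majority base at a column set."""
    bases = [seq[p] for p in positions]
    best = max(bases.count(b) for b in set(bases))
    return best / len(bases)


def detect_arrays(scaffold: Scaffold, params: DetectParams | None = None) -> list[CrisprArray]:
    params = params or DetectParams()
    seq = scaffold.seq
    n = len(seq)
    k = params.seed_k
    rep_min, rep_max = params.repeat_len
    sp_min, sp_max = params.spacer_len
    period_min = rep_min + sp_min
    period_max = rep_max + sp_max
    if n < 3 * rep_min + 2 * sp_min:
        return []

    codes, valid = _kmer_codes(seq_to_arr(seq), k)
    posmap: dict[int, list[int]] = {}
    for p in np.nonzero(valid)[0]:
        posmap.setdefault(int(codes[p]), []).append(int(p))

    raw_candidates: dict[tuple, CrisprArray] = {}
    for positions in posmap.values():
        if len(positions) < 3:
            continue
        i = 0
        while i < len(positions):
            chain = [positions[i]]
            j = i
            while True:
                nxt = None
                for jj in range(j + 1, len(positions)):
                    d = positions[jj] - chain[-1]
                    if d < period_min:
                        continue
                    if d > period_max:
                        break
                    nxt, j = positions[jj], jj
                    break
                if nxt is None:
                    break
                chain.append(nxt)
            i = j + 1 if len(chain) > 1 else i + 1
            if len(chain) < 3:
                continue
            arr = _extend_chain(seq, chain, k, params)
            if arr is not None:
                raw_candidates.setdefault(tuple(arr.repeats), arr)

    # maximal non-overlapping selection: largest span first (so fragment
    # chains of the same array never shadow it), leftmost on ties
    chosen: list[CrisprArray] = []
    for arr in sorted(
        raw_candidates.values(),
        key=lambda a: (-(a.interval[1] - a.interval[0]), -len(a.repeats), a.interval[0]),
    ):
        if all(
            arr.interval[1] <= c.interval[0] or arr.interval[0] >= c.interval[1]
            for c in chosen
        ):
            chosen.append(arr)
    chosen.sort(key=lambda a: a.interval[0])
    out = []
    for idx, arr in enumerate(chosen):
        final = _finalize(seq, scaffold.id, f"{scaffold.id}_array_{idx}", arr.repeats)
        out.append(final)
    return out


def _extend_chain(
    seq: str, chain: list[int], k: int, params: DetectParams
) -> CrisprArray | None:
    """Grow seed occurrences into repeats; None when validation fails."""
    n = len(seq)
    rep_min, rep_max = params.repeat_len
    sp_min, sp_max = params.spacer_len
    min_gap = min(b - a for a, b in zip(chain, chain[1:]))
    max_rep_len = min(rep_max, min_gap - 1)
    agree_min = 1.0 - params.max_repeat_mismatch_frac

    left = 0
    while k + left < max_rep_len and chain[0] - left - 1 >= 0:
        cols = [p - left - 1 for p in chain]
        if _column_agreement(seq, cols) < agree_min:
            break
        left += 1
    right = 0
    while k + left + right < max_rep_len and chain[-1] + k + right < n:
        cols = [p + k + right for p in chain]
        if _column_agreement(seq, cols) < agree_min:
            break
        right += 1

    rep_len = k + left + right
    if not rep_min <= rep_len <= rep_max:
        return None
    repeats = [(p - left, p - left + rep_len) for p in chain]
    rep_seqs = [seq[s:e] for s, e in repeats]
    consensus = consensus_sequence(rep_seqs)
    max_mm = params.max_repeat_mismatch_frac * rep_len
    if any(hamming_str(r, consensus) > max_mm for r in rep_seqs):
        return None
    spacer_seqs = []
    for (s1, e1), (s2, _e2) in zip(repeats, repeats[1:]):
        if not sp_min <= s2 - e1 <= sp_max:
            return None
        spacer_seqs.append(seq[e1:s2])
    # tandem-repeat guard: tandem arrays have (near-)identical adjacent
    # "spacers"; adjacent pairs keep the check O(n) for very long arrays
    for a, b in zip(spacer_seqs, spacer_seqs[1:]):
        if seq_identity(a, b) > params.max_spacer_pair_identity:
            return None
    if len(spacer_seqs) < params.min_spacers:
        return None
    return _finalize(seq, "", "", repeats)


def _finalize(seq: str, scaffold_id: str, array_id: str, repeats: list[tuple[int, int]]) -> CrisprArray:
    start, end = repeats[0][0], repeats[-1][1]
    spacers = [
        (i, (e1, s2), seq[e1:s2])
        for i, ((_s1, e1), (s2, _e2)) in enumerate(zip(repeats, repeats[1:]))
    ]
    rep_seqs = [seq[s:e] for s, e in repeats]
    return CrisprArray(
        array_id=array_id,
        scaffold_id=scaffold_id,
        interval=(start, end),
        repeats=list(repeats),
        consensus_repeat=consensus_sequence(rep_seqs),
        spacers=spacers,
        flank_5p=seq[max(0, start - FLANK_LEN) : start],
        flank_3p=seq[end : end + FLANK_LEN],
        partial=(start == 0 or end == len(seq)),
    )


def excise_spacers(array: CrisprArray, host_id: str) -> list:
    """One Spacer per spacer interval, 5'->3', ids ``{array_id}:{index}``."""
    from .spacer_match import Spacer

    return [
        Spacer(
            spacer_id=f"{array.array_id}:{idx}",
            owner_id=host_id,
            scaffold_id=array.scaffold_id,
            array_id=array.array_id,
            index_in_array=idx,
            seq=seq,
        )
        for idx, _interval, seq in array.spacers
    ]


def load_arrays_gff(
    path: str | Path, scaffolds: Iterable[Scaffold]
) -> list[CrisprArray]:
    """Build arrays from GFF3 annotation, slicing sequences from scaffolds."""
    seq_by_id = {sc.id: sc.seq for sc in scaffolds}
    records = parse_gff3(path)
    parents: dict[str, dict] = {}
    for rec in records:
        if rec.type == "repeat_region":
            aid = rec.attributes.get("ID")
            if aid is None:
                raise GffFormatError(f"{path}: repeat_region without ID")
            parents[aid] = {"rec": rec, "repeats": [], "spacers": []}
    for rec in records:
        if rec.type in ("direct_repeat", "spacer"):
            parent = rec.attributes.get("Parent")
            if parent not in parents:
                raise GffFormatError(f"{path}: {rec.type} with unknown Parent {parent!r}")
            key = "repeats" if rec.type == "direct_repeat" else "spacers"
            parents[parent][key].append(rec)

    arrays = []
    for aid, group in parents.items():
        seqid = group["rec"].seqid
        if seqid not in seq_by_id:
            raise GffFormatError(f"{path}: array {aid} references unknown scaffold {seqid!r}")
        seq = seq_by_id[seqid]
        for rec in [group["rec"], *group["repeats"], *group["spacers"]]:
            if rec.start < 0 or rec.end > len(seq) or rec.start >= rec.end:
                raise CoordinateError(
                    f"{path}: feature {rec.type} [{rec.start},{rec.end}) outside "
                    f"scaffold {seqid} (length {len(seq)})"
                )
        repeats = sorted((r.start, r.end) for r in group["repeats"])
        spacer_ivs = sorted((s.start, s.end) for s in group["spacers"])
        if len(repeats) != len(spacer_ivs) + 1:
            raise GffFormatError(
                f"{path}: array {aid} has {len(repeats)} repeats but "
                f"{len(spacer_ivs)} spacers (expected n_repeats = n_spacers + 1)"
            )
        for i, (ss, se) in enumerate(spacer_ivs):
            if not (repeats[i][1] <= ss and se <= repeats[i + 1][0]):
                raise GffFormatError(f"{path}: array {aid} features not alternating")
        arr = _finalize(seq, seqid, aid, repeats)
        if group["rec"].attributes.get("partial") == "true":
            arr.partial = True
        arr.validate(repeat_seqs=[seq[s:e] for s, e in repeats])
        arrays.append(arr)
    arrays.sort(key=lambda a: (a.scaffold_id, a.interval[0]))
    return arrays
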