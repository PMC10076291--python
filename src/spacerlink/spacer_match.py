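"""Mismatch-tolerant spacer -> protospacer search.

Retention criteria: at most one mismatch (a substitution; no indels), query
coverage >= 90%, and an ungapped Karlin-Altschul E-value <= 1e-4 computed
with BLASTN-default reward/penalty (+2/-3) and constants lambda = 0.625,
K = 0.41 over the summed target length on both strands. Sub-full coverage is
realized only as contiguous clipping of at most 10% of the query from one
end -- the only alignment shape consistent with >=90% coverage and <=1
substitution at spacer lengths.

The production search exploits the pigeonhole principle: an admissible
aligned core with <=1 substitution contains an exact half, so looking up the
k-mer at the start of each half of the core against an exact k-mer index
finds every candidate, which is then verified by direct Hamming count. A
brute-force sliding-window scan (``brute_match``) provides the independent
oracle and the fallback for spacers too short for the seeded guarantee.

Overlapping admissible alignments at one locus (e.g. a full-length hit and
its clipped sub-alignments) are reduced to the single best-scoring one, so
match counts equal distinct protospacer loci.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._dna import KmerIndex, revcomp, seq_to_arr, sliding_mismatches
from .crispr_detect import CrisprArray


@dataclass
class Spacer:
    spacer_id: str
    owner_id: str
    scaffold_id: str
    array_id: str
    index_in_array: int
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"spacer {self.spacer_id}: empty sequence")
        if self.seq != self.seq.upper():
            raise ValueError(f"spacer {self.spacer_id}: sequence must be uppercase")
        if self.index_in_array < 0:
            raise ValueError(f"spacer {self.spacer_id}: negative index")


@dataclass
class MatchParams:
    max_mismatches: int = 1
    min_query_coverage: float = 0.90
    max_evalue: float = 1e-4
    ka_lambda: float = 0.625
    ka_K: float = 0.41
    reward: int = 2
    penalty: int = -3
    index_k: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.min_query_coverage <= 1.0:
            raise ValueError("min_query_coverage must be in (0,1]")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class ProtospacerMatch:
    spacer_id: str
    owner_id: str
    target_id: str
    start: int  # 0-based half-open on the forward target strand
    end: int
    strand: str  # '+' or '-'
    n_mismatches: int
    query_coverage: float
    score: int
    evalue: float
    in_array: bool = False

    @property
    def match_id(self) -> str:
        return f"{self.spacer_id}|{self.target_id}|{self.start}|{self.end}|{self.strand}"

    def locus(self) -> tuple[str, int, int, str]:
        return (self.target_id, self.start, self.end, self.strand)


def build_target_index(targets: Sequence, k: int = 10) -> KmerIndex:
    """Exact k-mer index over the forward strand of every target scaffold.

    Reverse-strand hits are found by searching the reverse complement of the
    query, so only forward k-mers need to be stored.
    """
    return KmerIndex({t.id: t.seq for t in targets}, k)


def _max_clip(length: int, min_cov: float) -> int:
    return int(math.floor((1.0 - min_cov) * length + 1e-9))


def _alignment_stats(
    core_len: int, n_mm: int, spacer_len: int, total_target_len: int, params: MatchParams
) -> tuple[int, float, float]:
    score = params.reward * (core_len - n_mm) + params.penalty * n_mm
    coverage = core_len / spacer_len
    n_db = 2 * total_target_len  # both strands
    evalue = params.ka_K * spacer_len * n_db * math.exp(-params.ka_lambda * score)
    return score, coverage, evalue


def _clippings(length: int, c_max: int) -> list[tuple[int, int]]:
    """(clip_left, clip_right) shapes: full, then one-end clips of 1..c_max."""
    out = [(0, 0)]
    for c in range(1, c_max + 1):
        out.append((c, 0))
        out.append((0, c))
    return out


def _reduce_loci(hits: list[ProtospacerMatch]) -> list[ProtospacerMatch]:
    """Keep one best alignment per overlapping locus per (spacer, target, strand)."""
    groups: dict[tuple[str, str, str], list[ProtospacerMatch]] = {}
    for h in hits:
        groups.setdefault((h.spacer_id, h.target_id, h.strand), []).append(h)
    reduced = []
    for group in groups.values():
        group.sort(key=lambda h: (h.start, h.end))
        cluster: list[ProtospacerMatch] = []
        cluster_end = -1
        for h in group:
            if cluster and h.start >= cluster_end:
                reduced.append(_best_of(cluster))
                cluster = []
                cluster_end = -1
            cluster.append(h)
            cluster_end = max(cluster_end, h.end)
        if cluster:
            reduced.append(_best_of(cluster))
    reduced.sort(key=lambda h: (h.spacer_id, h.target_id, h.start, h.strand))
    return reduced


def _best_of(cluster: list[ProtospacerMatch]) -> ProtospacerMatch:
    return max(cluster, key=lambda h: (h.score, h.end - h.start, -h.start))


def find_protospacers(
    spacers: Iterable[Spacer], index: KmerIndex, params: MatchParams | None = None
) -> list[ProtospacerMatch]:
    """Seeded pigeonhole search; equivalent to ``brute_match`` as a set."""
    params = params or MatchParams()
    k = index.k
    hits: list[ProtospacerMatch] = []
    for sp in spacers:
        L = len(sp.seq)
        c_max = _max_clip(L, params.min_query_coverage)
        if L - c_max < 2 * k:
            raise ValueError(
                f"spacer {sp.spacer_id} ({L} bp) too short for the seeded search "
                f"(core may fall below {2 * k} bp); use brute_match"
            )
        best: dict[tuple[str, int, int, str], ProtospacerMatch] = {}
        for strand in "+-":
            query = sp.seq if strand == "+" else revcomp(sp.seq)
            q_arr = seq_to_arr(query)
            for cl, cr in _clippings(L, c_max):
                core = q_arr[cl : L - cr]
                m = core.size
                half = m // 2
                evaluated: set[tuple[str, int]] = set()
                for off in (0, half):
                    kmer = query[cl + off : cl + off + k]
                    for tid, pos in index.lookup(kmer):
                        start = pos - off
                        end = start + m
                        if start < 0 or end > index.target_lengths[tid]:
                            continue
                        if (tid, start) in evaluated:
                            continue  # both seeds of this clipping found it
                        evaluated.add((tid, start))
                        t_arr = index.target_arrays[tid]
                        window = t_arr[start:end]
                        n_mm = int(((window != core) | (window < 0) | (core < 0)).sum())
                        if n_mm > params.max_mismatches:
                            continue
                        score, cov, ev = _alignment_stats(
                            m, n_mm, L, index.total_length, params
                        )
                        if cov < params.min_query_coverage or ev > params.max_evalue:
                            continue
                        hit = ProtospacerMatch(
                            spacer_id=sp.spacer_id,
                            owner_id=sp.owner_id,
                            target_id=tid,
                            start=start,
                            end=end,
                            strand=strand,
                            n_mismatches=n_mm,
                            query_coverage=cov,
                            score=score,
                            evalue=ev,
                        )
                        key = (tid, start, end, strand)
                        # same interval reachable from distinct equal-length
                        # clippings: keep the higher score, first clipping on tie
                        if key not in best or hit.score > best[key].score:
                            best[key] = hit
        hits.extend(best.values())
    return _reduce_loci(hits)


def brute_match(
    spacers: Iterable[Spacer], targets: Sequence, params: MatchParams | None = None
) -> list[ProtospacerMatch]:
    """Exhaustive sliding-window Hamming oracle with identical retention rules."""
    params = params or MatchParams()
    target_seqs = {t.id: t.seq for t in targets}
    target_arrs = {tid: seq_to_arr(s) for tid, s in target_seqs.items()}
    total_len = sum(len(s) for s in target_seqs.values())
    hits: list[ProtospacerMatch] = []
    for sp in spacers:
        L = len(sp.seq)
        c_max = _max_clip(L, params.min_query_coverage)
        for strand in "+-":
            query = sp.seq if strand == "+" else revcomp(sp.seq)
            q_arr = seq_to_arr(query)
            for cl, cr in _clippings(L, c_max):
                core = q_arr[cl : L - cr]
                m = core.size
                for tid, t_arr in target_arrs.items():
                    if t_arr.size < m:
                        continue
                    mm = sliding_mismatches(t_arr, core)
                    for start in np.nonzero(mm <= params.max_mismatches)[0]:
                        n_mm = int(mm[start])
                        score, cov, ev = _alignment_stats(m, n_mm, L, total_len, params)
                        if cov < params.min_query_coverage or ev > params.max_evalue:
                            continue
                        hits.append(
                            ProtospacerMatch(
                                spacer_id=sp.spacer_id,
                                owner_id=sp.owner_id,
                                target_id=tid,
                                start=int(start),
                                end=int(start) + m,
                                strand=strand,
                                n_mismatches=n_mm,
                                query_coverage=cov,
                                score=score,
                                evalue=ev,
                            )
                        )
    # same interval reachable from distinct equal-length clippings: keep the
    # higher score, first clipping on tie (mirrors find_protospacers)
    uniq: dict[tuple, ProtospacerMatch] = {}
    for h in hits:
        key = (h.spacer_id,) + h.locus()
        if key not in uniq or h.score > uniq[key].score:
            uniq[key] = h
    return _reduce_loci(list(uniq.values()))


def flag_in_array(
    matches: Iterable[ProtospacerMatch], target_arrays: Iterable[CrisprArray]
) -> list[ProtospacerMatch]:
    """Set in_array=True where >=50% of the match interval overlaps array features.

    Array features are the repeat and spacer intervals of CRISPR arrays
    detected on the *target* scaffold. Such hits are spacer-spacer matches
    with no adjacent PAM and confer no immunity.
    """
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for arr in target_arrays:
        ivs = by_scaffold.setdefault(arr.scaffold_id, [])
        ivs.extend(arr.repeats)
        ivs.extend(iv for _i, iv, _s in arr.spacers)
    out = []
    for m in matches:
        overlap = 0
        for s, e in by_scaffold.get(m.target_id, ()):
            overlap += max(0, min(e, m.end) - max(s, m.start))
        m.in_array = overlap >= 0.5 * (m.end - m.start)
        out.append(m)
    return out


_MATCH_COLUMNS = (
    "spacer_id", "owner", "target", "start", "end", "strand",
    "mismatches", "coverage", "evalue", "in_array",
)


def write_matches(matches: Iterable[ProtospacerMatch], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MATCH_COLUMNS)
        for m in matches:
            w.writerow(
                [m.spacer_id, m.owner_id, m.target_id, m.start, m.end, m.strand,
                 m.n_mismatches, f"{m.query_coverage:.4f}", f"{m.evalue:.6g}",
                 int(m.in_array)]
            )


def read_matches(path: str | Path) -> list[ProtospacerMatch]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                ProtospacerMatch(
                    spacer_id=row["spacer_id"],
                    owner_id=row["owner"],
                    target_id=row["target"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    n_mismatches=int(row["mismatches"]),
                    query_coverage=float(row["coverage"]),
                    score=0,
                    evalue=float(row["evalue"]),
                    in_array=bool(int(row["in_array"])),
                )
            )
    return out
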