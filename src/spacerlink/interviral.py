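"""Virally-encoded CRISPR arrays, interviral conflicts, and provirus calls.

A viral element that encodes its own CRISPR array can target other viruses
(an interviral conflict). A conflict is *genuine* only when at least one
supporting spacer->protospacer match lands outside the target's own arrays:
spacer-spacer matches between two arrays carry no adjacent PAM and are not
cleavable, so they are flagged non-genuine.

Proviruses are found by locally aligning CRISPR-encoding viral elements
against host-bin scaffolds. Retention follows the conventional thresholds:
bit score >= 50, E-value <= 1e-3, alignment >= 2500 bp, average nucleotide
identity over the alignment >= 70% (gap columns count as non-matches). When
the alignment covers >= 90% of the host scaffold the viral sequence is
classified as co-binned (a free viral scaffold binned with the host) rather
than integrated.

The aligner anchors exact 16-mers, keeps the densest co-linear diagonal
cluster, and runs a banded affine Smith-Waterman (match +1, mismatch -2,
gap open -5, gap extend -2; a length-g gap costs 5 + 2g) over the band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from ._dna import seq_to_arr, revcomp
from ._stats import mean, percent
from .crispr_detect import CrisprArray, DetectParams, detect_arrays, excise_spacers
from .io_formats import Scaffold
from .spacer_match import (
    MatchParams,
    ProtospacerMatch,
    Spacer,
    find_protospacers,
    flag_in_array,
)


@dataclass
class AlignScoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    anchor_k: int = 16
    band_pad: int = 32
    ka_lambda: float = 0.625
    ka_K: float = 0.41


@dataclass
class ProvirusParams:
    min_bitscore: float = 50.0
    max_evalue: float = 1e-3
    min_aln_len: int = 2500
    min_identity: float = 0.70
    cobin_fraction: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0 or not 0.0 < self.cobin_fraction <= 1.0:
            raise ValueError("fractions must be in (0,1]")


@dataclass
class LocalAlignment:
    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    score: int
    bitscore: float
    evalue: float
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        """Matches over alignment columns, gaps counted as non-matches."""
        return self.matches / self.columns if self.columns else 0.0

    @property
    def aligned_len(self) -> int:
        return self.columns


@dataclass
class ProvirusCall:
    viral_id: str
    host_mag_id: str
    host_scaffold_id: str
    interval: tuple[int, int]  # on the host scaffold, forward coordinates
    identity: float
    aligned_len: int
    cls: str  # "integrated" | "cobinned"


@dataclass
class InterviralConflict:
    source_viral_id: str
    target_viral_id: str
    match_ids: tuple[str, ...]
    genuine: bool
    reason: str


# ---------------------------------------------------------------------------
# banded affine local alignment
# ---------------------------------------------------------------------------


@njit(cache=False)
def _banded_sw(q, t, dlo, dhi, match, mismatch, gap_open_cost, gap_ext_cost):
    """Banded affine Smith-Waterman; diagonals d = j - i restricted to [dlo,dhi].

    Returns (score, q_start, q_end, t_start, t_end, matches, columns) with
    half-open end coordinates. Gap of length g costs gap_open_cost +
    g * gap_ext_cost.
    """
    n = q.size
    m = t.size
    B = dhi - dlo + 1
    NEG = -(10**9)
    H = np.zeros((n + 1, B), dtype=np.int32)
    E = np.full((n + 1, B), NEG, dtype=np.int32)
    F = np.full((n + 1, B), NEG, dtype=np.int32)
    pH = np.zeros((n + 1, B), dtype=np.uint8)
    pE = np.zeros((n + 1, B), dtype=np.uint8)
    pF = np.zeros((n + 1, B), dtype=np.uint8)
    best = 0
    bi = 0
    bb = 0
    for i in range(1, n + 1):
        for b in range(B):
            j = i + dlo + b
            if j < 1 or j > m:
                continue
            a = q[i - 1]
            c = t[j - 1]
            s = match if (a == c and a >= 0) else mismatch
            diag = H[i - 1, b] + s
            ev = NEG
            if b - 1 >= 0:
                e_open = H[i, b - 1] - gap_open_cost - gap_ext_cost
                e_ext = E[i, b - 1] - gap_ext_cost
                if e_open >= e_ext:
                    ev = e_open
                    pE[i, b] = 0
                else:
                    ev = e_ext
                    pE[i, b] = 1
            E[i, b] = ev
            fv = NEG
            if b + 1 < B:
                f_open = H[i - 1, b + 1] - gap_open_cost - gap_ext_cost
                f_ext = F[i - 1, b + 1] - gap_ext_cost
                if f_open >= f_ext:
                    fv = f_open
                    pF[i, b] = 0
                else:
                    fv = f_ext
                    pF[i, b] = 1
            F[i, b] = fv
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if ev > h:
                h = ev
                p = 2
            if fv > h:
                h = fv
                p = 3
            H[i, b] = h
            pH[i, b] = p
            if h > best:
                best = h
                bi = i
                bb = b
    # traceback from the maximum
    i = bi
    b = bb
    matches = 0
    columns = 0
    state = 0
    q_end = bi
    t_end = bi + dlo + bb
    while i > 0:
        if state == 0:
            p = pH[i, b]
            if p == 0:
                break
            if p == 1:
                j = i + dlo + b
                columns += 1
                if q[i - 1] == t[j - 1] and q[i - 1] >= 0:
                    matches += 1
                i -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:  # gap consuming target
            columns += 1
            nxt = pE[i, b]
            b -= 1
            state = 0 if nxt == 0 else 2
        else:  # gap consuming query
            columns += 1
            nxt = pF[i, b]
            i -= 1
            b += 1
            state = 0 if nxt == 0 else 3
    q_start = i
    t_start = i + dlo + b
    return best, q_start, q_end, t_start, t_end, matches, columns


def _collect_anchors(
    q_seq: str, t_seq: str, k: int, max_per_kmer: int = 8, max_anchors: int = 20000
) -> list[tuple[int, int]]:
    from ._dna import _kmer_codes

    t_codes, t_valid = _kmer_codes(seq_to_arr(t_seq), k)
    posmap: dict[int, list[int]] = {}
    for p in np.nonzero(t_valid)[0]:
        lst = posmap.setdefault(int(t_codes[p]), [])
        if len(lst) < max_per_kmer:
            lst.append(int(p))
    q_codes, q_valid = _kmer_codes(seq_to_arr(q_seq), k)
    anchors: list[tuple[int, int]] = []
    for qp in np.nonzero(q_valid)[0]:
        for tp in posmap.get(int(q_codes[qp]), ()):
            anchors.append((int(qp), tp))
            if len(anchors) >= max_anchors:
                return anchors
    return anchors


def _best_diagonal_window(
    anchors: list[tuple[int, int]], width: int
) -> list[tuple[int, int]]:
    """Anchors in the diagonal window of given width holding the most anchors."""
    diags = sorted(((tp - qp, qp, tp) for qp, tp in anchors))
    best_lo, best_hi, best_count = 0, 0, 0
    lo = 0
    for hi in range(len(diags)):
        while diags[hi][0] - diags[lo][0] > width:
            lo += 1
        if hi - lo + 1 > best_count:
            best_lo, best_hi, best_count = lo, hi, hi - lo + 1
    return [(qp, tp) for _d, qp, tp in diags[best_lo : best_hi + 1]]


def align_pair(
    query: str,
    target: str,
    query_id: str = "query",
    target_id: str = "target",
    scoring: AlignScoring | None = None,
    strand: str = "+",
) -> LocalAlignment | None:
    """Best local alignment of query vs the forward strand of target.

    Returns None when no exact anchor k-mer is shared (no alignable region).
    """
    scoring = scoring or AlignScoring()
    anchors = _collect_anchors(query, target, scoring.anchor_k)
    if not anchors:
        return None
    window = _best_diagonal_window(anchors, scoring.band_pad)
    diag_vals = [tp - qp for qp, tp in window]
    dlo = min(diag_vals) - scoring.band_pad
    dhi = max(diag_vals) + scoring.band_pad
    q_arr = seq_to_arr(query)
    t_arr = seq_to_arr(target)
    score, qs, qe, ts, te, matches, columns = _banded_sw(
        q_arr,
        t_arr,
        np.int64(dlo),
        np.int64(dhi),
        np.int64(scoring.match),
        np.int64(scoring.mismatch),
        np.int64(-scoring.gap_open),
        np.int64(-scoring.gap_extend),
    )
    if score <= 0:
        return None
    m, n = len(query), len(target)
    bitscore = (scoring.ka_lambda * score - math.log(scoring.ka_K)) / math.log(2.0)
    evalue = scoring.ka_K * m * n * math.exp(-scoring.ka_lambda * score)
    return LocalAlignment(
        query_id=query_id,
        target_id=target_id,
        q_start=int(qs),
        q_end=int(qe),
        t_start=int(ts),
        t_end=int(te),
        strand=strand,
        score=int(score),
        bitscore=bitscore,
        evalue=evalue,
        matches=int(matches),
        columns=int(columns),
    )


def align_pair_bidirectional(
    query: str,
    target: str,
    query_id: str = "query",
    target_id: str = "target",
    scoring: AlignScoring | None = None,
) -> LocalAlignment | None:
    """Best of forward and reverse-complement query alignments.

    Reverse-strand coordinates are reported on the forward target strand.
    """
    fwd = align_pair(query, target, query_id, target_id, scoring, strand="+")
    rev = align_pair(revcomp(query), target, query_id, target_id, scoring, strand="-")
    if rev is not None:
        L = len(query)
        rev.q_start, rev.q_end = L - rev.q_end, L - rev.q_start
    candidates = [a for a in (fwd, rev) if a is not None]
    if not candidates:
        return None
    return max(candidates, key=lambda a: a.score)


# ---------------------------------------------------------------------------
# virally-encoded arrays and conflicts
# ---------------------------------------------------------------------------


def find_viral_arrays(
    virals: Sequence[Scaffold], detect_params: DetectParams | None = None
) -> tuple[dict[str, list[CrisprArray]], dict]:
    """Detect CRISPR arrays on (unclustered) viral scaffolds plus a summary.

    The summary reports how many viral elements encode arrays, the fraction
    of the set (printed to 2 decimals as a percentage), spacer-count
    min/max/mean, and the number of arrays with more than 10 spacers.
    """
    detect_params = detect_params or DetectParams()
    arrays_by_virus: dict[str, list[CrisprArray]] = {}
    for sc in virals:
        arrs = detect_arrays(sc, detect_params)
        if arrs:
            arrays_by_virus[sc.id] = arrs
    counts = [a.n_spacers for arrs in arrays_by_virus.values() for a in arrs]
    summary = {
        "n_viral_elements": len(virals),
        "n_with_arrays": len(arrays_by_virus),
        "pct_with_arrays": percent(len(arrays_by_virus), len(virals), ndigits=2),
        "n_arrays": len(counts),
        "spacers_min": min(counts) if counts else 0,
        "spacers_max": max(counts) if counts else 0,
        "spacers_mean": mean(counts) if counts else 0.0,
        "arrays_gt10_spacers": sum(1 for c in counts if c > 10),
    }
    return arrays_by_virus, summary


def find_conflicts(
    viral_spacers: Sequence[Spacer],
    viral_index,
    viral_arrays: Iterable[CrisprArray],
    match_params: MatchParams | None = None,
) -> list[InterviralConflict]:
    """Spacer search of virus-encoded spacers against all viral scaffolds.

    Self-hits (source == target) are dropped. Conflicts are grouped by
    (source, target); genuine requires >= 1 match outside the target's arrays.
    """
    match_params = match_params or MatchParams()
    matches = find_protospacers(viral_spacers, viral_index, match_params)
    matches = flag_in_array(matches, viral_arrays)
    grouped: dict[tuple[str, str], list[ProtospacerMatch]] = {}
    for mt in matches:
        if mt.owner_id == mt.target_id:
            continue
        grouped.setdefault((mt.owner_id, mt.target_id), []).append(mt)
    conflicts = []
    for (src, tgt), ms in sorted(grouped.items()):
        genuine = any(not m.in_array for m in ms)
        reason = (
            "protospacer match outside the target's CRISPR arrays"
            if genuine
            else "all supporting matches are spacer-spacer (inside target arrays)"
        )
        conflicts.append(
            InterviralConflict(
                source_viral_id=src,
                target_viral_id=tgt,
                match_ids=tuple(m.match_id for m in ms),
                genuine=genuine,
                reason=reason,
            )
        )
    return conflicts


# ---------------------------------------------------------------------------
# provirus calling and superinfection exclusion
# ---------------------------------------------------------------------------


def align_viral_to_bins(
    virals: Sequence[Scaffold],
    host_scaffolds: Sequence[Scaffold],
    scoring: AlignScoring | None = None,
) -> list[LocalAlignment]:
    """Best local alignment per (viral, host scaffold) pair sharing anchors."""
    scoring = scoring or AlignScoring()
    out = []
    for v in virals:
        for h in host_scaffolds:
            aln = align_pair_bidirectional(v.seq, h.seq, v.id, h.id, scoring)
            if aln is not None:
                out.append(aln)
    return out


def call_proviruses(
    alignments: Iterable[LocalAlignment],
    params: ProvirusParams | None = None,
    host_scaffold_lengths: Mapping[str, int] | None = None,
    scaffold_to_mag: Mapping[str, str] | None = None,
) -> list[ProvirusCall]:
    """Threshold alignments and classify integrated vs co-binned."""
    params = params or ProvirusParams()
    host_scaffold_lengths = host_scaffold_lengths or {}
    scaffold_to_mag = scaffold_to_mag or {}
    calls = []
    for a in alignments:
        if (
            a.bitscore < params.min_bitscore
            or a.evalue > params.max_evalue
            or a.aligned_len < params.min_aln_len
            or a.identity < params.min_identity
        ):
            continue
        host_len = host_scaffold_lengths.get(a.target_id)
        frac = (a.t_end - a.t_start) / host_len if host_len else 0.0
        cls = "cobinned" if frac >= params.cobin_fraction else "integrated"
        calls.append(
            ProvirusCall(
                viral_id=a.query_id,
                host_mag_id=scaffold_to_mag.get(a.target_id, ""),
                host_scaffold_id=a.target_id,
                interval=(a.t_start, a.t_end),
                identity=a.identity,
                aligned_len=a.aligned_len,
                cls=cls,
            )
        )
    return calls


def write_provirus_gff(calls: Sequence[ProvirusCall], path) -> None:
    """Provirus intervals as GFF3 features on their host scaffolds."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls):
            s, e = c.interval
            fh.write(
                f"{c.host_scaffold_id}\tspacerlink\tprovirus\t{s + 1}\t{e}\t.\t+\t.\t"
                f"ID=provirus_{i};viral_id={c.viral_id};class={c.cls};"
                f"identity={c.identity:.4f}\n"
            )


@dataclass
class SuperinfectionRecord:
    host_mag_id: str
    viral_id: str
    # match_id -> "provirus-encoded" | "host-native"
    attributions: dict[str, str] = field(default_factory=dict)
    non_immunizing: bool = False  # supported only by spacer-spacer matches


def superinfection_report(
    proviruses: Sequence[ProvirusCall],
    host_arrays: Sequence[CrisprArray],
    matches: Sequence[ProtospacerMatch],
    scaffold_to_mag: Mapping[str, str],
) -> list[SuperinfectionRecord]:
    """Attribute each host->virus match to a provirus-encoded or native array.

    A host array is provirus-encoded when >= 50% of its span lies inside a
    called provirus interval on the same host scaffold. Pairs supported only
    by in_array (spacer-spacer) matches are flagged non-immunizing: without
    an adjacent PAM those loci are not cleavable.
    """
    provirus_ivs: dict[str, list[tuple[int, int]]] = {}
    for pv in proviruses:
        if pv.cls == "integrated":
            provirus_ivs.setdefault(pv.host_scaffold_id, []).append(pv.interval)
    array_class: dict[str, str] = {}
    for arr in host_arrays:
        s, e = arr.interval
        inside = sum(
            max(0, min(e, pe) - max(s, ps))
            for ps, pe in provirus_ivs.get(arr.scaffold_id, ())
        )
        array_class[arr.array_id] = (
            "provirus-encoded" if inside >= 0.5 * (e - s) else "host-native"
        )
    records: dict[tuple[str, str], SuperinfectionRecord] = {}
    for m in matches:
        array_id = m.spacer_id.rsplit(":", 1)[0]
        host = scaffold_to_mag.get(m.owner_id, m.owner_id)
        key = (host, m.target_id)
        rec = records.setdefault(
            key, SuperinfectionRecord(host_mag_id=host, viral_id=m.target_id)
        )
        rec.attributions[m.match_id] = array_class.get(array_id, "host-native")
    # flag pairs supported only by spacer-spacer matches
    by_key_in_array: dict[tuple[str, str], list[bool]] = {}
    for m in matches:
        host = scaffold_to_mag.get(m.owner_id, m.owner_id)
        by_key_in_array.setdefault((host, m.target_id), []).append(m.in_array)
    out = []
    for key, rec in sorted(records.items()):
        rec.non_immunizing = all(by_key_in_array[key])
        out.append(rec)
    return out
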