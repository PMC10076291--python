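"""Synthetic landfill-like community generator with a ground-truth manifest.

The generator emits host MAGs carrying repeat-spacer CRISPR arrays, viral
scaffolds carrying planted protospacers (with a controlled number of
substitutions each), virally-encoded arrays (optionally sharing spacers with
other viral arrays), integrated or co-binned proviruses, and controllable
Chi-motif counts. Everything planted is recorded in a TruthManifest so every
downstream detector has an exact recovery test.

Design guarantees (what makes recovery tests exact rather than statistical):

* Background sequence is i.i.d. at the configured GC; planted spacers are
  drawn with a pairwise Hamming separation large enough that the <=1-mismatch
  neighborhoods of distinct spacers stay disjoint even after boundary
  adjustments, and a final verification pass searches every planted spacer
  against the whole community and raises if it occurs anywhere unplanned.
* Protospacers planted with >= 2 mismatches put every substitution in the
  interior that no admissible <=10% end-clipping can remove, so the default
  matcher recovers exactly the <=1-mismatch links and none of the others.
* The single background column flanking each side of a planted repeat set is
  resampled when >= 80% of the repeat occurrences agree there, so
  majority-agreement extension stops exactly at the planted repeat boundary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._dna import count_overlapping, hamming_str, revcomp
from .io_formats import (
    Scaffold,
    write_arrays_gff,
    write_mag_table,
    write_sequences,
    write_viral_table,
)
from .vh_network import HostMAG, ViralElement

CHI_MOTIF = "GCTGGTGG"
_EDGE_MARGIN = 250
_MIN_SPACER_SEPARATION = 7  # survives boundary tweaks with >= 3 to spare


class ConfigError(ValueError):
    """Infeasible synthetic configuration."""


class GeneratorError(RuntimeError):
    """The generated community violates a planted-feature guarantee."""


@dataclass
class SyntheticConfig:
    n_hosts: int = 20
    n_viruses: int = 200
    host_scaffolds_per_mag: int = 2
    scaffold_len_range: tuple[int, int] = (6000, 12000)
    viral_len_range: tuple[int, int] = (8000, 15000)
    gc: float = 0.5
    arrays_per_host: tuple[int, int] = (1, 2)
    repeat_len: tuple[int, int] = (23, 40)
    spacer_len: tuple[int, int] = (25, 45)
    spacers_per_array: tuple[int, int] = (3, 8)
    # (host_idx, virus_idx, n_protospacers, mismatches_per_protospacer)
    planted_links: tuple[tuple[int, int, int, int], ...] = ()
    # (virus_idx, n_spacers, targets); target = (target_virus_idx, mode),
    # mode in {"protospacer", "shared_spacer"}
    viral_array_spec: tuple[tuple[int, int, tuple], ...] = ()
    # (virus_idx, host_idx, identity, length, mode in {"integrated","cobinned"})
    provirus_spec: tuple[tuple[int, int, float, int, str], ...] = ()
    chi_spec: Mapping[int, int] = field(default_factory=dict)
    # extra near-duplicate members appended for clustering tests:
    # (source_virus_idx, n_substitutions)
    viral_duplicates: tuple[tuple[int, int], ...] = ()
    host_duplicates: tuple[tuple[int, int], ...] = ()
    sites: tuple[str, ...] = ("LW1", "LW2", "LW3", "GW1")
    year: int = 2016
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ConfigError("gc must be in (0,1)")
        for h, v, n, mm in self.planted_links:
            if not (0 <= h < self.n_hosts and 0 <= v < self.n_viruses):
                raise ConfigError(f"planted link ({h},{v}) index out of range")
            if n < 1 or mm < 0:
                raise ConfigError("planted link needs n_protospacers >= 1, mismatches >= 0")
            if mm > self.spacer_len[0]:
                raise ConfigError("more substitutions than spacer bases")
        for v, _n, targets in self.viral_array_spec:
            if not 0 <= v < self.n_viruses:
                raise ConfigError(f"viral array virus index {v} out of range")
            for tv, mode in targets:
                if not 0 <= tv < self.n_viruses:
                    raise ConfigError(f"viral array target index {tv} out of range")
                if mode not in ("protospacer", "shared_spacer"):
                    raise ConfigError(f"unknown viral array target mode {mode!r}")
        for v, h, ident, length, mode in self.provirus_spec:
            if not (0 <= v < self.n_viruses and 0 <= h < self.n_hosts):
                raise ConfigError("provirus index out of range")
            if not 0.0 < ident <= 1.0:
                raise ConfigError("provirus identity must be in (0,1]")
            if length > self.viral_len_range[0]:
                raise ConfigError("provirus length exceeds minimum viral length")
            if mode not in ("integrated", "cobinned"):
                raise ConfigError(f"unknown provirus mode {mode!r}")
        if self.spacer_len[0] + 2 * self.repeat_len[0] > self.scaffold_len_range[0] - 2 * _EDGE_MARGIN:
            raise ConfigError("spacer/repeat ranges do not fit in the smallest scaffold")


@dataclass
class PlantedArray:
    array_key: str  # generator-side identifier
    owner_id: str  # MAG or viral element id
    scaffold_id: str
    interval: tuple[int, int]
    repeat_consensus: str
    repeats: tuple[tuple[int, int], ...]
    spacers: tuple[tuple[tuple[int, int], str], ...]  # (interval, seq)

    @property
    def spacer_seqs(self) -> tuple[str, ...]:
        return tuple(s for _iv, s in self.spacers)


@dataclass
class PlantedProtospacer:
    spacer_owner_id: str
    spacer_seq: str
    virus_id: str
    interval: tuple[int, int]
    strand: str
    n_mismatches: int


@dataclass
class PlantedProvirus:
    virus_id: str
    host_mag_id: str
    host_scaffold_id: str
    interval: tuple[int, int]
    identity: float
    mode: str  # "integrated" | "cobinned"


@dataclass
class TruthManifest:
    arrays: list[PlantedArray] = field(default_factory=list)
    protospacers: list[PlantedProtospacer] = field(default_factory=list)
    proviruses: list[PlantedProvirus] = field(default_factory=list)
    # (virus_a, virus_b, shared spacer sequence)
    shared_spacer_overlaps: list[tuple[str, str, str]] = field(default_factory=list)
    chi_counts: dict[str, int] = field(default_factory=dict)
    # (host_id, virus_id, n_protospacers, mismatches)
    links: list[tuple[str, str, int, int]] = field(default_factory=list)
    # (member_id, duplicate_id, n_substitutions)
    duplicate_pairs: list[tuple[str, str, int]] = field(default_factory=list)

    def links_with_max_mismatches(self, max_mm: int) -> set[tuple[str, str]]:
        return {(h, v) for h, v, _n, mm in self.links if mm <= max_mm}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)

        def _tup(x):
            return tuple(_tup(i) for i in x) if isinstance(x, list) else x

        m = cls()
        m.arrays = [
            PlantedArray(**{k: _tup(v) if k != "array_key" else v for k, v in a.items()})
            for a in d["arrays"]
        ]
        m.protospacers = [PlantedProtospacer(**{**p, "interval": tuple(p["interval"])}) for p in d["protospacers"]]
        m.proviruses = [PlantedProvirus(**{**p, "interval": tuple(p["interval"])}) for p in d["proviruses"]]
        m.shared_spacer_overlaps = [tuple(t) for t in d["shared_spacer_overlaps"]]
        m.chi_counts = dict(d["chi_counts"])
        m.links = [tuple(t) for t in d["links"]]
        m.duplicate_pairs = [tuple(t) for t in d["duplicate_pairs"]]
        return m


def recovery_scenario_config(seed: int = 0) -> SyntheticConfig:
    """The standard planted-link study design: 20 hosts, 200 viruses,
    50 links at 0-1 mismatches and 10 at 2 mismatches (unrecoverable under
    the default one-mismatch retention rule), 1-3 protospacers per link.
    """
    rng = np.random.default_rng(seed)
    n_hosts, n_viruses = 20, 200
    virus_order = rng.permutation(n_viruses)
    links = []
    vi = 0
    for i in range(50):
        mm = i % 2  # half exact, half one-mismatch
        links.append(
            (i % n_hosts, int(virus_order[vi]), int(rng.integers(1, 4)), mm)
        )
        vi += 1
    for i in range(10):
        links.append(
            (i % n_hosts, int(virus_order[vi]), int(rng.integers(1, 4)), 2)
        )
        vi += 1
    return SyntheticConfig(
        n_hosts=n_hosts,
        n_viruses=n_viruses,
        planted_links=tuple(links),
        seed=seed,
    )


@dataclass
class SyntheticCommunity:
    config: SyntheticConfig
    mags: list[HostMAG]
    host_scaffolds: dict[str, list[Scaffold]]  # mag_id -> scaffolds
    virals: list[ViralElement]
    viral_scaffolds: list[Scaffold]
    manifest: TruthManifest

    @property
    def all_host_scaffolds(self) -> list[Scaffold]:
        return [sc for scs in self.host_scaffolds.values() for sc in scs]

    def scaffold_to_mag(self) -> dict[str, str]:
        return {
            sc.id: mag_id
            for mag_id, scs in self.host_scaffolds.items()
            for sc in scs
        }

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the exact input formats the pipeline consumes, plus the manifest."""
        outdir = Path(outdir)
        hosts_dir = outdir / "hosts"
        hosts_dir.mkdir(parents=True, exist_ok=True)
        for mag in self.mags:
            write_sequences(self.host_scaffolds[mag.mag_id], hosts_dir / f"{mag.mag_id}.fasta")
        write_sequences(self.viral_scaffolds, outdir / "viruses.fasta")
        write_mag_table(self.mags, outdir / "mags.tsv")
        write_viral_table(self.virals, outdir / "virals.tsv")
        arrays = [
            _planted_to_crispr_array(a, self._seq_of(a.scaffold_id))
            for a in self.manifest.arrays
        ]
        write_arrays_gff(arrays, outdir / "arrays.gff3")
        self.manifest.to_json(outdir / "manifest.json")
        return {
            "hosts_dir": hosts_dir,
            "viral_fasta": outdir / "viruses.fasta",
            "mag_table": outdir / "mags.tsv",
            "viral_table": outdir / "virals.tsv",
            "arrays_gff": outdir / "arrays.gff3",
            "manifest": outdir / "manifest.json",
        }

    def _seq_of(self, scaffold_id: str) -> str:
        for sc in self.all_host_scaffolds + self.viral_scaffolds:
            if sc.id == scaffold_id:
                return sc.seq
        raise KeyError(scaffold_id)


def _planted_to_crispr_array(a: PlantedArray, seq: str):
    from .crispr_detect import _finalize

    arr = _finalize(seq, a.scaffold_id, a.array_key, list(a.repeats))
    return arr


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode("ascii")


def mutate(seq: str, n_subs: int, seed: int | np.random.Generator = 0) -> str:
    """Exactly n_subs substitutions at distinct positions; length preserved."""
    if n_subs > len(seq):
        raise ConfigError(f"cannot place {n_subs} substitutions in {len(seq)} bases")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def _mutate_interior(seq: str, n_subs: int, clip_max: int, rng: np.random.Generator) -> str:
    """Substitutions restricted to [clip_max, len-clip_max): un-clippable."""
    interior = np.arange(clip_max, len(seq) - clip_max)
    if interior.size < n_subs:
        raise ConfigError("interior too small for requested substitutions")
    positions = rng.choice(interior, size=n_subs, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def _draw_unique_spacer(
    rng: np.random.Generator,
    length: int,
    gc: float,
    existing: Sequence[str],
    neighbor: str | None = None,
) -> str:
    """Rejection-sample until far (Hamming >= 7) from all same-length spacers.

    ``neighbor`` is the preceding spacer in the same array; candidates too
    similar to it (> 0.55 alignment identity) are redrawn so the detector's
    adjacent-spacer tandem guard can never fire on a planted array.
    """
    from .crispr_detect import seq_identity

    same_len = [s for s in existing if len(s) == length]
    for _ in range(200):
        cand = random_dna(rng, length, gc)
        if not all(
            hamming_str(cand, s) >= _MIN_SPACER_SEPARATION
            and hamming_str(cand, revcomp(s)) >= _MIN_SPACER_SEPARATION
            for s in same_len
        ):
            continue
        if neighbor is not None and seq_identity(cand, neighbor) > 0.55:
            continue
        return cand
    raise GeneratorError("could not draw a sufficiently distinct spacer")


@dataclass
class _PlannedArray:
    owner_id: str
    repeat: str
    spacers: list[str]


def _array_sequence(p: _PlannedArray) -> str:
    parts = [p.repeat]
    for s in p.spacers:
        parts.append(s)
        parts.append(p.repeat)
    return "".join(parts)


def _enforce_boundary_diversity(
    planned: _PlannedArray, rng: np.random.Generator, frozen: frozenset[int] = frozenset()
) -> None:
    """Diversify the first and last characters across an array's spacers.

    The repeat-extension rule grows repeats while per-column majority
    agreement across occurrences is >= 0.8. The column just outside each
    repeat edge holds one character per spacer plus one background flank
    character; requiring the most common spacer edge character to occur
    at most ceil(0.8 * n_repeats) - 2 times guarantees agreement < 0.8 there
    whatever the background base is, so extension stops exactly at the
    planted boundary. Spacer indices in ``frozen`` (shared spacers whose
    sequence identity must be preserved) are never edited.
    """
    n_rep = len(planned.spacers) + 1
    limit = int(np.ceil(0.8 * n_rep)) - 2  # max allowed multiplicity
    limit = max(limit, 1)
    for pos_of in (lambda s: 0, lambda s: len(s) - 1):
        for _ in range(200):
            chars = [s[pos_of(s)] for s in planned.spacers]
            counts = {b: chars.count(b) for b in set(chars)}
            worst = max(counts, key=lambda b: counts[b])
            if counts[worst] <= limit:
                break
            editable = [
                i
                for i, s in enumerate(planned.spacers)
                if i not in frozen and s[pos_of(s)] == worst
            ]
            if not editable:
                raise GeneratorError("cannot diversify array boundary (all slots frozen)")
            i = editable[int(rng.integers(len(editable)))]
            s = planned.spacers[i]
            p = pos_of(s)
            alt = [b for b in "ACGT" if b != s[p]]
            planned.spacers[i] = s[:p] + alt[int(rng.integers(len(alt)))] + s[p + 1 :]
        else:
            raise GeneratorError("cannot diversify array boundary columns")


def _place_nonoverlapping(
    rng: np.random.Generator,
    scaffold_len: int,
    feature_len: int,
    occupied: list[tuple[int, int]],
    margin: int = _EDGE_MARGIN,
    gap: int = 20,
) -> int:
    lo, hi = margin, scaffold_len - margin - feature_len
    if hi <= lo:
        raise ConfigError(
            f"feature of {feature_len} bp does not fit in scaffold of {scaffold_len} bp"
        )
    for _ in range(500):
        start = int(rng.integers(lo, hi))
        iv = (start - gap, start + feature_len + gap)
        if all(iv[1] <= s or iv[0] >= e for s, e in occupied):
            occupied.append((start, start + feature_len))
            return start
    raise GeneratorError("could not place feature without overlap")


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def generate_community(cfg: SyntheticConfig) -> SyntheticCommunity:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    year = cfg.year

    mag_ids = [f"H{i:03d}" for i in range(cfg.n_hosts)]
    virus_ids = [f"V{i:03d}_{year}" for i in range(cfg.n_viruses)]

    host_seqs: dict[str, list[list[str]]] = {}
    host_scaffold_ids: dict[str, list[str]] = {}
    for i, mid in enumerate(mag_ids):
        seqs, sids = [], []
        for j in range(cfg.host_scaffolds_per_mag):
            L = int(rng.integers(cfg.scaffold_len_range[0], cfg.scaffold_len_range[1] + 1))
            seqs.append(list(random_dna(rng, L, cfg.gc)))
            sids.append(f"{mid}_s{j}")
        host_seqs[mid] = seqs
        host_scaffold_ids[mid] = sids

    viral_seqs: list[list[str]] = []
    for vid in virus_ids:
        L = int(rng.integers(cfg.viral_len_range[0], cfg.viral_len_range[1] + 1))
        viral_seqs.append(list(random_dna(rng, L, cfg.gc)))

    all_spacers: list[str] = []

    # -- plan host arrays, sized to cover planted-link demand ---------------
    demand = {i: 0 for i in range(cfg.n_hosts)}
    for h, _v, n, _mm in cfg.planted_links:
        demand[h] += n
    planned_host_arrays: dict[int, list[_PlannedArray]] = {}
    for i, mid in enumerate(mag_ids):
        n_arrays = int(rng.integers(cfg.arrays_per_host[0], cfg.arrays_per_host[1] + 1))
        counts = [
            int(rng.integers(cfg.spacers_per_array[0], cfg.spacers_per_array[1] + 1))
            for _ in range(n_arrays)
        ]
        while sum(counts) < demand[i]:
            counts[-1] += 1
        arrays = []
        for n_sp in counts:
            rep_len = int(rng.integers(cfg.repeat_len[0], cfg.repeat_len[1] + 1))
            repeat = random_dna(rng, rep_len, cfg.gc)
            spacers = []
            for _ in range(n_sp):
                sp_len = int(rng.integers(cfg.spacer_len[0], cfg.spacer_len[1] + 1))
                sp = _draw_unique_spacer(
                    rng, sp_len, cfg.gc, all_spacers,
                    neighbor=spacers[-1] if spacers else None,
                )
                spacers.append(sp)
                all_spacers.append(sp)
            planned = _PlannedArray(owner_id=mid, repeat=repeat, spacers=spacers)
            _enforce_boundary_diversity(planned, rng)
            arrays.append(planned)
        planned_host_arrays[i] = arrays

    # -- plan viral arrays (before splicing, so spacer sharing is possible) --
    planned_viral_arrays: dict[int, _PlannedArray] = {}
    for v_idx, n_sp, _targets in cfg.viral_array_spec:
        rep_len = int(rng.integers(cfg.repeat_len[0], cfg.repeat_len[1] + 1))
        repeat = random_dna(rng, rep_len, cfg.gc)
        spacers = []
        for _ in range(n_sp):
            sp_len = int(rng.integers(cfg.spacer_len[0], cfg.spacer_len[1] + 1))
            sp = _draw_unique_spacer(
                rng, sp_len, cfg.gc, all_spacers,
                neighbor=spacers[-1] if spacers else None,
            )
            spacers.append(sp)
            all_spacers.append(sp)
        planned = _PlannedArray(owner_id=virus_ids[v_idx], repeat=repeat, spacers=spacers)
        _enforce_boundary_diversity(planned, rng)
        planned_viral_arrays[v_idx] = planned

    manifest = TruthManifest()
    shared_assignments: list[tuple[int, int, str]] = []  # (src_idx, tgt_idx, seq)
    protospacer_plants: list[tuple[str, str, int, int, int]] = []
    # (owner_id, spacer_seq, virus_idx, n_mismatches, _order)

    for v_idx, _n_sp, targets in cfg.viral_array_spec:
        src = planned_viral_arrays[v_idx]
        for t_i, (tv, mode) in enumerate(targets):
            if t_i >= len(src.spacers):
                raise ConfigError(
                    f"viral array on virus {v_idx} has {len(src.spacers)} spacers "
                    f"but {len(targets)} targets"
                )
            if mode == "shared_spacer":
                if tv not in planned_viral_arrays:
                    raise ConfigError(
                        f"shared_spacer target virus {tv} has no viral array spec"
                    )
                sp = src.spacers[t_i]
                tgt_arr = planned_viral_arrays[tv]
                slot = t_i % len(tgt_arr.spacers)
                tgt_arr.spacers[slot] = sp
                # re-diversify the target boundary without touching the copy
                _enforce_boundary_diversity(tgt_arr, rng, frozen=frozenset({slot}))
                shared_assignments.append((v_idx, tv, sp))
    for v_idx, _n_sp, targets in cfg.viral_array_spec:
        src = planned_viral_arrays[v_idx]
        for t_i, (tv, mode) in enumerate(targets):
            if mode == "protospacer":
                sp = src.spacers[t_i]
                protospacer_plants.append(
                    (virus_ids[v_idx], sp, tv, 0, len(protospacer_plants))
                )

    # -- planted host->virus links ------------------------------------------
    spacer_cursor = {i: 0 for i in range(cfg.n_hosts)}
    for h, v, n, mm in cfg.planted_links:
        pool = [sp for arr in planned_host_arrays[h] for sp in arr.spacers]
        for _ in range(n):
            if spacer_cursor[h] >= len(pool):
                raise ConfigError(f"host {h} has too few spacers for its links")
            sp = pool[spacer_cursor[h]]
            spacer_cursor[h] += 1
            protospacer_plants.append((mag_ids[h], sp, v, mm, len(protospacer_plants)))
        manifest.links.append((mag_ids[h], virus_ids[v], n, mm))

    # -- splice arrays into scaffolds ---------------------------------------
    host_occupied: dict[str, list[tuple[int, int]]] = {}
    for i, mid in enumerate(mag_ids):
        for arr_i, planned in enumerate(planned_host_arrays[i]):
            arr_seq = _array_sequence(planned)
            j = arr_i % cfg.host_scaffolds_per_mag
            sid = host_scaffold_ids[mid][j]
            seq_list = host_seqs[mid][j]
            occupied = host_occupied.setdefault(sid, [])
            start = _place_nonoverlapping(rng, len(seq_list), len(arr_seq), occupied)
            seq_list[start : start + len(arr_seq)] = list(arr_seq)
            manifest.arrays.append(
                _record_array(planned, sid, start, f"{mid}_planted_{arr_i}")
            )

    viral_occupied: dict[int, list[tuple[int, int]]] = {}
    for v_idx, planned in planned_viral_arrays.items():
        arr_seq = _array_sequence(planned)
        seq_list = viral_seqs[v_idx]
        occupied = viral_occupied.setdefault(v_idx, [])
        start = _place_nonoverlapping(rng, len(seq_list), len(arr_seq), occupied)
        seq_list[start : start + len(arr_seq)] = list(arr_seq)
        manifest.arrays.append(
            _record_array(planned, virus_ids[v_idx], start, f"{virus_ids[v_idx]}_planted_0")
        )
    for src_idx, tgt_idx, sp in shared_assignments:
        manifest.shared_spacer_overlaps.append(
            (virus_ids[src_idx], virus_ids[tgt_idx], sp)
        )

    # -- plant protospacers ---------------------------------------------------
    clip_guard = int((1 - 0.90) * cfg.spacer_len[1]) + 1
    for owner, sp, v_idx, mm, _ord in protospacer_plants:
        if mm == 0:
            proto = sp
        elif mm == 1:
            proto = mutate(sp, 1, rng)
        else:
            proto = _mutate_interior(sp, mm, clip_guard, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = proto if strand == "+" else revcomp(proto)
        seq_list = viral_seqs[v_idx]
        occupied = viral_occupied.setdefault(v_idx, [])
        start = _place_nonoverlapping(rng, len(seq_list), len(planted), occupied, gap=5)
        seq_list[start : start + len(planted)] = list(planted)
        manifest.protospacers.append(
            PlantedProtospacer(
                spacer_owner_id=owner,
                spacer_seq=sp,
                virus_id=virus_ids[v_idx],
                interval=(start, start + len(planted)),
                strand=strand,
                n_mismatches=mm,
            )
        )

    # -- proviruses -----------------------------------------------------------
    for v_idx, h_idx, ident, length, mode in cfg.provirus_spec:
        v_seq = "".join(viral_seqs[v_idx])
        if length > len(v_seq):
            raise ConfigError("provirus segment longer than its virus")
        lo, hi = 0, len(v_seq) - length
        if v_idx in planned_viral_arrays:
            # carry the viral CRISPR array into the host when it fits: the
            # integrated copy is what superinfection-exclusion analysis reads
            arr_rec = next(
                a for a in manifest.arrays if a.owner_id == virus_ids[v_idx]
            )
            a_start, a_end = arr_rec.interval
            if a_end - a_start <= length:
                lo, hi = max(0, a_end - length), min(a_start, len(v_seq) - length)
        seg_start = int(rng.integers(lo, hi + 1))
        segment = v_seq[seg_start : seg_start + length]
        n_subs = int(round((1.0 - ident) * length))
        segment = mutate(segment, n_subs, rng) if n_subs else segment
        mid = mag_ids[h_idx]
        if mode == "integrated":
            j = 0
            sid = host_scaffold_ids[mid][j]
            seq_list = host_seqs[mid][j]
            occupied = host_occupied.setdefault(sid, [])
            # insert strictly after every planted feature so recorded
            # coordinates stay valid; never inside an earlier feature
            e_max = max([e for _s, e in occupied], default=0)
            ins = min(e_max + _EDGE_MARGIN, len(seq_list) - 50)
            if ins < e_max:
                ins = e_max
            _plant_mismatch_barrier(seq_list, ins - 1, v_seq, seg_start - 1, -1, rng)
            _plant_mismatch_barrier(
                seq_list, ins, v_seq, seg_start + length, +1, rng
            )
            host_seqs[mid][j] = seq_list[:ins] + list(segment) + seq_list[ins:]
            interval = (ins, ins + length)
            occupied.append(interval)
        else:  # cobinned: a mostly-viral free scaffold in the host bin
            flank = max(8, int(length * 0.04))
            left = list(random_dna(rng, flank, cfg.gc))
            right = list(random_dna(rng, flank, cfg.gc))
            _plant_mismatch_barrier(left, flank - 1, v_seq, seg_start - 1, -1, rng)
            _plant_mismatch_barrier(right, 0, v_seq, seg_start + length, +1, rng)
            new_seq = "".join(left) + segment + "".join(right)
            sid = f"{mid}_s{len(host_scaffold_ids[mid])}"
            host_scaffold_ids[mid].append(sid)
            host_seqs[mid].append(list(new_seq))
            interval = (flank, flank + length)
        manifest.proviruses.append(
            PlantedProvirus(
                virus_id=virus_ids[v_idx],
                host_mag_id=mid,
                host_scaffold_id=sid,
                interval=interval,
                identity=ident,
                mode=mode,
            )
        )

    # -- Chi motifs -----------------------------------------------------------
    for v_idx, want in sorted(cfg.chi_spec.items()):
        seq_list = viral_seqs[v_idx]
        occupied = viral_occupied.setdefault(v_idx, [])
        _scrub_motif(seq_list, occupied, rng)
        for _ in range(want):
            start = _place_nonoverlapping(rng, len(seq_list), len(CHI_MOTIF), occupied, gap=2)
            seq_list[start : start + len(CHI_MOTIF)] = list(CHI_MOTIF)
        seq = "".join(seq_list)
        n_found = count_overlapping(seq, CHI_MOTIF) + count_overlapping(seq, revcomp(CHI_MOTIF))
        if n_found != want:
            raise GeneratorError(
                f"chi planting on virus {v_idx}: wanted {want}, sequence has {n_found}"
            )
        manifest.chi_counts[virus_ids[v_idx]] = want

    # -- appended near-duplicates for clustering/dereplication tests ----------
    extra_virals: list[tuple[str, str]] = []
    for src_idx, n_subs in cfg.viral_duplicates:
        src_id = virus_ids[src_idx]
        dup_id = f"{src_id}_dup{len(extra_virals)}"
        dup_seq = mutate("".join(viral_seqs[src_idx]), n_subs, rng)
        extra_virals.append((dup_id, dup_seq))
        manifest.duplicate_pairs.append((src_id, dup_id, n_subs))
    extra_hosts: list[tuple[str, list[str]]] = []
    for src_idx, n_subs in cfg.host_duplicates:
        src_id = mag_ids[src_idx]
        dup_id = f"{src_id}dup{len(extra_hosts)}"
        dup_seqs = [mutate("".join(s), n_subs, rng) for s in host_seqs[src_id]]
        extra_hosts.append((dup_id, dup_seqs))
        manifest.duplicate_pairs.append((src_id, dup_id, n_subs))

    # -- assemble containers ---------------------------------------------------
    sites = cfg.sites
    mags = []
    host_scaffolds: dict[str, list[Scaffold]] = {}
    for i, mid in enumerate(mag_ids):
        site = sites[i % len(sites)]
        scs = [
            Scaffold(id=sid, seq="".join(s), source_sample=site, year=year)
            for sid, s in zip(host_scaffold_ids[mid], host_seqs[mid])
        ]
        host_scaffolds[mid] = scs
        mags.append(
            HostMAG(
                mag_id=mid,
                scaffold_ids=tuple(sc.id for sc in scs),
                completeness=float(round(75 + 24 * rng.random(), 2)),
                contamination=float(round(5 * rng.random(), 2)),
                lineage=_random_lineage(rng, i),
                site=site,
                year=year,
            )
        )
    for dup_id, dup_seqs in extra_hosts:
        scs = [
            Scaffold(id=f"{dup_id}_s{j}", seq=s, source_sample=sites[0], year=year)
            for j, s in enumerate(dup_seqs)
        ]
        host_scaffolds[dup_id] = scs
        mags.append(
            HostMAG(
                mag_id=dup_id,
                scaffold_ids=tuple(sc.id for sc in scs),
                completeness=90.0,
                contamination=1.0,
                lineage=_random_lineage(rng, cfg.n_hosts),
                site=sites[0],
                year=year,
            )
        )

    virals = []
    viral_scaffolds = []
    for i, vid in enumerate(virus_ids):
        seq = "".join(viral_seqs[i])
        site = sites[(i + 1) % len(sites)]
        viral_scaffolds.append(Scaffold(id=vid, seq=seq, source_sample=site, year=year))
        virals.append(
            ViralElement(
                viral_id=vid, scaffold_id=vid, length=len(seq), site=site, year=year,
                category="nonintegrated",
            )
        )
    for dup_id, dup_seq in extra_virals:
        viral_scaffolds.append(
            Scaffold(id=dup_id, seq=dup_seq, source_sample=sites[0], year=year)
        )
        virals.append(
            ViralElement(
                viral_id=dup_id, scaffold_id=dup_id, length=len(dup_seq),
                site=sites[0], year=year, category="nonintegrated",
            )
        )

    community = SyntheticCommunity(
        config=cfg,
        mags=mags,
        host_scaffolds=host_scaffolds,
        virals=virals,
        viral_scaffolds=viral_scaffolds,
        manifest=manifest,
    )
    _verify_planted_uniqueness(community)
    return community


def _record_array(
    planned: _PlannedArray, scaffold_id: str, start: int, key: str
) -> PlantedArray:
    rep_len = len(planned.repeat)
    repeats = []
    spacers = []
    pos = start
    repeats.append((pos, pos + rep_len))
    for s in planned.spacers:
        sp_start = pos + rep_len
        spacers.append(((sp_start, sp_start + len(s)), s))
        pos = sp_start + len(s)
        repeats.append((pos, pos + rep_len))
    end = pos + rep_len
    return PlantedArray(
        array_key=key,
        owner_id=planned.owner_id,
        scaffold_id=scaffold_id,
        interval=(start, end),
        repeat_consensus=planned.repeat,
        repeats=tuple(repeats),
        spacers=tuple(spacers),
    )


def _plant_mismatch_barrier(
    host_list: list[str],
    host_pos: int,
    v_seq: str,
    v_pos: int,
    step: int,
    rng: np.random.Generator,
    width: int = 8,
) -> None:
    """Force ``width`` mismatching columns at a planted-insert boundary.

    Local alignment of the viral sequence against the host otherwise extends
    past the planted segment whenever adjacent background bases happen to
    match the viral continuation (probability 1/4 per column), blurring the
    planted boundary. Eight consecutive forced mismatches push the extension
    score walk to -16, from which recovery under +1/-2 scoring is
    negligible, so called boundaries equal planted ones.
    """
    for k in range(width):
        hp = host_pos + step * k
        vp = v_pos + step * k
        if not (0 <= hp < len(host_list) and 0 <= vp < len(v_seq)):
            return
        if host_list[hp] == v_seq[vp]:
            alt = [b for b in "ACGT" if b != v_seq[vp]]
            host_list[hp] = alt[int(rng.integers(3))]


def _scrub_motif(
    seq_list: list[str], protected: list[tuple[int, int]], rng: np.random.Generator
) -> None:
    """Remove incidental Chi motif occurrences outside planted features."""
    motifs = (CHI_MOTIF, revcomp(CHI_MOTIF))
    for _ in range(100):
        seq = "".join(seq_list)
        hits = []
        for motif in motifs:
            start = 0
            while True:
                i = seq.find(motif, start)
                if i < 0:
                    break
                hits.append(i)
                start = i + 1
        hits = [
            i
            for i in hits
            if all(i + len(CHI_MOTIF) <= s or i >= e for s, e in protected)
        ]
        if not hits:
            return
        for i in hits:
            p = i + int(rng.integers(len(CHI_MOTIF)))
            alt = [b for b in "ACGT" if b != seq_list[p]]
            seq_list[p] = alt[rng.integers(len(alt))]
    raise GeneratorError("could not scrub Chi motifs")


def _random_lineage(rng: np.random.Generator, i: int) -> tuple[str, ...]:
    phyla = ("Firmicutes", "Proteobacteria", "Bacteroidota", "Patescibacteria",
             "Myxococcota", "Actinobacteriota")
    phylum = phyla[i % len(phyla)]
    return (
        "Bacteria", phylum, f"c{i}", f"o{i}", f"f{i}", f"g{i}", f"s{i}",
    )


def _verify_planted_uniqueness(com: SyntheticCommunity) -> None:
    """Search every planted spacer community-wide; raise on unplanned loci.

    Allowed loci per spacer: inside any planted array span, inside any
    planted protospacer interval for that spacer, or inside a planted
    provirus interval on a host scaffold (an integrated copy of a viral
    array). Anything else breaks the recovery contract.
    """
    from ._dna import KmerIndex
    from .spacer_match import MatchParams, Spacer, find_protospacers

    targets = {
        sc.id: sc.seq for sc in com.all_host_scaffolds + com.viral_scaffolds
    }
    index = KmerIndex(targets, k=10)
    allowed: dict[str, list[tuple[int, int]]] = {}
    for a in com.manifest.arrays:
        allowed.setdefault(a.scaffold_id, []).append(a.interval)
    for pv in com.manifest.proviruses:
        allowed.setdefault(pv.host_scaffold_id, []).append(pv.interval)
    proto_allowed: dict[str, list[tuple[str, tuple[int, int]]]] = {}
    for p in com.manifest.protospacers:
        proto_allowed.setdefault(p.spacer_seq, []).append((p.virus_id, p.interval))

    spacers = []
    seen_ids = set()
    for a in com.manifest.arrays:
        for si, (_iv, seq) in enumerate(a.spacers):
            sp_id = f"{a.array_key}:{si}"
            if sp_id in seen_ids:
                continue
            seen_ids.add(sp_id)
            spacers.append(
                Spacer(
                    spacer_id=sp_id, owner_id=a.owner_id, scaffold_id=a.scaffold_id,
                    array_id=a.array_key, index_in_array=si, seq=seq,
                )
            )
    matches = find_protospacers(spacers, index, MatchParams())
    spacer_seq = {sp.spacer_id: sp.seq for sp in spacers}
    for m in matches:
        ivs = allowed.get(m.target_id, [])
        if any(s <= m.start and m.end <= e for s, e in ivs):
            continue
        seq = spacer_seq[m.spacer_id]
        if any(
            vid == m.target_id and s - 1 <= m.start and m.end <= e + 1
            for vid, (s, e) in proto_allowed.get(seq, [])
        ):
            continue
        raise GeneratorError(
            f"planted spacer {m.spacer_id} has an unplanned match on "
            f"{m.target_id}:{m.start}-{m.end}; re-seed the generator"
        )
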