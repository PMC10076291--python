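"""Virus-host network construction and interrogation.

Networks are bipartite: host MAG nodes on one side, viral elements on the
other. An edge exists when at least one retained CRISPR spacer -> protospacer
match links the pair; the edge weight counts *distinct protospacer loci* on
the viral element (a single spacer hitting two loci contributes two, two
spacers hitting the same locus contribute one). "Unique links" counts
distinct (host, virus) pairs regardless of weight.

Hosts are gated on assembly quality before matching: completeness strictly
above 70% and contamination strictly below 10% (medium-quality draft MAG or
better). Hyper-targeting flags a (virus, host) pair whose single host's
spacer set targets at least 20 distinct protospacer loci on that element.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover
    from .spacer_match import ProtospacerMatch

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


class ConsistencyError(ValueError):
    """A record references an unknown MAG or viral element."""


@dataclass
class HostMAG:
    """A metagenome-assembled genome with CheckM-style quality metadata."""

    mag_id: str
    scaffold_ids: tuple[str, ...] = ()
    completeness: float = 0.0
    contamination: float = 100.0
    lineage: tuple[str, ...] = ("",) * 7
    site: str = ""
    year: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"completeness outside [0,100]: {self.completeness}")
        if not 0.0 <= self.contamination <= 100.0:
            raise ValueError(f"contamination outside [0,100]: {self.contamination}")
        if len(self.lineage) != 7:
            raise ValueError("lineage must have 7 ranks (domain..species)")

    def rank(self, name: str) -> str:
        return self.lineage[RANKS.index(name)]


@dataclass
class ViralElement:
    """A predicted viral scaffold (labels consumed from upstream prediction)."""

    viral_id: str
    scaffold_id: str = ""
    length: int = 0
    site: str = ""
    year: int = 0
    dgr_flag: bool = False
    category: str = "nonintegrated"  # or "provirus"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("viral element length must be >= 1")


@dataclass
class QualityParams:
    min_completeness: float = 70.0
    max_contamination: float = 10.0
    hyper_threshold: int = 20
    min_curation_scaffold_len: int = 10_000  # flag-only in curation


@dataclass
class VirusHostNetwork:
    """Weighted bipartite host<->virus graph with provenance annotations."""

    label: str
    hosts: dict[str, HostMAG] = field(default_factory=dict)
    virals: dict[str, ViralElement] = field(default_factory=dict)
    # (host_id, viral_id) -> supporting match ids; weight = distinct loci
    edges: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    weights: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def unique_links(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(label=self.label)
        for hid, mag in self.hosts.items():
            g.add_node(
                hid,
                kind="host",
                site=mag.site,
                year=mag.year,
                taxonomy=";".join(mag.lineage),
            )
        for vid, ve in self.virals.items():
            g.add_node(
                vid,
                kind="virus",
                site=ve.site,
                year=ve.year,
                taxonomy="",
                dgr=ve.dgr_flag,
            )
        for (hid, vid), mids in self.edges.items():
            g.add_edge(hid, vid, weight=self.weights[(hid, vid)], matches=",".join(mids))
        return g


def quality_filter_mags(
    mags: Iterable[HostMAG], params: QualityParams | None = None
) -> list[HostMAG]:
    """Keep MAGs with completeness strictly > 70 and contamination strictly < 10."""
    params = params or QualityParams()
    return [
        m
        for m in mags
        if m.completeness > params.min_completeness
        and m.contamination < params.max_contamination
    ]


def build_network(
    matches: Sequence["ProtospacerMatch"],
    mags: Iterable[HostMAG],
    virals: Iterable[ViralElement],
    label: str = "",
) -> VirusHostNetwork:
    """Aggregate retained spacer->protospacer matches into a bipartite network.

    Matches flagged ``in_array`` (protospacer falls inside a CRISPR array on
    the target, i.e. a spacer-spacer hit with no adjacent PAM) are excluded:
    they do not evidence infection. Edge weight = distinct target loci.
    """
    mag_by_id = {m.mag_id: m for m in mags}
    viral_by_id = {v.viral_id: v for v in virals}
    net = VirusHostNetwork(label=label)
    loci: dict[tuple[str, str], set[tuple[int, int, str]]] = {}
    for m in matches:
        if m.in_array:
            continue
        if m.owner_id not in mag_by_id:
            raise ConsistencyError(f"match references unknown MAG {m.owner_id!r}")
        if m.target_id not in viral_by_id:
            raise ConsistencyError(f"match references unknown viral element {m.target_id!r}")
        key = (m.owner_id, m.target_id)
        net.hosts.setdefault(m.owner_id, mag_by_id[m.owner_id])
        net.virals.setdefault(m.target_id, viral_by_id[m.target_id])
        net.edges.setdefault(key, []).append(m.match_id)
        loci.setdefault(key, set()).add((m.start, m.end, m.strand))
    for key, locus_set in loci.items():
        net.weights[key] = len(locus_set)
    return net


def summarize_network(net: VirusHostNetwork) -> dict:
    """Counts mirroring a networks-summary table row plus degree statistics."""
    host_deg: dict[str, int] = {h: 0 for h in net.hosts}
    viral_deg: dict[str, int] = {v: 0 for v in net.virals}
    for hid, vid in net.edges:
        host_deg[hid] += 1
        viral_deg[vid] += 1
    n_hosts, n_virals = len(net.hosts), len(net.virals)
    multi_h = sum(1 for d in host_deg.values() if d >= 2)
    multi_v = sum(1 for d in viral_deg.values() if d >= 2)
    weights = sorted(net.weights.values())
    return {
        "network": net.label,
        "n_host_mags": n_hosts,
        "n_viral_scaffolds": n_virals,
        "unique_links": net.unique_links,
        "pct_hosts_multi_viral": 100.0 * multi_h / n_hosts if n_hosts else 0.0,
        "pct_virals_multi_host": 100.0 * multi_v / n_virals if n_virals else 0.0,
        "weight_distribution": {w: weights.count(w) for w in sorted(set(weights))},
    }


def write_network_summaries(summaries: Iterable[Mapping], path) -> None:
    """TSV with columns Network / Host MAGs / Viral scaffolds / Unique links."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["network", "host_mags", "viral_scaffolds", "unique_links"])
        for s in summaries:
            w.writerow(
                [s["network"], s["n_host_mags"], s["n_viral_scaffolds"], s["unique_links"]]
            )


def find_hyper_targeted(
    net: VirusHostNetwork, threshold: int = 20
) -> list[tuple[str, str, int]]:
    """(viral_id, host_id, n_protospacer_loci) pairs at weight >= threshold."""
    hits = [
        (vid, hid, w) for (hid, vid), w in net.weights.items() if w >= threshold
    ]
    hits.sort(key=lambda t: (-t[2], t[0], t[1]))
    return hits


@dataclass
class CrossTaxonCandidate:
    viral_id: str
    rank: str
    host_ids: tuple[str, ...]
    rank_values: tuple[str, ...]  # parallel to host_ids; "" = unrankable
    unrankable_hosts: tuple[str, ...]
    networks: tuple[str, ...] = ()


def find_cross_taxon(
    net: VirusHostNetwork, rank: str = "phylum"
) -> list[CrossTaxonCandidate]:
    """Viral elements whose linked hosts differ at the given taxonomic rank.

    Hosts with an empty value at the rank are flagged unrankable and do not
    count toward the distinct-value requirement.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    by_virus: dict[str, list[str]] = {}
    for hid, vid in net.edges:
        by_virus.setdefault(vid, []).append(hid)
    out = []
    for vid in sorted(by_virus):
        hids = sorted(set(by_virus[vid]))
        values = [net.hosts[h].rank(rank) for h in hids]
        unrankable = tuple(h for h, v in zip(hids, values) if not v)
        distinct = {v for v in values if v}
        if len(distinct) >= 2:
            out.append(
                CrossTaxonCandidate(
                    viral_id=vid,
                    rank=rank,
                    host_ids=tuple(hids),
                    rank_values=tuple(values),
                    unrankable_hosts=unrankable,
                    networks=(net.label,),
                )
            )
    return out


@dataclass
class CurationVerdict:
    candidate: CrossTaxonCandidate
    quality_ok: bool
    short_scaffold_hosts: tuple[str, ...]  # flag-only
    shared_spacer_counts: dict[tuple[str, str], int]
    possible_hgt_pairs: tuple[tuple[str, str], ...]
    taxonomy_ok: bool | None  # None when no per-scaffold taxonomy supplied
    passed: bool
    reasons: tuple[str, ...]


def _lineages_congruent(mag_lineage: Sequence[str], scaffold_lineage: Sequence[str]) -> bool:
    """Congruent when no rank where both are non-empty disagrees."""
    return all(
        (not a) or (not b) or a == b for a, b in zip(mag_lineage, scaffold_lineage)
    )


def curate_cross_taxon(
    candidates: Sequence[CrossTaxonCandidate],
    mags: Iterable[HostMAG],
    array_scaffold_info: Mapping[str, Sequence[tuple[str, int, Sequence[str]]]],
    scaffold_taxonomy: Mapping[str, Sequence[str]] | None = None,
    params: QualityParams | None = None,
    hgt_min_shared: int = 5,
) -> list[CurationVerdict]:
    """Case-by-case screen of cross-taxon infection candidates.

    ``array_scaffold_info`` maps host_id -> records of the CRISPR-array-bearing
    scaffolds implicated in the candidate links: (scaffold_id, scaffold_len,
    spacer_sequences). Checks: (a) MAG quality gate (fails verdict);
    (b) scaffold length floor (flag only); (c) identical-spacer sharing between
    the implicated arrays, annotated as possible horizontal transfer when high;
    (d) MAG-vs-scaffold taxonomy congruence when supplied (fails verdict).
    """
    params = params or QualityParams()
    mag_by_id = {m.mag_id: m for m in mags}
    verdicts = []
    for cand in candidates:
        reasons: list[str] = []
        cand_mags = [mag_by_id[h] for h in cand.host_ids]
        good = {m.mag_id for m in quality_filter_mags(cand_mags, params)}
        quality_ok = good == set(cand.host_ids)
        if not quality_ok:
            bad = sorted(set(cand.host_ids) - good)
            reasons.append(f"MAG quality gate failed: {','.join(bad)}")

        short_hosts = []
        for hid in cand.host_ids:
            for sid, slen, _sp in array_scaffold_info.get(hid, ()):
                if slen < params.min_curation_scaffold_len:
                    short_hosts.append(hid)
                    reasons.append(
                        f"array scaffold {sid} of {hid} shorter than "
                        f"{params.min_curation_scaffold_len} bp (flag only)"
                    )

        shared_counts: dict[tuple[str, str], int] = {}
        hgt_pairs = []
        hids = list(cand.host_ids)
        for i in range(len(hids)):
            for j in range(i + 1, len(hids)):
                sp_i = {s for _sid, _l, sps in array_scaffold_info.get(hids[i], ()) for s in sps}
                sp_j = {s for _sid, _l, sps in array_scaffold_info.get(hids[j], ()) for s in sps}
                n_shared = len(sp_i & sp_j)
                shared_counts[(hids[i], hids[j])] = n_shared
                if n_shared >= hgt_min_shared:
                    hgt_pairs.append((hids[i], hids[j]))
                    reasons.append(
                        f"{hids[i]} and {hids[j]} share {n_shared} identical spacers"
                        " (possible horizontal transfer of the array)"
                    )

        taxonomy_ok: bool | None = None
        if scaffold_taxonomy is not None:
            taxonomy_ok = True
            for hid in cand.host_ids:
                for sid, _l, _sp in array_scaffold_info.get(hid, ()):
                    lin = scaffold_taxonomy.get(sid)
                    if lin is not None and not _lineages_congruent(
                        mag_by_id[hid].lineage, lin
                    ):
                        taxonomy_ok = False
                        reasons.append(
                            f"scaffold {sid} taxonomy incongruent with MAG {hid}"
                        )

        passed = quality_ok and (taxonomy_ok is not False)
        verdicts.append(
            CurationVerdict(
                candidate=cand,
                quality_ok=quality_ok,
                short_scaffold_hosts=tuple(dict.fromkeys(short_hosts)),
                shared_spacer_counts=shared_counts,
                possible_hgt_pairs=tuple(hgt_pairs),
                taxonomy_ok=taxonomy_ok,
                passed=passed,
                reasons=tuple(reasons),
            )
        )
    return verdicts


def write_curation_report(verdicts: Sequence[CurationVerdict], path) -> None:
    """One row per candidate per check outcome."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["viral_id", "rank", "hosts", "check", "outcome", "detail"])
        for v in verdicts:
            c = v.candidate
            hosts = ",".join(c.host_ids)
            w.writerow([c.viral_id, c.rank, hosts, "mag_quality", "pass" if v.quality_ok else "fail", ""])
            w.writerow(
                [c.viral_id, c.rank, hosts, "scaffold_length",
                 "flag" if v.short_scaffold_hosts else "pass",
                 ",".join(v.short_scaffold_hosts)]
            )
            for (a, b), n in sorted(v.shared_spacer_counts.items()):
                w.writerow([c.viral_id, c.rank, hosts, "shared_spacers",
                            "hgt_flag" if (a, b) in v.possible_hgt_pairs else "pass",
                            f"{a}~{b}:{n}"])
            if v.taxonomy_ok is not None:
                w.writerow([c.viral_id, c.rank, hosts, "scaffold_taxonomy",
                            "pass" if v.taxonomy_ok else "fail", ""])
            w.writerow([c.viral_id, c.rank, hosts, "overall",
                        "pass" if v.passed else "fail", "; ".join(v.reasons)])
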